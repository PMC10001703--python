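"""Compare a dosimetry-guided boost plan against whole-lesion SBRT.

Runs the full pipeline on one synthetic case — SIRT dose, target selection,
idealized 36 Gy / 3 fraction SBRT dose for both plan variants — then prints
the clinic's feasibility metrics and constraint checks for each.
"""

from sirtboost import PhantomConfig, check_constraints, compare_plans, run_synthetic_case

res = run_synthetic_case(PhantomConfig(seed=42))

for metrics in (res.alone, res.boost):
    if metrics is None:
        continue
    rep = check_constraints(metrics)
    print(f"SBRT_{metrics.plan_kind:<5}  MLD {metrics.mld_nlt:5.2f} Gy "
          f"(<9: {'pass' if rep.mld_pass else 'FAIL'})  "
          f"CV15 {metrics.cv15_cc:6.1f} cc (>700: {'pass' if rep.cv15_pass else 'FAIL'})  "
          f"NTCP {metrics.ntcp_pct:5.2f}%  PTV {metrics.ptv_cc:6.1f} cc")

if res.boost is not None:
    c = compare_plans(res.alone, res.boost)
    print(f"boost spares {c.d_mld_gy:.2f} Gy of mean normal-liver dose and "
          f"debulks the PTV by {c.rel_ptv_reduction_pct:.0f}%")

# The boost plan irradiates less normal liver because SIRT already treated
# part of the tumor burden; the CV15 floor (hepatic reserve) is easier to
# hold and the RILD NTCP drops with the gEUD of the liver dose.
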
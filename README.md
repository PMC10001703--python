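# sirtboost

Analysis pipeline for planning a stereotactic body radiotherapy (SBRT)
boost on top of ⁹⁰Y selective internal radiation therapy (SIRT) of
hepatocellular carcinoma, driven by the *delivered* microsphere dose.

SIRT frequently underdoses lesions or lesion subregions; post-therapy
PET-derived absorbed-dose maps make that visible per voxel.  `sirtboost`
takes such a dose map plus liver and lesion masks and

1. predicts per-lesion response with logistic TCP models,
   `TCP(d) = 1 / (1 + exp(-(b0 + b1 d)))`, calibrated by their 50%-TCP
   doses — 292 Gy for the partial-volume-corrected mean lesion dose and
   70 Gy for the uncorrected coverage metric D90;
2. carves dose-painted boost targets: lesions with mean dose < 292 Gy,
   restricted to their sub-70 Gy voxels, expanded anisotropically
   (5 mm left/right/anterior/posterior, 8 mm superior/inferior) into PTVs;
3. evaluates and compares the boost plan against whole-lesion SBRT by mean
   normal-liver-tissue (NLT) dose, hepatic cold volume CV15Gy, PTV volume,
   and Lyman–Kutcher–Burman NTCP for radiation-induced liver disease,
   `NTCP = Φ((gEUD − TD₅₀)/(m·TD₅₀))` with n = 0.97, m = 0.12,
   TD₅₀ = 35.4 Gy.

A synthetic-phantom generator (ellipsoidal liver, spherical lesions,
log-normal intra-lesion SIRT dose at PET-like resolution, idealized
exponential-falloff SBRT dose) makes every stage testable without clinical
data, and a packaged 20-patient reference table of per-plan metrics
supports cohort-level analyses.  It is a library for radiotherapy
physicists and dosimetry researchers, used from Python; the scripts in
`examples/` are the entry points.

## Worked example

`python examples/03_evaluate_plans.py` runs the full chain on a seeded
synthetic case and prints:

```
SBRT_alone  MLD  5.49 Gy (<9: pass)  CV15  966.8 cc (>700: pass)  NTCP  0.00%  PTV   58.8 cc
SBRT_boost  MLD  2.80 Gy (<9: pass)  CV15 1030.1 cc (>700: pass)  NTCP  0.00%  PTV   25.5 cc
boost spares 2.68 Gy of mean normal-liver dose and debulks the PTV by 57%
```

One of the two lesions received 450 Gy mean SIRT dose, is predicted to
respond and leaves the boost target; the other (120 Gy mean, D90 36 Gy)
keeps only its sub-70 Gy subvolume.  The boost PTV is therefore less than
half the monotherapy PTV, the mean NLT dose drops by 2.7 Gy, and the
CV15Gy hepatic reserve grows — the liver-sparing rationale of the combined
approach.  `examples/05_cohort_summary.py` prints the cohort statistics of
the packaged reference table (12/20 monotherapy and 10/14 boost plans
within the MLD < 9 Gy constraint; mean relative PTV reduction 39%).

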
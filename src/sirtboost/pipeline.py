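"""End-to-end synthetic case runner.

Composes the full chain on one synthetic case: phantom geometry → SIRT dose
→ lesion dose metrics → two-stage boost-target selection → idealized SBRT
dose for both the monotherapy and the boost plan → plan metrics.  Exists so
examples, tests and reproduction scripts share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dvh import RecoveryCurve
from .grids import DoseGrid, StructureSet
from .ntcp import LKBParams
from .phantom import PhantomConfig, SBRTDoseModel, make_phantom, simulate_sbrt_dose, simulate_sirt_dose
from .plan_eval import ConstraintSet, PlanMetrics, evaluate_plan
from .targets import CaseTargets, Lesion, SelectionConfig, build_boost_targets, lesion_from_mask

__all__ = ["CaseResult", "run_synthetic_case"]


@dataclass
class CaseResult:
    """Everything one synthetic case produces."""

    structures: StructureSet
    sirt_dose: DoseGrid
    lesions: list[Lesion]
    targets: CaseTargets
    alone: PlanMetrics
    boost: PlanMetrics | None   # None when no lesion is boost-eligible


def run_synthetic_case(phantom_config: PhantomConfig,
                       selection: SelectionConfig | None = None,
                       sbrt_model: SBRTDoseModel | None = None,
                       constraints: ConstraintSet | None = None,
                       lkb: LKBParams | None = None,
                       recovery: RecoveryCurve | None = None) -> CaseResult:
    selection = selection or SelectionConfig()
    sbrt_model = sbrt_model or SBRTDoseModel()
    constraints = constraints or ConstraintSet()
    lkb = lkb or LKBParams()

    structures = make_phantom(phantom_config)
    sirt = simulate_sirt_dose(structures, phantom_config)
    lesions = [lesion_from_mask(name, structures[name], sirt, recovery)
               for name in structures.gtv_names]
    targets = build_boost_targets(lesions, sirt, selection)

    alone_ptvs = list(targets.alone_ptvs.values())
    alone_dose = simulate_sbrt_dose(alone_ptvs, sbrt_model)
    alone = evaluate_plan(alone_dose, structures, alone_ptvs,
                          plan_kind="alone",
                          lesions_targeted=len(alone_ptvs),
                          lesions_total=len(lesions),
                          constraints=constraints, lkb=lkb)

    boost = None
    if targets.boost_eligible:
        boost_ptvs = [t.ptv for t in targets.boost_targets if t.eligible]
        boost_dose = simulate_sbrt_dose(boost_ptvs, sbrt_model)
        boost = evaluate_plan(boost_dose, structures, boost_ptvs,
                              plan_kind="boost",
                              lesions_targeted=targets.n_targeted,
                              lesions_total=len(lesions),
                              constraints=constraints, lkb=lkb)
    return CaseResult(structures, sirt, lesions, targets, alone, boost)
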
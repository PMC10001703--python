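"""Plan metric extraction, constraint checks and cohort aggregation.

Each SBRT plan — monotherapy ("alone", targeting every evaluable lesion) or
dosimetry-guided ("boost", targeting only SIRT-underdosed subvolumes) — is
summarised by the clinic's feasibility metrics: mean dose to the normal
liver tissue (MLD), RILD NTCP, the cold hepatic reserve CV15Gy, and total
PTV volume.  The standard-of-care constraints at a 36 Gy / 3 fraction
prescription are MLD strictly below 9 Gy and CV15Gy strictly above 700 cc.

A reference 20-patient cohort table (per-plan metrics as printed, including
non-eligible cases marked NA) ships with the package; ``summarize_cohort``
reproduces its aggregate statistics — constraint pass counts, paired deltas
and the relative target-debulking benefit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .dvh import cold_volume_cc, mean_dose
from .grids import DoseGrid, StructureMask, StructureSet, derive_nlt, union_masks, volume_cc
from .ntcp import LKBParams, rild_ntcp
from .targets import debulking_stats

__all__ = [
    "PlanMetrics",
    "ConstraintSet",
    "ConstraintReport",
    "PlanComparison",
    "CohortSummary",
    "evaluate_plan",
    "check_constraints",
    "compare_plans",
    "summarize_cohort",
    "load_reference_cohort",
    "pairs_from_table",
]


@dataclass
class PlanMetrics:
    """One plan's feasibility metrics (one cohort-table row)."""

    case_id: str
    plan_kind: str  # "alone" | "boost"
    mld_nlt: float      # Gy
    ntcp_pct: float     # percent
    cv15_cc: float      # cc
    ptv_cc: float       # cc
    lesions_targeted: int
    lesions_total: int

    def __post_init__(self) -> None:
        if self.plan_kind not in ("alone", "boost"):
            raise ValueError(f"plan_kind must be 'alone' or 'boost', got {self.plan_kind!r}")
        if self.lesions_targeted > self.lesions_total:
            raise ValueError("lesions_targeted cannot exceed lesions_total")
        if self.ptv_cc < 0:
            raise ValueError("ptv_cc must be non-negative")

    def rounded(self) -> dict:
        """Report-style rounding: Gy to 1 decimal, cc and percent to integer."""
        return {
            "case_id": self.case_id,
            "plan_kind": self.plan_kind,
            "mld_nlt_gy": round(self.mld_nlt, 1),
            "ntcp_pct": round(self.ntcp_pct),
            "cv15_cc": round(self.cv15_cc),
            "ptv_cc": round(self.ptv_cc),
            "lesions": f"{self.lesions_targeted}/{self.lesions_total}",
        }


@dataclass(frozen=True)
class ConstraintSet:
    """Normal-liver objectives; both inequalities are strict."""

    mld_limit_gy: float = 9.0
    cv15_floor_cc: float = 700.0
    prescription_gy: float = 36.0   # metadata
    fractions: int = 3              # metadata
    cv15_threshold_gy: float = 15.0

    def __post_init__(self) -> None:
        if self.mld_limit_gy <= 0 or self.cv15_floor_cc <= 0:
            raise ValueError("constraint limits must be positive")


@dataclass(frozen=True)
class ConstraintReport:
    mld_pass: bool
    cv15_pass: bool

    @property
    def overall(self) -> bool:
        return self.mld_pass and self.cv15_pass


def evaluate_plan(dose: DoseGrid, structures: StructureSet,
                  ptvs: list[StructureMask], *, case_id: str | None = None,
                  plan_kind: str = "alone", lesions_targeted: int | None = None,
                  lesions_total: int | None = None,
                  constraints: ConstraintSet | None = None,
                  lkb: LKBParams | None = None) -> PlanMetrics:
    """Extract all feasibility metrics of one plan.

    NLT is taken from ``structures['nlt']`` if present, else derived as
    liver minus all GTVs.  The reported PTV volume is the volume of the
    union of the targeted PTVs.
    """
    if not ptvs:
        raise ValueError("plan has no PTVs")
    constraints = constraints or ConstraintSet()
    lkb = lkb or LKBParams()
    nlt = structures["nlt"] if "nlt" in structures else derive_nlt(
        structures.liver, structures.gtvs)
    ptv_union = union_masks(ptvs, name="ptv_union")
    n_total = lesions_total if lesions_total is not None else len(structures.gtv_names)
    n_targeted = lesions_targeted if lesions_targeted is not None else len(ptvs)
    return PlanMetrics(
        case_id=case_id or structures.case_id,
        plan_kind=plan_kind,
        mld_nlt=mean_dose(dose, nlt),
        ntcp_pct=100.0 * rild_ntcp(dose, nlt, lkb),
        cv15_cc=cold_volume_cc(dose, nlt, constraints.cv15_threshold_gy),
        ptv_cc=volume_cc(ptv_union),
        lesions_targeted=n_targeted,
        lesions_total=n_total,
    )


def check_constraints(metrics: PlanMetrics,
                      constraints: ConstraintSet | None = None) -> ConstraintReport:
    """Strict constraint check: MLD < limit and CV15Gy > floor."""
    constraints = constraints or ConstraintSet()
    return ConstraintReport(
        mld_pass=metrics.mld_nlt < constraints.mld_limit_gy,
        cv15_pass=metrics.cv15_cc > constraints.cv15_floor_cc,
    )


@dataclass(frozen=True)
class PlanComparison:
    """Paired deltas, oriented so positive numbers favour the boost plan."""

    case_id: str
    d_mld_gy: float             # alone - boost (dose spared)
    d_cv15_cc: float            # boost - alone (reserve gained)
    d_ptv_cc: float             # alone - boost (volume debulked)
    rel_ptv_reduction_pct: float


def compare_plans(alone: PlanMetrics, boost: PlanMetrics) -> PlanComparison:
    if alone.case_id != boost.case_id:
        raise ValueError(f"case mismatch: {alone.case_id!r} vs {boost.case_id!r}")
    if alone.plan_kind != "alone" or boost.plan_kind != "boost":
        raise ValueError("expected one 'alone' and one 'boost' plan")
    return PlanComparison(
        case_id=alone.case_id,
        d_mld_gy=alone.mld_nlt - boost.mld_nlt,
        d_cv15_cc=boost.cv15_cc - alone.cv15_cc,
        d_ptv_cc=alone.ptv_cc - boost.ptv_cc,
        rel_ptv_reduction_pct=debulking_stats(alone.ptv_cc, boost.ptv_cc),
    )


@dataclass
class CohortSummary:
    """Cohort-level aggregates over (alone, boost-or-None) plan pairs."""

    n_cases: int
    n_boost_eligible: int
    lesions_targeted_total: int
    lesions_total: int
    alone_mld_pass: int
    boost_mld_pass: int
    alone_cv15_pass: int
    boost_cv15_pass: int
    mean_d_mld_gy: float
    sd_d_mld_gy: float
    mean_d_cv15_cc: float
    sd_d_cv15_cc: float
    mean_d_ptv_cc: float
    sd_d_ptv_cc: float
    mean_rel_ptv_reduction_pct: float
    sd_rel_ptv_reduction_pct: float
    min_rel_ptv_reduction_pct: float
    max_rel_ptv_reduction_pct: float
    comparisons: list[PlanComparison] = field(default_factory=list, repr=False)


def summarize_cohort(pairs: list[tuple[PlanMetrics, PlanMetrics | None]],
                     constraints: ConstraintSet | None = None,
                     ddof: int = 1) -> CohortSummary:
    """Aggregate a cohort of paired plans.

    ``pairs`` holds one (alone, boost) tuple per case; cases not eligible
    for a boost carry ``None``.  Paired deltas and debulking statistics are
    computed over boost-eligible cases only; ``ddof=1`` gives the sample
    standard deviation used for reported plus/minus values.  Deterministic
    and permutation-invariant over cases.
    """
    if not pairs:
        raise ValueError("empty cohort")
    constraints = constraints or ConstraintSet()

    comparisons = []
    for alone, boost in pairs:
        if boost is not None:
            comparisons.append(compare_plans(alone, boost))
    comparisons.sort(key=lambda c: c.case_id)

    def _stats(x: np.ndarray) -> tuple[float, float]:
        if x.size == 0:
            return float("nan"), float("nan")
        sd = float(np.std(x, ddof=ddof)) if x.size > ddof else 0.0
        return float(np.mean(x)), sd

    d_mld = np.array([c.d_mld_gy for c in comparisons])
    d_cv15 = np.array([c.d_cv15_cc for c in comparisons])
    d_ptv = np.array([c.d_ptv_cc for c in comparisons])
    rel = np.array([c.rel_ptv_reduction_pct for c in comparisons])

    alones = [a for a, _ in pairs]
    boosts = [b for _, b in pairs if b is not None]
    return CohortSummary(
        n_cases=len(pairs),
        n_boost_eligible=len(boosts),
        lesions_targeted_total=sum(b.lesions_targeted for b in boosts),
        lesions_total=sum(a.lesions_total for a in alones),
        alone_mld_pass=sum(check_constraints(a, constraints).mld_pass for a in alones),
        boost_mld_pass=sum(check_constraints(b, constraints).mld_pass for b in boosts),
        alone_cv15_pass=sum(check_constraints(a, constraints).cv15_pass for a in alones),
        boost_cv15_pass=sum(check_constraints(b, constraints).cv15_pass for b in boosts),
        mean_d_mld_gy=_stats(d_mld)[0], sd_d_mld_gy=_stats(d_mld)[1],
        mean_d_cv15_cc=_stats(d_cv15)[0], sd_d_cv15_cc=_stats(d_cv15)[1],
        mean_d_ptv_cc=_stats(d_ptv)[0], sd_d_ptv_cc=_stats(d_ptv)[1],
        mean_rel_ptv_reduction_pct=_stats(rel)[0],
        sd_rel_ptv_reduction_pct=_stats(rel)[1],
        min_rel_ptv_reduction_pct=float(rel.min()) if rel.size else float("nan"),
        max_rel_ptv_reduction_pct=float(rel.max()) if rel.size else float("nan"),
        comparisons=comparisons,
    )


def load_reference_cohort() -> pd.DataFrame:
    """Packaged 20-patient reference cohort table (values as printed; NA for
    cases with no boost plan)."""
    with resources.files("sirtboost.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh, na_values=["NA"])


def pairs_from_table(df: pd.DataFrame) -> list[tuple[PlanMetrics, PlanMetrics | None]]:
    """Convert a cohort table into (alone, boost) :class:`PlanMetrics` pairs."""
    pairs = []
    for row in df.itertuples(index=False):
        case = str(row.patient)
        # the monotherapy plan targets every evaluable lesion
        alone = PlanMetrics(case, "alone", row.alone_mld_gy, row.alone_ntcp_pct,
                            row.alone_cv15_cc, row.alone_ptv_cc,
                            int(row.lesions_total), int(row.lesions_total))
        boost = None
        if not pd.isna(row.boost_mld_gy):
            boost = PlanMetrics(case, "boost", row.boost_mld_gy, row.boost_ntcp_pct,
                                row.boost_cv15_cc, row.boost_ptv_cc,
                                int(row.lesions_targeted), int(row.lesions_total))
        pairs.append((alone, boost))
    return pairs
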
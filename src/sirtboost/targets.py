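"""Two-stage boost-target selection and anisotropic PTV expansion.

Target debulking proceeds in two stages driven by the SIRT dose map:

1. Lesion stage — lesions whose partial-volume-corrected mean SIRT dose is
   at least the 50%-TCP threshold (292 Gy by default) are predicted
   responders and excluded from the boost; lesions below it are eligible.
2. Voxel stage — within each eligible lesion, only the subvolume that
   received strictly less than the D90-derived voxel threshold (70 Gy by
   default) is targeted.  A lesion whose GTV is entirely at or above the
   voxel threshold drops out with reason ``empty-subvolume``.

Boost subvolumes (and, for the comparison plan, whole GTVs) are expanded to
planning target volumes by an anisotropic Euclidean margin: 5 mm
left/right/anterior/posterior and 8 mm superior/inferior by default, with
asymmetric margins resolved per displacement sign and the expansion clipped
at the grid boundary.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dvh import RecoveryCurve, apply_recovery_coefficient, dose_at_volume_fraction, mean_dose
from .grids import DoseGrid, StructureMask, union_masks, volume_cc

__all__ = [
    "Lesion",
    "BoostTarget",
    "SelectionConfig",
    "lesion_from_mask",
    "classify_lesions",
    "extract_boost_subvolume",
    "expand_to_ptv",
    "build_boost_targets",
    "debulking_stats",
]


@dataclass
class SelectionConfig:
    """Thresholds and margins of the selection pipeline.

    ``margins_mm`` order: (left, right, anterior, posterior, superior,
    inferior) — i.e. per signed direction of the x, y, z axes.
    """

    mean_dose_threshold_gy: float = 292.0
    voxel_threshold_gy: float = 70.0
    margins_mm: tuple[float, float, float, float, float, float] = (5, 5, 5, 5, 8, 8)
    min_lesion_volume_cc: float = 2.0

    def __post_init__(self) -> None:
        if self.mean_dose_threshold_gy <= 0 or self.voxel_threshold_gy <= 0:
            raise ValueError("thresholds must be positive")
        if any(m < 0 for m in self.margins_mm):
            raise ValueError("margins must be non-negative")


@dataclass
class Lesion:
    """A segmented GTV with its SIRT dose metrics."""

    id: str
    gtv: StructureMask
    mean_dose_corrected: float
    d90_uncorrected: float
    volume_cc: float

    def __post_init__(self) -> None:
        for v in (self.mean_dose_corrected, self.d90_uncorrected, self.volume_cc):
            if not np.isfinite(v):
                raise ValueError(f"lesion {self.id}: metrics must be finite")

    @property
    def evaluable(self) -> bool:
        """Study inclusion rule: lesions must exceed 2 cc to be evaluable
        (below that, PET partial-volume effects make the dosimetry unreliable)."""
        return self.volume_cc > 2.0


def lesion_from_mask(lesion_id: str, gtv: StructureMask, sirt_dose: DoseGrid,
                     recovery: RecoveryCurve | None = None) -> Lesion:
    """Measure a lesion's dose metrics from the SIRT dose map.

    Mean dose is partial-volume corrected through ``recovery`` (identity
    curve if omitted); D90 is deliberately left uncorrected.
    """
    vol = volume_cc(gtv)
    measured_mean = mean_dose(sirt_dose, gtv)
    curve = recovery if recovery is not None else RecoveryCurve.identity()
    return Lesion(
        id=lesion_id,
        gtv=gtv,
        mean_dose_corrected=apply_recovery_coefficient(measured_mean, vol, curve),
        d90_uncorrected=dose_at_volume_fraction(sirt_dose, gtv, 0.90),
        volume_cc=vol,
    )


def classify_lesions(lesions: list[Lesion], config: SelectionConfig | None = None,
                     ) -> tuple[list[Lesion], list[Lesion]]:
    """Partition lesions into (excluded, eligible) by corrected mean dose.

    A lesion receiving at least the mean-dose threshold is predicted to
    respond and is excluded from the boost; the boundary dose itself is
    excluded.  Ordering is preserved.
    """
    config = config or SelectionConfig()
    if not lesions:
        raise ValueError("empty lesion list")
    excluded = [l for l in lesions
                if l.mean_dose_corrected >= config.mean_dose_threshold_gy]
    eligible = [l for l in lesions
                if l.mean_dose_corrected < config.mean_dose_threshold_gy]
    return excluded, eligible


def extract_boost_subvolume(gtv: StructureMask, sirt_dose: DoseGrid,
                            config: SelectionConfig | None = None) -> StructureMask:
    """GTV voxels with SIRT dose strictly below the voxel threshold.

    Equivalent to subtracting the threshold isodose contour at voxel
    resolution.  May be empty (lesion fully covered by SIRT) or the whole
    GTV (maximum SIRT dose below threshold); disconnected subvolumes are
    kept as one mask.
    """
    config = config or SelectionConfig()
    sirt_dose.geometry.require_match(gtv.geometry, what=gtv.name or "gtv")
    if gtv.is_empty():
        raise ValueError("gtv is empty")
    sub = gtv.values & (sirt_dose.values < config.voxel_threshold_gy)
    return gtv.with_values(sub, name=f"{gtv.name or 'gtv'}_boost")


def _margin_footprint(spacing, margins_mm) -> np.ndarray:
    """Boolean offset neighbourhood of the anisotropic ellipsoidal margin.

    Offset (dx,dy,dz) from a target voxel is inside the PTV iff
    sum((delta/margin_signed)^2) <= 1, the signed margin picked per axis
    direction; zero margins confine that direction to delta == 0.
    """
    ml, mr, ma, mp, ms, mi = margins_mm
    # voxel reach per axis (max of both directions)
    reach = [int(math.floor(max(neg, pos) / s + 1e-9))
             for s, (neg, pos) in zip(spacing, [(ml, mr), (mp, ma), (mi, ms)])]
    shape = tuple(2 * r + 1 for r in reach)
    fp = np.zeros(shape, dtype=bool)
    for di, dj, dk in itertools.product(*(range(-r, r + 1) for r in reach)):
        dx, dy, dz = di * spacing[0], dj * spacing[1], dk * spacing[2]
        q = 0.0
        for delta, neg, pos in ((dx, ml, mr), (dy, mp, ma), (dz, mi, ms)):
            m = pos if delta > 0 else neg
            if delta == 0:
                continue
            if m == 0:
                q = np.inf
                break
            q += (delta / m) ** 2
        if q <= 1.0 + 1e-12:
            fp[di + reach[0], dj + reach[1], dk + reach[2]] = True
    return fp


def expand_to_ptv(target: StructureMask,
                  margins_mm: tuple[float, ...] = (5, 5, 5, 5, 8, 8),
                  name: str | None = None) -> StructureMask:
    """Anisotropic Euclidean (ellipsoidal) expansion of a target to its PTV.

    A voxel joins the PTV iff some target voxel lies within the scaled
    ellipsoid defined by the six directional margins; the expansion is
    clipped at the grid boundary.
    """
    if target.is_empty():
        raise ValueError("target is empty")
    if any(m < 0 for m in margins_mm):
        raise ValueError("margins must be non-negative")
    fp = _margin_footprint(target.spacing, margins_mm)
    out = ndimage.binary_dilation(target.values, structure=fp)
    return target.with_values(out, name=name or f"{target.name or 'target'}_ptv")


@dataclass
class BoostTarget:
    """Per-lesion selection outcome; ``reason`` is one of
    ``eligible`` / ``responder`` / ``empty-subvolume`` / ``too-small``."""

    lesion_id: str
    eligible: bool
    reason: str
    boost_gtv: StructureMask | None = None
    ptv: StructureMask | None = None

    @property
    def boost_gtv_cc(self) -> float:
        return 0.0 if self.boost_gtv is None else volume_cc(self.boost_gtv)

    @property
    def ptv_cc(self) -> float:
        return 0.0 if self.ptv is None else volume_cc(self.ptv)


@dataclass
class CaseTargets:
    """All selection outputs of one case: per-lesion boost targets, the
    union boost PTV, and the comparison (all-lesion) PTV."""

    boost_targets: list[BoostTarget]
    alone_ptvs: dict[str, StructureMask]
    boost_eligible: bool = field(init=False)

    def __post_init__(self) -> None:
        self.boost_eligible = any(t.eligible for t in self.boost_targets)

    @property
    def n_targeted(self) -> int:
        return sum(t.eligible for t in self.boost_targets)

    def boost_ptv_union(self) -> StructureMask | None:
        ptvs = [t.ptv for t in self.boost_targets if t.eligible and t.ptv is not None]
        return union_masks(ptvs, name="ptv_boost") if ptvs else None

    def alone_ptv_union(self) -> StructureMask | None:
        ptvs = list(self.alone_ptvs.values())
        return union_masks(ptvs, name="ptv_alone") if ptvs else None


def build_boost_targets(lesions: list[Lesion], sirt_dose: DoseGrid,
                        config: SelectionConfig | None = None) -> CaseTargets:
    """Run the full two-stage selection for one case.

    Produces a :class:`BoostTarget` per evaluable lesion and, for the
    monotherapy comparison plan, a PTV from each whole GTV under the same
    margins.  A case is boost-eligible iff at least one lesion survives
    both stages.
    """
    config = config or SelectionConfig()
    if not lesions:
        raise ValueError("empty lesion list")

    boost_targets: list[BoostTarget] = []
    alone_ptvs: dict[str, StructureMask] = {}
    for lesion in lesions:
        if lesion.volume_cc <= config.min_lesion_volume_cc:
            boost_targets.append(BoostTarget(lesion.id, False, "too-small"))
            continue
        alone_ptvs[lesion.id] = expand_to_ptv(
            lesion.gtv, config.margins_mm, name=f"{lesion.id}_ptv_alone")
        if lesion.mean_dose_corrected >= config.mean_dose_threshold_gy:
            boost_targets.append(BoostTarget(lesion.id, False, "responder"))
            continue
        sub = extract_boost_subvolume(lesion.gtv, sirt_dose, config)
        if sub.is_empty():
            boost_targets.append(BoostTarget(lesion.id, False, "empty-subvolume"))
            continue
        ptv = expand_to_ptv(sub, config.margins_mm, name=f"{lesion.id}_ptv_boost")
        boost_targets.append(BoostTarget(lesion.id, True, "eligible",
                                         boost_gtv=sub, ptv=ptv))
    return CaseTargets(boost_targets=boost_targets, alone_ptvs=alone_ptvs)


def debulking_stats(alone_ptv_cc: float, boost_ptv_cc: float) -> float:
    """Relative PTV reduction in percent: 100 * (alone - boost) / alone."""
    if alone_ptv_cc <= 0:
        raise ValueError("alone PTV volume must be positive")
    return 100.0 * (alone_ptv_cc - boost_ptv_cc) / alone_ptv_cc
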
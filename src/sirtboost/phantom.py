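"""Synthetic cases: phantom geometry, SIRT and SBRT dose fields, responses.

The generator stands in for the clinical inputs the pipeline normally
consumes — a post-therapy PET-derived microsphere dose map on a 2 mm
lattice, radiologist lesion contours and an inverse-optimised SBRT dose —
with the statistical structure the analysis assumes:

* an ellipsoidal liver with spherical lesion GTVs;
* heterogeneous intra-lesion SIRT dose, drawn log-normally per voxel
  (wide spread, controllable target mean), Gaussian-smoothed to mimic PET
  resolution, then rescaled so each lesion's realized mean hits its target;
  low positive background dose elsewhere in the liver;
* an idealized SBRT dose: uniform prescription inside the PTV union with
  exponential distance falloff outside — a declared stand-in for a VMAT
  dose engine, isolated so a real one could replace it;
* Bernoulli lesion responses drawn from a logistic TCP model.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import DoseGrid, StructureMask, StructureSet, derive_nlt, union_masks
from .tcp import LogitTCPModel, ResponseRecord, tcp

__all__ = [
    "LesionSpec",
    "PhantomConfig",
    "SBRTDoseModel",
    "make_phantom",
    "simulate_sirt_dose",
    "simulate_sbrt_dose",
    "simulate_responses",
]


@dataclass(frozen=True)
class LesionSpec:
    """One spherical lesion: geometry plus intended SIRT dose statistics."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    target_mean_dose_gy: float
    heterogeneity: float = 0.8   # log-normal sigma of intra-lesion dose

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be positive")
        if self.target_mean_dose_gy <= 0:
            raise ValueError("target mean dose must be positive")
        if self.heterogeneity < 0:
            raise ValueError("heterogeneity must be non-negative")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, dose statistics and seed of one synthetic case."""

    shape: tuple[int, int, int] = (96, 96, 80)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    liver_center_mm: tuple[float, float, float] = (96.0, 96.0, 80.0)
    liver_semiaxes_mm: tuple[float, float, float] = (80.0, 60.0, 55.0)
    lesions: tuple[LesionSpec, ...] = (
        LesionSpec((70.0, 90.0, 80.0), 15.0, 120.0),
        LesionSpec((120.0, 100.0, 70.0), 12.0, 450.0),
    )
    background_dose_gy: float = 5.0
    smoothing_mm: float = 4.0    # PET-resolution surrogate (Gaussian sigma)
    seed: int = 0
    case_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.background_dose_gy < 0 or self.smoothing_mm < 0:
            raise ValueError("background dose and smoothing must be non-negative")


def _coordinate_fields(config: PhantomConfig) -> tuple[np.ndarray, ...]:
    axes = [np.arange(n) * s for n, s in zip(config.shape, config.spacing_mm)]
    return np.meshgrid(*axes, indexing="ij")


def make_phantom(config: PhantomConfig) -> StructureSet:
    """Build the liver / lesion / NLT masks of one synthetic case.

    Raises if any lesion sphere is not entirely inside the liver ellipsoid.
    """
    xx, yy, zz = _coordinate_fields(config)
    cx, cy, cz = config.liver_center_mm
    ax, ay, az = config.liver_semiaxes_mm
    liver_vals = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 + ((zz - cz) / az) ** 2 <= 1.0
    liver = StructureMask(liver_vals, config.spacing_mm, name="liver")

    sset = StructureSet(case_id=config.case_id)
    sset.add(liver)
    for i, spec in enumerate(config.lesions, start=1):
        lx, ly, lz = spec.center_mm
        r = spec.radius_mm
        inside = (((lx - cx) / ax) ** 2 + ((ly - cy) / ay) ** 2
                  + ((lz - cz) / az) ** 2)
        # conservative containment: centre offset + radius within the
        # smallest semi-axis worth of slack
        if np.sqrt(inside) + r / min(ax, ay, az) > 1.0:
            raise ValueError(f"lesion {i} (centre {spec.center_mm}, r={r} mm) "
                             "is not contained in the liver")
        vals = (xx - lx) ** 2 + (yy - ly) ** 2 + (zz - lz) ** 2 <= r ** 2
        sset.add(StructureMask(vals, config.spacing_mm, name=f"gtv_{i}"))
    sset.add(derive_nlt(liver, sset.gtvs))
    sset.validate()
    return sset


def simulate_sirt_dose(phantom: StructureSet, config: PhantomConfig) -> DoseGrid:
    """Heterogeneous microsphere absorbed-dose map for one phantom.

    Intra-lesion dose is log-normal with log-sd equal to the lesion's
    heterogeneity parameter, realized as a spatially correlated log-Gaussian
    field: white Gaussian noise is smoothed by ``smoothing_mm`` (the
    PET-resolution surrogate, entering as the field's correlation length)
    and renormalized to unit variance before exponentiation, so smoothing
    sets the spatial texture without shrinking the dose spread.  Each lesion
    is then rescaled multiplicatively so its realized in-mask mean equals
    the target mean.  Liver background is ``background_dose_gy`` with mild
    (10%) multiplicative noise on the same field; dose outside the liver is
    zero.
    """
    rng = np.random.default_rng(config.seed)
    liver = phantom.liver
    shape = liver.geometry.shape

    field = rng.normal(size=shape)
    if config.smoothing_mm > 0:
        sig_vox = [config.smoothing_mm / s for s in config.spacing_mm]
        field = ndimage.gaussian_filter(field, sigma=sig_vox)
        field /= field.std()

    values = np.zeros(shape)
    values[liver.values] = config.background_dose_gy * np.exp(
        0.1 * field[liver.values] - 0.005)

    gtvs = phantom.gtvs
    if len(gtvs) != len(config.lesions):
        raise ValueError("phantom and config lesion counts differ")
    for mask, spec in zip(gtvs, config.lesions):
        sigma = spec.heterogeneity
        values[mask.values] = spec.target_mean_dose_gy * np.exp(
            sigma * field[mask.values] - 0.5 * sigma**2)

    for mask, spec in zip(gtvs, config.lesions):
        realized = values[mask.values].mean()
        if realized <= 0:
            raise ValueError(f"unattainable target mean for lesion {mask.name}")
        values[mask.values] *= spec.target_mean_dose_gy / realized

    return DoseGrid(values, config.spacing_mm)


@dataclass(frozen=True)
class SBRTDoseModel:
    """Idealized external-beam dose: flat prescription in the PTV union,
    exponential falloff with Euclidean distance (mm) outside."""

    prescription_gy: float = 36.0
    falloff_mm: float = 8.0
    fractions: int = 3   # metadata

    def __post_init__(self) -> None:
        if self.prescription_gy <= 0 or self.falloff_mm <= 0:
            raise ValueError("prescription and falloff must be positive")


def simulate_sbrt_dose(ptvs: list[StructureMask],
                       model: SBRTDoseModel | None = None) -> DoseGrid:
    """Dose field for a plan targeting the union of ``ptvs``.

    Inside the union the dose equals the prescription exactly; outside it is
    prescription * exp(-d / falloff) with d the anisotropy-aware Euclidean
    distance (mm) to the nearest PTV voxel.  Shrinking the union can only
    lower the dose at any fixed voxel — the debulking mechanism this
    analysis quantifies.
    """
    model = model or SBRTDoseModel()
    if not ptvs:
        raise ValueError("need at least one PTV")
    union = union_masks(ptvs, name="ptv_union")
    if union.is_empty():
        raise ValueError("PTV union is empty")
    dist = ndimage.distance_transform_edt(~union.values, sampling=union.spacing)
    values = model.prescription_gy * np.exp(-dist / model.falloff_mm)
    return DoseGrid(values, union.spacing, union.origin)


def simulate_responses(dose_metrics, model: LogitTCPModel,
                       seed: int = 0) -> list[ResponseRecord]:
    """Bernoulli lesion responses: responder ~ Bern(TCP(metric))."""
    rng = np.random.default_rng(seed)
    metrics = np.asarray(dose_metrics, dtype=float)
    p = tcp(model, metrics)
    draws = rng.random(metrics.size) < np.atleast_1d(p)
    return [ResponseRecord(dose_metric=float(m), responder=bool(r),
                           lesion_id=f"lesion_{i+1}")
            for i, (m, r) in enumerate(zip(metrics, draws))]
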
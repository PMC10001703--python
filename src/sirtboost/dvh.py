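"""Dose-volume histograms and scalar dose metrics.

All scalar metrics (mean dose, Dxx, Vx, cold volume) are computed exactly
from the voxel doses inside a mask; the binned DVH exists for reporting and
export only.  The Dxx quantile uses the convention that with N voxels,
D(f) is the ceil(f*N)-th largest voxel dose, which guarantees that at least
a fraction f of the volume receives >= D(f).

Partial-volume recovery coefficients (sphere-phantom style) correct a
PET-measured lesion *mean* dose for resolution loss; they are a volume-
dependent divisor and apply to mean dose only, never to coverage metrics
like D90.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import DoseGrid, StructureMask, volume_cc

__all__ = [
    "DVH",
    "RecoveryCurve",
    "compute_dvh",
    "mean_dose",
    "dose_at_volume_fraction",
    "volume_fraction_at_dose",
    "cold_volume_cc",
    "apply_recovery_coefficient",
]


def _masked_doses(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    dose.geometry.require_match(mask.geometry, what=mask.name or "mask")
    if mask.is_empty():
        raise ValueError(f"mask {mask.name!r} is empty")
    return dose.values[mask.values]


@dataclass
class DVH:
    """Differential + cumulative dose-volume histogram with uniform bins."""

    bin_edges: np.ndarray          # Gy, ascending, len = nbins + 1
    diff_volume_cc: np.ndarray     # volume per [edge, edge+width) bin
    cum_volume_cc: np.ndarray      # volume receiving >= lower bin edge
    total_volume_cc: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_edge_Gy": self.bin_edges[:-1],
            "diff_cc": self.diff_volume_cc,
            "cum_cc": self.cum_volume_cc,
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def compute_dvh(dose: DoseGrid, mask: StructureMask, bin_width: float = 0.1) -> DVH:
    """Histogram the masked voxel doses into uniform ``bin_width`` Gy bins.

    Each voxel falls in exactly one ``[edge, edge + width)`` bin; the
    maximum dose lands in the last bin.  Differential bins sum to the mask
    volume by construction.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    doses = _masked_doses(dose, mask)
    vox_cc = mask.geometry.voxel_volume_cc
    nbins = int(np.floor(doses.max() / bin_width)) + 1
    edges = np.arange(nbins + 1) * bin_width
    idx = np.minimum((doses // bin_width).astype(int), nbins - 1)
    counts = np.bincount(idx, minlength=nbins)
    diff = counts * vox_cc
    cum = diff[::-1].cumsum()[::-1]
    return DVH(edges, diff, cum, total_volume_cc=doses.size * vox_cc)


def mean_dose(dose: DoseGrid, mask: StructureMask) -> float:
    """Volume-weighted mean dose inside the mask (plain mean on a uniform lattice)."""
    return float(_masked_doses(dose, mask).mean())


def dose_at_volume_fraction(dose: DoseGrid, mask: StructureMask, fraction: float) -> float:
    """Dxx: largest dose d such that >= ``fraction`` of the volume receives >= d.

    ``fraction=0.90`` gives D90, the minimum dose to the best-covered 90% of
    the structure.  With N voxels this is the ceil(fraction*N)-th largest
    voxel dose; ``fraction=1.0`` returns the minimum voxel dose.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    doses = np.sort(_masked_doses(dose, mask))[::-1]
    k = math.ceil(fraction * doses.size)
    return float(doses[k - 1])


def volume_fraction_at_dose(dose: DoseGrid, mask: StructureMask, threshold: float) -> float:
    """Vx in percent: 100 x (volume receiving >= threshold) / total volume."""
    doses = _masked_doses(dose, mask)
    return 100.0 * float(np.count_nonzero(doses >= threshold)) / doses.size


def cold_volume_cc(dose: DoseGrid, mask: StructureMask, threshold: float = 15.0) -> float:
    """CVx: absolute volume (cc) of masked voxels receiving strictly less than
    ``threshold`` Gy.  CV15Gy of the normal liver is the hepatic-reserve
    surrogate used as a planning constraint."""
    doses = _masked_doses(dose, mask)
    return float(np.count_nonzero(doses < threshold)) * mask.geometry.voxel_volume_cc


@dataclass
class RecoveryCurve:
    """Volume-dependent recovery coefficients for partial-volume correction.

    Piecewise-linear in lesion volume, clamped to the end values outside the
    tabulated range.  Coefficients are in (0, 1] and non-decreasing with
    volume: small lesions lose more apparent dose to PET resolution.
    """

    volumes_cc: np.ndarray
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.volumes_cc = np.asarray(self.volumes_cc, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.volumes_cc.size == 0:
            raise ValueError("recovery curve is empty")
        if self.volumes_cc.size != self.coefficients.size:
            raise ValueError("volumes and coefficients must have equal length")
        if np.any(np.diff(self.volumes_cc) <= 0):
            raise ValueError("volumes must be strictly ascending")
        if np.any(np.diff(self.coefficients) < 0):
            raise ValueError("coefficients must be non-decreasing with volume")
        if np.any(self.coefficients <= 0) or self.coefficients[-1] > 1.0:
            raise ValueError("coefficients must be in (0, 1]")

    def __call__(self, volume_cc: float) -> float:
        return float(np.interp(volume_cc, self.volumes_cc, self.coefficients))

    @classmethod
    def identity(cls) -> "RecoveryCurve":
        """RC == 1 everywhere (no partial-volume correction)."""
        return cls(np.array([1.0]), np.array([1.0]))

    @classmethod
    def default(cls) -> "RecoveryCurve":
        """Shipped sphere-phantom-style default; configurable, not clinical."""
        return cls(np.array([2.0, 10.0, 30.0, 100.0]),
                   np.array([0.55, 0.75, 0.90, 1.00]))

    @classmethod
    def from_csv(cls, path) -> "RecoveryCurve":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"volume_cc": self.volumes_cc,
                      "rc": self.coefficients}).to_csv(path, index=False)


def apply_recovery_coefficient(measured_mean: float, lesion_volume_cc: float,
                               curve: RecoveryCurve) -> float:
    """Correct a PET-measured lesion mean dose: corrected = measured / RC(volume)."""
    if lesion_volume_cc <= 0:
        raise ValueError("lesion volume must be positive")
    return measured_mean / curve(lesion_volume_cc)
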
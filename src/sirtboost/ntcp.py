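"""Lyman-Kutcher-Burman NTCP for radiation-induced liver disease.

The heterogeneous normal-liver dose distribution is reduced to a single
generalized equivalent uniform dose,

    gEUD = ( sum_i v_i * d_i^(1/n) )^n,

with v_i the fractional volumes, and mapped to a complication probability
through the Lyman probit,

    NTCP = Phi( (gEUD - TD50) / (m * TD50) ).

Defaults n = 0.97, m = 0.12, TD50 = 35.4 Gy are the liver-tolerance
parameters for whole-organ RILD; n near 1 makes the liver a strongly
volume-effect ("parallel") organ whose gEUD is close to mean dose.  Physical
dose only — no fraction-size (EQD2/BED) conversion and no combination with
the microsphere dose, for which no validated complication model exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .grids import DoseGrid, StructureMask

__all__ = ["LKBParams", "geud", "ntcp_lkb", "rild_ntcp"]


@dataclass(frozen=True)
class LKBParams:
    """LKB liver parameters: volume effect ``n``, slope ``m``, tolerance ``td50`` (Gy)."""

    n: float = 0.97
    m: float = 0.12
    td50: float = 35.4

    def __post_init__(self) -> None:
        if self.n <= 0 or self.m <= 0 or self.td50 <= 0:
            raise ValueError("LKB parameters must be positive")


def geud(dose: DoseGrid, mask: StructureMask, n: float = 0.97) -> float:
    """Generalized equivalent uniform dose with exponent a = 1/n.

    Power-mean of the masked voxel doses; zero-dose voxels inside the mask
    contribute zero.  Uniform dose D gives gEUD = D for any n; n = 1
    reduces to mean dose.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    dose.geometry.require_match(mask.geometry, what=mask.name or "mask")
    if mask.is_empty():
        raise ValueError(f"mask {mask.name!r} is empty")
    d = dose.values[mask.values]
    a = 1.0 / n
    return float(np.mean(d ** a) ** n)


def ntcp_lkb(geud_value: float, params: LKBParams | None = None) -> float:
    """Lyman probit: standard-normal CDF of t = (gEUD - TD50) / (m * TD50)."""
    params = params or LKBParams()
    t = (geud_value - params.td50) / (params.m * params.td50)
    return float(ndtr(t))


def rild_ntcp(dose: DoseGrid, nlt: StructureMask,
              params: LKBParams | None = None) -> float:
    """RILD complication probability of the normal liver for one plan.

    Composition of :func:`geud` and :func:`ntcp_lkb` on the NLT mask;
    returns a probability in (0, 1) — scale by 100 for reporting.
    """
    params = params or LKBParams()
    return ntcp_lkb(geud(dose, nlt, params.n), params)
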
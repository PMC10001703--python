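"""Logistic tumor-control-probability models for lesion response to SIRT.

A lesion's probability of responding (complete or partial response by
modified RECIST) is modelled as a logistic function of a single SIRT dose
metric d:

    TCP(d) = 1 / (1 + exp(-(b0 + b1 * d)))

Two metrics are in clinical use here: the partial-volume-corrected mean
absorbed dose, and the uncorrected D90 coverage metric.  The published
models are characterised by their 50%-TCP thresholds — 292 Gy for corrected
mean dose, 70 Gy for D90 — and the selection pipeline consumes the
thresholds, not the full curves; :meth:`LogitTCPModel.from_threshold`
builds such threshold-calibrated models with a configurable slope.

Fitting is plain maximum likelihood via Newton scoring (IRLS).  Small
lesion-response datasets frequently exhibit complete separation, which the
fitter detects and flags rather than silently diverging; an optional
Firth-style penalty (Jeffreys prior) gives finite estimates in that case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LogitTCPModel",
    "ResponseRecord",
    "TCPFitResult",
    "SeparationError",
    "tcp",
    "dose_at_tcp",
    "fit_logit",
]

MEAN_DOSE_THRESHOLD_GY = 292.0   # corrected mean dose at 50% TCP
D90_THRESHOLD_GY = 70.0          # uncorrected D90 at 50% TCP


class SeparationError(RuntimeError):
    """Raised when complete separation makes the MLE non-finite."""


@dataclass(frozen=True)
class LogitTCPModel:
    """Logistic dose-response model: intercept ``b0``, slope ``b1`` (per Gy)."""

    b0: float
    b1: float
    metric_name: str = "mean_dose_corrected"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.b0) and np.isfinite(self.b1)):
            raise ValueError("coefficients must be finite")

    def tcp(self, d) -> np.ndarray | float:
        return tcp(self, d)

    def dose_at_tcp(self, p: float) -> float:
        return dose_at_tcp(self, p)

    @classmethod
    def from_threshold(cls, dose_50: float, slope: float = 0.02,
                       metric_name: str = "mean_dose_corrected") -> "LogitTCPModel":
        """Model calibrated only by its 50%-TCP dose, with a chosen slope.

        ``tcp(dose_50) == 0.5`` exactly for any positive slope.
        """
        if slope <= 0:
            raise ValueError("slope must be positive")
        return cls(b0=-slope * dose_50, b1=slope, metric_name=metric_name)

    @classmethod
    def mean_dose_default(cls, slope: float = 0.02) -> "LogitTCPModel":
        """Threshold-calibrated corrected-mean-dose model (50% TCP at 292 Gy)."""
        return cls.from_threshold(MEAN_DOSE_THRESHOLD_GY, slope, "mean_dose_corrected")

    @classmethod
    def d90_default(cls, slope: float = 0.05) -> "LogitTCPModel":
        """Threshold-calibrated uncorrected-D90 model (50% TCP at 70 Gy)."""
        return cls.from_threshold(D90_THRESHOLD_GY, slope, "d90_uncorrected")

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"metric_name": self.metric_name, "b0": self.b0, "b1": self.b1})
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "LogitTCPModel":
        try:
            obj = json.loads(source)
        except (json.JSONDecodeError, TypeError):
            with open(source) as fh:
                obj = json.load(fh)
        return cls(b0=obj["b0"], b1=obj["b1"], metric_name=obj["metric_name"])


@dataclass(frozen=True)
class ResponseRecord:
    """One lesion's dose metric (Gy) and binary mRECIST response."""

    dose_metric: float
    responder: bool
    lesion_id: str = ""

    def __post_init__(self) -> None:
        if self.dose_metric < 0:
            raise ValueError("dose metric must be non-negative")


def tcp(model: LogitTCPModel, d):
    """Response probability at dose ``d`` (Gy); vectorised over ``d``."""
    d = np.asarray(d, dtype=float)
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-(model.b0 + model.b1 * d)))
    return float(out) if out.ndim == 0 else out


def dose_at_tcp(model: LogitTCPModel, p: float) -> float:
    """Inverse of :func:`tcp`: the dose at which TCP equals ``p``."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if model.b1 == 0:
        raise ValueError("slope is zero; model has no dose threshold")
    return (np.log(p / (1.0 - p)) - model.b0) / model.b1


@dataclass
class TCPFitResult:
    """Fitted model plus diagnostics from :func:`fit_logit`."""

    model: LogitTCPModel
    converged: bool
    separation: bool
    n_iter: int
    log_likelihood: float
    bse: np.ndarray = field(default_factory=lambda: np.array([np.nan, np.nan]))

    @property
    def se_b0(self) -> float:
        return float(self.bse[0])

    @property
    def se_b1(self) -> float:
        return float(self.bse[1])

    def se_dose_at_tcp50(self) -> float:
        """Delta-method standard error of the 50%-TCP dose, -b0/b1."""
        b0, b1 = self.model.b0, self.model.b1
        grad = np.array([-1.0 / b1, b0 / b1**2])
        return float(np.sqrt(grad @ self._cov @ grad))

    _cov: np.ndarray = field(default_factory=lambda: np.full((2, 2), np.nan))


def _check_separation(d: np.ndarray, y: np.ndarray) -> bool:
    # univariate logistic: MLE is non-finite iff the classes do not overlap
    lo, hi = d[y == 1], d[y == 0]
    return float(lo.min()) > float(hi.max()) or float(hi.min()) > float(lo.max())


def fit_logit(records: list[ResponseRecord], *, firth: bool = False,
              tol: float = 1e-8, max_iter: int = 100) -> TCPFitResult:
    """Maximum-likelihood logistic regression of response on one dose metric.

    Newton scoring (iteratively reweighted least squares) until the largest
    coefficient change drops below ``tol`` or ``max_iter`` is reached.
    Complete separation is reported through ``TCPFitResult.separation``;
    without ``firth`` the returned coefficients are then the (large, finite)
    iterates at stopping and must not be interpreted as an MLE.  With
    ``firth=True`` a Jeffreys-prior penalty keeps the estimate finite.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    d = np.array([r.dose_metric for r in records], dtype=float)
    y = np.array([float(r.responder) for r in records])
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")

    separated = _check_separation(d, y)
    X = np.column_stack([np.ones_like(d), d])
    beta = np.zeros(2)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        info = X.T @ (X * w[:, None])
        resid = y - p
        if firth:
            # Firth score adjustment: shrink via the hat-matrix leverages
            try:
                info_inv = np.linalg.inv(info)
            except np.linalg.LinAlgError:
                break
            h = np.einsum("ij,jk,ik->i", X * w[:, None], info_inv, X)
            resid = y - p + h * (0.5 - p)
        try:
            step = np.linalg.solve(info, X.T @ resid)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    eta = X @ beta
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-12
    ll = float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    w = p * (1.0 - p)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
        bse = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
        bse = np.array([np.nan, np.nan])

    model = LogitTCPModel(b0=float(beta[0]), b1=float(beta[1]),
                          metric_name="fitted")
    return TCPFitResult(model=model,
                        converged=converged and (firth or not separated),
                        separation=separated, n_iter=it,
                        log_likelihood=ll, bse=bse, _cov=cov)
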
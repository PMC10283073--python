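"""The four logistic response families and their Bernoulli log-likelihood.

All four model the probability of a binary endpoint as a function of the IR
laser power ``x`` (mW), and optionally the normalized target-cell size ``c``
(z-score; c = 0 is a cell of average area, ~3,000 µm² in the calibrated
design):

* ``simple``        p = 1 / (1 + exp(−(a·x + b)))
* ``bounded``       p = lim / (1 + exp(−(a·x + b)))        with 0 < lim ≤ 1
* ``size``          p = 1 / (1 + exp(−(a1·x + a2·c + a3·x·c + b)))
* ``bounded_size``  p = lim·(1 + a4·c) / (1 + exp(−(a1·x + a2·c + a3·x·c + b)))

The bounded families put an upper asymptote (*lim*, optionally modulated
linearly by cell size) below 1 on the response — recombination that plateaus
well short of certainty no matter how hard the cell is driven.  The families
nest: ``bounded_size`` at c = 0 is ``bounded``; ``size`` at c = 0 is
``simple``; ``bounded`` at lim = 1 is ``simple``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .errors import DomainError, UsageError, ValidationError
from .trial_data import ENDPOINTS, SizeStats

__all__ = [
    "SimpleLogisticParams",
    "BoundedLogisticParams",
    "SizeLogisticParams",
    "BoundedSizeParams",
    "ResponseCurve",
    "predict_simple",
    "predict_bounded",
    "predict_size",
    "predict_bounded_size",
    "log_likelihood",
    "LogLikelihood",
    "FAMILIES",
]

FAMILIES = ("simple", "bounded", "size", "bounded_size")

# Linear predictors are clamped here before exponentiation; exp(35) ~ 1.6e15,
# so in-range results are exact to double precision and out-of-range ones
# saturate instead of overflowing.
_ETA_CLAMP = 35.0

# Probability floor/ceiling used inside log-likelihood only (never in predictions),
# so optimizers see finite objectives; the exact-contradiction case is flagged.
_P_EPS = 1e-12


def _sigmoid(eta) -> np.ndarray:
    eta = np.clip(np.asarray(eta, dtype=float), -_ETA_CLAMP, _ETA_CLAMP)
    return 1.0 / (1.0 + np.exp(-eta))


def _check_finite(name: str, *vals: float) -> None:
    if not all(np.isfinite(v) for v in vals):
        raise ValidationError(f"{name} parameters must be finite")


@dataclass(frozen=True)
class SimpleLogisticParams:
    a: float  # slope per mW
    b: float  # intercept

    def __post_init__(self):
        _check_finite("simple", self.a, self.b)


@dataclass(frozen=True)
class BoundedLogisticParams:
    lim: float  # upper limit of probability, in (0, 1]
    a: float
    b: float

    def __post_init__(self):
        _check_finite("bounded", self.lim, self.a, self.b)
        if not 0 < self.lim <= 1:
            raise ValidationError(f"lim must be in (0, 1], got {self.lim}")


@dataclass(frozen=True)
class SizeLogisticParams:
    a1: float  # slope per mW
    a2: float  # slope per unit normalized size
    a3: float  # interaction slope per (mW × unit size)
    b: float

    def __post_init__(self):
        _check_finite("size", self.a1, self.a2, self.a3, self.b)


@dataclass(frozen=True)
class BoundedSizeParams:
    lim: float  # baseline upper limit at average cell size
    a1: float
    a2: float
    a3: float
    a4: float  # linear size modifier of the upper limit
    b: float

    def __post_init__(self):
        _check_finite("bounded_size", self.lim, self.a1, self.a2, self.a3, self.a4, self.b)
        if not 0 < self.lim <= 1:
            raise ValidationError(f"lim must be in (0, 1], got {self.lim}")

    def effective_limit(self, c):
        return self.lim * (1.0 + self.a4 * np.asarray(c, dtype=float))


Params = Union[SimpleLogisticParams, BoundedLogisticParams, SizeLogisticParams, BoundedSizeParams]

_PARAM_TYPES = {
    "simple": SimpleLogisticParams,
    "bounded": BoundedLogisticParams,
    "size": SizeLogisticParams,
    "bounded_size": BoundedSizeParams,
}


def predict_simple(params: SimpleLogisticParams, x):
    """p = 1/(1+exp(−(a·x+b)))."""
    return _sigmoid(params.a * np.asarray(x, dtype=float) + params.b)


def predict_bounded(params: BoundedLogisticParams, x):
    """p = lim/(1+exp(−(a·x+b))); the asymptote is *lim*."""
    return params.lim * _sigmoid(params.a * np.asarray(x, dtype=float) + params.b)


def predict_size(params: SizeLogisticParams, x, c):
    """p = 1/(1+exp(−(a1·x + a2·c + a3·x·c + b)))."""
    x = np.asarray(x, dtype=float)
    c = np.asarray(c, dtype=float)
    return _sigmoid(params.a1 * x + params.a2 * c + params.a3 * x * c + params.b)


def predict_bounded_size(params: BoundedSizeParams, x, c):
    """p = lim·(1+a4·c)/(1+exp(−(a1·x + a2·c + a3·x·c + b))).

    The effective upper limit lim·(1+a4·c) must lie in (0, 1] for every
    supplied c; otherwise a DomainError is raised.
    """
    x = np.asarray(x, dtype=float)
    c = np.asarray(c, dtype=float)
    eff = params.effective_limit(c)
    if np.any(eff <= 0) or np.any(eff > 1):
        raise DomainError(
            f"effective limit lim·(1+a4·c) outside (0, 1] (range "
            f"[{np.min(eff):.4g}, {np.max(eff):.4g}])"
        )
    eta = params.a1 * x + params.a2 * c + params.a3 * x * c + params.b
    return eff * _sigmoid(eta)


@dataclass
class ResponseCurve:
    """A fitted (or specified) probability curve for one endpoint.

    ``size_stats``, when present, lets the curve be evaluated on raw cell
    areas in µm² via :meth:`predict_size_um2`.
    """

    family: str
    params: Params
    endpoint: str
    duration: float
    size_stats: SizeStats | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}")
        if not isinstance(self.params, _PARAM_TYPES[self.family]):
            raise ValidationError(
                f"family {self.family!r} requires {_PARAM_TYPES[self.family].__name__}"
            )
        if self.endpoint not in ENDPOINTS:
            raise ValidationError(f"unknown endpoint {self.endpoint!r}")

    @property
    def requires_size(self) -> bool:
        return self.family in ("size", "bounded_size")

    def predict(self, x, c=0.0):
        """Probability at power ``x`` mW and normalized size ``c`` (ignored by
        size-free families)."""
        if self.family == "simple":
            return predict_simple(self.params, x)
        if self.family == "bounded":
            return predict_bounded(self.params, x)
        if self.family == "size":
            return predict_size(self.params, x, c)
        return predict_bounded_size(self.params, x, c)

    def predict_size_um2(self, x, size_um2):
        """Evaluate on raw cell area (µm²) using the stored normalization."""
        if not self.requires_size:
            return self.predict(x)
        if self.size_stats is None:
            raise UsageError("curve has no size_stats; cannot normalize raw sizes")
        return self.predict(x, self.size_stats.normalize(size_um2))

    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "endpoint": self.endpoint,
            "duration": self.duration,
            "params": asdict(self.params),
        }
        if self.size_stats is not None:
            d["size_stats"] = {"mean": self.size_stats.mean, "sd": self.size_stats.sd}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ResponseCurve":
        fam = d["family"]
        params = _PARAM_TYPES[fam](**d["params"])
        ss = d.get("size_stats")
        return cls(
            family=fam,
            params=params,
            endpoint=d["endpoint"],
            duration=float(d["duration"]),
            size_stats=SizeStats(**ss) if ss else None,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ResponseCurve":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class LogLikelihood:
    """Total Bernoulli log-likelihood; ``flagged`` marks a certain prediction
    contradicted by the data (unclamped value −∞)."""

    value: float
    flagged: bool

    def __float__(self) -> float:
        return self.value


def log_likelihood(curve: ResponseCurve, x, y, c=None) -> LogLikelihood:
    """Σ [y·ln p + (1−y)·ln(1−p)] over trials.

    Probabilities are clipped to [1e-12, 1−1e-12] inside the sum so the result
    stays finite for optimizers; if an *exact* 0/1 prediction contradicts an
    observation the result is flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if curve.requires_size:
        if c is None:
            raise UsageError(f"family {curve.family!r} requires normalized sizes")
        p = curve.predict(x, np.asarray(c, dtype=float))
    else:
        p = curve.predict(x)
    p = np.asarray(p, dtype=float)
    contradiction = bool(np.any((p == 0.0) & (y == 1.0)) or np.any((p == 1.0) & (y == 0.0)))
    pc = np.clip(p, _P_EPS, 1.0 - _P_EPS)
    total = float(np.sum(y * np.log(pc) + (1.0 - y) * np.log1p(-pc)))
    return LogLikelihood(value=total, flagged=contradiction)
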
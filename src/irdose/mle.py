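"""Maximum-likelihood fitting of the unbounded logistic families and the
standard nested likelihood-ratio test.

The likelihood is concave in the coefficients, so a damped Newton iteration
(IRLS with step-halving) with analytic gradient/Hessian converges reliably;
quasi-complete separation is detected and reported, not repaired.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.stats import chi2

from .errors import DegenerateOutcomeError, UsageError, ValidationError
from .models import (
    LogLikelihood,
    ResponseCurve,
    SimpleLogisticParams,
    SizeLogisticParams,
    log_likelihood,
)
from .trial_data import Dataset

__all__ = ["MleFit", "LrtResult", "fit_logistic", "lrt_nested", "fit_by_size_strata", "StratumFit"]

_MAX_ITER = 200
_GRAD_TOL = 1e-8
_SEPARATION_ETA = 30.0  # |linear predictor| beyond this at convergence flags separation


@dataclass
class MleFit:
    """A fitted curve with its maximized log-likelihood and diagnostics."""

    curve: ResponseCurve
    loglik: float
    converged: bool
    n_used: int
    separation_flag: bool = False
    boundary_flag: bool = False  # used by bounded fits when lim hits 1
    stderr: dict[str, float] = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return len(self.curve.params.__dataclass_fields__)

    def to_dict(self) -> dict:
        return {
            "curve": self.curve.to_dict(),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_used": self.n_used,
            "separation_flag": self.separation_flag,
            "boundary_flag": self.boundary_flag,
            "stderr": self.stderr,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass(frozen=True)
class LrtResult:
    """Likelihood-ratio test of nested models: 2Δloglik ~ χ²(df) under the null."""

    statistic: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "df": self.df, "p_value": self.p_value}


def _newton_logistic(
    X: np.ndarray, y: np.ndarray, beta0: np.ndarray | None = None
) -> tuple[np.ndarray, bool, bool, np.ndarray]:
    """Damped Newton ascent of the Bernoulli log-likelihood.

    Returns (beta, converged, separation_flag, stderr).
    """
    n, k = X.shape
    beta = np.zeros(k) if beta0 is None else np.asarray(beta0, dtype=float).copy()

    def loglik(b):
        eta = np.clip(X @ b, -35, 35)
        return float(np.sum(y * eta - np.log1p(np.exp(eta))))

    ll = loglik(beta)
    converged = False
    for _ in range(_MAX_ITER):
        eta = np.clip(X @ beta, -35, 35)
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - p)
        if np.linalg.norm(grad) < _GRAD_TOL:
            converged = True
            break
        w = p * (1.0 - p)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(k), grad)
        except np.linalg.LinAlgError:
            break
        # step-halving keeps the ascent monotone even far from the optimum
        t = 1.0
        for _ in range(50):
            cand = beta + t * step
            ll_new = loglik(cand)
            if ll_new >= ll - 1e-12:
                beta, ll = cand, ll_new
                break
            t *= 0.5
        else:
            break
        if np.linalg.norm(beta) > 1e6:  # diverging coefficients: separation
            break
    eta = X @ beta
    separation = bool(np.max(np.abs(eta)) > _SEPARATION_ETA) or not np.all(
        np.isfinite(beta)
    )
    if separation:
        converged = False
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = p * (1.0 - p)
    H = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    return beta, converged, separation, se


def fit_logistic(data: Dataset, endpoint: str, family: str = "simple") -> MleFit:
    """Fit the ``simple`` (power only) or ``size`` (power × normalized size)
    logistic model for one endpoint by maximum likelihood.

    Records without a normalized size are excluded from ``size`` fits.
    """
    if family not in ("simple", "size"):
        raise UsageError(f"fit_logistic handles families 'simple'/'size', not {family!r}")
    x, y, c = data.endpoint_arrays(endpoint, require_size=(family == "size"))
    if len(x) == 0:
        raise DegenerateOutcomeError("no usable records")
    if y.min() == y.max():
        raise DegenerateOutcomeError(
            f"endpoint {endpoint!r} is constant ({int(y[0])}) — logistic fit undefined"
        )
    durations = {r.duration for r in data.records}
    duration = durations.pop() if len(durations) == 1 else float("nan")

    if family == "simple":
        X = np.column_stack([x, np.ones_like(x)])
        names = ["a", "b"]
    else:
        X = np.column_stack([x, c, x * c, np.ones_like(x)])
        names = ["a1", "a2", "a3", "b"]
    beta, converged, separation, se = _newton_logistic(X, y)

    if family == "simple":
        params = SimpleLogisticParams(a=float(beta[0]), b=float(beta[1]))
    else:
        params = SizeLogisticParams(
            a1=float(beta[0]), a2=float(beta[1]), a3=float(beta[2]), b=float(beta[3])
        )
    curve = ResponseCurve(
        family=family,
        params=params,
        endpoint=endpoint,
        duration=duration,
        size_stats=data.size_stats,
    )
    ll = log_likelihood(curve, x, y, c)
    return MleFit(
        curve=curve,
        loglik=ll.value,
        converged=converged,
        n_used=len(x),
        separation_flag=separation,
        stderr=dict(zip(names, (float(s) for s in se))),
    )


_NESTINGS = {("size", "simple"): 2, ("bounded_size", "bounded"): 3, ("bounded", "simple"): 1}


def lrt_nested(full: MleFit, reduced: MleFit) -> LrtResult:
    """Standard likelihood-ratio test between nested fits on the same data.

    The statistic 2·(ℓ_full − ℓ_reduced) is clipped at zero; df is the
    parameter-count difference (2 for size vs simple).
    """
    key = (full.curve.family, reduced.curve.family)
    if key not in _NESTINGS:
        raise UsageError(
            f"{reduced.curve.family!r} is not nested in {full.curve.family!r}"
        )
    if full.curve.endpoint != reduced.curve.endpoint:
        raise UsageError("fits are for different endpoints")
    if full.n_used != reduced.n_used:
        raise UsageError("fits use different numbers of records")
    df = _NESTINGS[key]
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -1e-6:
        raise ValidationError(
            f"full model has materially lower likelihood ({stat=:.3g}); check convergence"
        )
    stat = max(stat, 0.0)
    return LrtResult(statistic=stat, df=df, p_value=float(chi2.sf(stat, df)))


@dataclass
class StratumFit:
    """Result of one size stratum: a fit, or a recorded reason for skipping."""

    label: str
    fit: MleFit | None
    skipped: bool = False
    reason: str = ""


def fit_by_size_strata(
    data: Dataset,
    endpoint: str,
    strata: Sequence[tuple[str, Callable[[float], bool]]],
    min_records: int = 10,
) -> list[StratumFit]:
    """Refit the simple logistic on cell-size-filtered subsets.

    ``strata`` is a list of (label, predicate-on-size-µm²).  A stratum with
    fewer than ``min_records`` sized records, or a constant endpoint, is
    marked skipped with a reason rather than failing the whole analysis.
    """
    out: list[StratumFit] = []
    for label, keep in strata:
        recs = [r for r in data.records if r.cell_size is not None and keep(r.cell_size)]
        if len(recs) < min_records:
            out.append(
                StratumFit(label, None, skipped=True, reason=f"only {len(recs)} records")
            )
            continue
        sub = Dataset(records=recs, size_stats=data.size_stats)
        try:
            fit = fit_logistic(sub, endpoint, family="simple")
        except DegenerateOutcomeError as exc:
            out.append(StratumFit(label, None, skipped=True, reason=str(exc)))
            continue
        out.append(StratumFit(label, fit))
    return out
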
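"""Composite-probability calculus over fitted curves and laser-power selection.

Two practical objectives are optimized over laser power x:

* **condition 1** — recombination in the single target cell and nowhere else:
  maximize P_target(x) · (1 − P_neighboring(x));
* **condition 2** — recombination somewhere local without any cell death:
  maximize P_local(x) · (1 − P_death(x)).

When no directly fitted P_local curve is available it is composed from
P_target and P_neighboring under the independence assumption
P_local ≈ P_t + P_n − P_t·P_n; ``local_consistency_check`` quantifies how far
the directly fitted curve departs from that composition.  ``raising_point``
inverts a monotone curve at a probability threshold (default 10%), the power
at which an endpoint starts to matter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .errors import UsageError
from .models import ResponseCurve

__all__ = [
    "CurveSet",
    "DoseRecommendation",
    "RaisingPoint",
    "compose_local",
    "condition_score",
    "optimize_condition",
    "raising_point",
    "local_consistency_check",
    "size_conditional_recommendation",
]


@dataclass
class CurveSet:
    """The four endpoint curves for one irradiation duration.

    ``local`` may be omitted, in which case it is composed on demand from
    ``target`` and ``neighboring``.
    """

    target: ResponseCurve
    neighboring: ResponseCurve
    death: ResponseCurve
    local: ResponseCurve | None = None

    def __post_init__(self):
        slots = {"target": self.target, "neighboring": self.neighboring, "death": self.death}
        if self.local is not None:
            slots["local"] = self.local
        for slot, curve in slots.items():
            if curve.endpoint != slot:
                raise UsageError(f"curve in slot {slot!r} is fitted for {curve.endpoint!r}")
        durations = {c.duration for c in slots.values()}
        if len(durations) > 1:
            raise UsageError(f"curves have mixed durations {sorted(durations)}")

    @property
    def duration(self) -> float:
        return self.target.duration

    def p_local(self, x, c=0.0):
        if self.local is not None:
            return self.local.predict(x, c)
        return compose_local(self.target.predict(x, c), self.neighboring.predict(x, c))


@dataclass
class DoseRecommendation:
    """An optimal laser power for one condition, with the score it achieves."""

    condition: int
    optimal_power: float  # mW, full precision
    achieved_score: float
    grid_step: float
    c: float = 0.0  # normalized size at which evaluated (0 = average cell)
    degenerate: bool = False  # score identically 0 over the searched range
    extrapolation_warning: bool = False

    @property
    def optimal_power_rounded(self) -> float:
        """Power rounded to 0.1 mW for reporting."""
        return round(self.optimal_power, 1)

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "optimal_power_mw": self.optimal_power,
            "optimal_power_mw_rounded": self.optimal_power_rounded,
            "achieved_score": self.achieved_score,
            "grid_step_mw": self.grid_step,
            "c": self.c,
            "degenerate": self.degenerate,
            "extrapolation_warning": self.extrapolation_warning,
        }


@dataclass
class RaisingPoint:
    """The power at which a curve reaches a probability threshold."""

    endpoint: str
    threshold: float
    power: float | None  # None when unreachable within the searched range
    unreachable: bool = False
    reason: str = ""

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "threshold": self.threshold,
            "power_mw": self.power,
            "unreachable": self.unreachable,
            "reason": self.reason,
        }


def compose_local(p_t, p_n):
    """Union of independent events: p_t + p_n − p_t·p_n."""
    p_t = np.asarray(p_t, dtype=float)
    p_n = np.asarray(p_n, dtype=float)
    return p_t + p_n - p_t * p_n


def condition_score(curves: CurveSet, condition: int, x, c: float = 0.0):
    """Score of one condition at power ``x`` (and normalized size ``c``)."""
    if condition == 1:
        return curves.target.predict(x, c) * (1.0 - curves.neighboring.predict(x, c))
    if condition == 2:
        return curves.p_local(x, c) * (1.0 - curves.death.predict(x, c))
    raise UsageError(f"condition must be 1 or 2, got {condition!r}")


def optimize_condition(
    curves: CurveSet,
    condition: int,
    power_range: tuple[float, float],
    c: float = 0.0,
    grid_step: float = 0.01,
) -> DoseRecommendation:
    """Maximize a condition score over a power range.

    Scores are evaluated on a ``grid_step``-mW grid (ties going to the lowest
    power), then the best grid cell is refined by bounded golden-section
    search.  A score that is identically zero over the range is flagged
    degenerate and the lower bound returned.
    """
    lo, hi = float(power_range[0]), float(power_range[1])
    if not lo < hi:
        raise UsageError(f"power range must satisfy lo < hi, got ({lo}, {hi})")
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    grid[-1] = min(grid[-1], hi)
    scores = np.asarray(condition_score(curves, condition, grid, c), dtype=float)
    if np.all(scores == 0.0):
        return DoseRecommendation(
            condition=condition,
            optimal_power=lo,
            achieved_score=0.0,
            grid_step=grid_step,
            c=c,
            degenerate=True,
        )
    best = int(np.argmax(scores))  # first max: ties break toward the lowest power
    x_best, s_best = float(grid[best]), float(scores[best])
    blo = max(lo, x_best - grid_step)
    bhi = min(hi, x_best + grid_step)
    res = minimize_scalar(
        lambda x: -float(condition_score(curves, condition, x, c)),
        bounds=(blo, bhi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if -res.fun > s_best:
        x_best, s_best = float(res.x), float(-res.fun)
    return DoseRecommendation(
        condition=condition,
        optimal_power=x_best,
        achieved_score=s_best,
        grid_step=grid_step,
        c=c,
    )


def _effective_slope(curve: ResponseCurve, c: float) -> float:
    p = curve.params
    if curve.family in ("simple", "bounded"):
        return p.a
    return p.a1 + p.a3 * c


def raising_point(
    curve: ResponseCurve,
    threshold: float = 0.10,
    power_range: tuple[float, float] = (0.0, 50.0),
    c: float = 0.0,
) -> RaisingPoint:
    """Solve curve(x) = threshold by bisection on a monotone-increasing curve.

    Unreachable when the curve stays below the threshold over the whole range
    (e.g. a bounded curve whose asymptote is below it) or is already above it
    at the lower bound.
    """
    if _effective_slope(curve, c) <= 0:
        raise UsageError("raising_point requires a curve increasing in power")
    lo, hi = float(power_range[0]), float(power_range[1])
    f = lambda x: float(curve.predict(x, c)) - threshold
    flo, fhi = f(lo), f(hi)
    if fhi < 0:
        return RaisingPoint(
            curve.endpoint, threshold, None, unreachable=True,
            reason=f"curve stays below {threshold} over [{lo}, {hi}] mW",
        )
    if flo > 0:
        return RaisingPoint(
            curve.endpoint, threshold, None, unreachable=True,
            reason=f"curve already above {threshold} at {lo} mW",
        )
    if flo == 0.0:
        return RaisingPoint(curve.endpoint, threshold, lo)
    x = float(brentq(f, lo, hi, xtol=1e-12))
    return RaisingPoint(curve.endpoint, threshold, x)


def local_consistency_check(
    direct_local: ResponseCurve,
    curves: CurveSet,
    power_range: tuple[float, float],
    c: float = 0.0,
    grid_step: float = 0.1,
) -> float:
    """Maximum |direct P_local − composed P_local| over a power grid.

    Small values support the independence approximation behind
    :func:`compose_local`; positive correlation between target and neighbor
    events inflates it.
    """
    if direct_local.endpoint != "local":
        raise UsageError("direct_local must be fitted on the 'local' endpoint")
    lo, hi = float(power_range[0]), float(power_range[1])
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    direct = np.asarray(direct_local.predict(grid, c), dtype=float)
    composed = compose_local(
        curves.target.predict(grid, c), curves.neighboring.predict(grid, c)
    )
    return float(np.max(np.abs(direct - composed)))


def size_conditional_recommendation(
    curves: CurveSet,
    condition: int,
    power_range: tuple[float, float],
    c_values: Sequence[float],
    grid_step: float = 0.01,
    c_warn: float = 2.0,
) -> list[DoseRecommendation]:
    """Optimal power per normalized cell size, from size-aware curves.

    Sizes more than ``c_warn`` normalized units from the average cell carry an
    extrapolation warning (the fit is unsupported that far out).
    """
    for slot in ("target", "neighboring", "death"):
        if not getattr(curves, slot).requires_size:
            raise UsageError(f"{slot} curve is not a size-aware family")
    if curves.local is not None and not curves.local.requires_size:
        raise UsageError("local curve is not a size-aware family")
    out = []
    for c in c_values:
        rec = optimize_condition(curves, condition, power_range, c=float(c), grid_step=grid_step)
        rec.extrapolation_warning = abs(float(c)) > c_warn
        out.append(rec)
    return out
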
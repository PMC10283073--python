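"""Synthetic irradiation-trial generator.

Emulates the statistical structure of the root-irradiation experiments: the
published power-bin design with its per-bin trial counts, a lognormal
target-cell-size distribution calibrated to a 3,000 µm² mean, and categorical
outcomes produced by drawing the three latent binary events — target VENUS
(T), neighbor VENUS (N), cell death (D) — from user-specified true endpoint
curves and collapsing them to the six observable categories.

T, N and D are independent by default, exactly the assumption the composed
P_local formula makes.  A dependence knob (Gaussian copula on a shared latent
"heat dose") exists solely to stress-test that assumption.

The (T, N, D) → category map is lossy in one documented way: any combination
with D = 1 and at least one VENUS event collapses into DEATH_AND_EXPRESSION,
because the observable taxonomy has no finer death-with-expression classes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .errors import DomainError, UsageError
from .models import (
    BoundedLogisticParams,
    BoundedSizeParams,
    ResponseCurve,
    SimpleLogisticParams,
    SizeLogisticParams,
)
from .trial_data import Dataset, OutcomeCategory, SizeStats, TrialRecord

__all__ = [
    "DesignSpec",
    "TruthSpec",
    "replicate_design",
    "sample_cell_sizes",
    "simulate_trials",
    "simulate_endpoint_trials",
    "leaf_fixture",
    "default_truth",
    "SIZE_MEAN_UM2",
    "SIZE_CV",
]

#: Calibrated cell-size distribution: mean 3,000 µm², coefficient of variation 0.5.
SIZE_MEAN_UM2 = 3000.0
SIZE_CV = 0.5
# lognormal(meanlog, sdlog) with mean m and CV v: sdlog² = ln(1+v²), here ln 1.25
_SDLOG = math.sqrt(math.log(1.0 + SIZE_CV**2))
_MEANLOG = math.log(SIZE_MEAN_UM2) - 0.5 * math.log(1.0 + SIZE_CV**2)

#: Published power-bin designs: (lo mW, hi mW, n trials) per bin.
_DESIGNS = {
    1: [(10.0, 16.0, 20), (17.0, 19.0, 30), (20.0, 24.0, 40)],
    60: [(5.5, 8.0, 50), (8.5, 11.0, 40), (11.5, 14.0, 30), (15.0, 20.0, 9)],
}

_LATTICE_STEP = 0.5  # powers are placed on a 0.5-mW lattice within each bin


@dataclass(frozen=True)
class DesignSpec:
    """An irradiation design: duration and per-bin (lo, hi, n) trial counts."""

    duration: float
    bins: tuple[tuple[float, float, int], ...]
    lattice_step: float = _LATTICE_STEP

    def __post_init__(self):
        prev_hi = -math.inf
        for lo, hi, n in self.bins:
            if lo > hi or n < 1:
                raise UsageError(f"bad bin ({lo}, {hi}, {n})")
            if lo <= prev_hi:
                raise UsageError("bins must be non-overlapping and increasing")
            prev_hi = hi

    @property
    def n_total(self) -> int:
        return sum(n for _, _, n in self.bins)

    def bin_counts(self) -> tuple[int, ...]:
        return tuple(n for _, _, n in self.bins)

    def powers(self) -> np.ndarray:
        """Trial powers: lattice points within each bin, cycled round-robin."""
        out: list[float] = []
        for lo, hi, n in self.bins:
            k = int(round((hi - lo) / self.lattice_step)) + 1
            lattice = [round(lo + i * self.lattice_step, 10) for i in range(k)]
            out.extend(lattice[i % len(lattice)] for i in range(n))
        return np.array(out, dtype=float)

    def inflate(self, factor: int) -> "DesignSpec":
        """Same bins with every per-bin n multiplied by ``factor``."""
        return DesignSpec(
            duration=self.duration,
            bins=tuple((lo, hi, n * factor) for lo, hi, n in self.bins),
            lattice_step=self.lattice_step,
        )


def replicate_design(duration: int) -> DesignSpec:
    """The published power-bin design for 1-s or 60-s irradiation."""
    if duration not in _DESIGNS:
        raise DomainError(f"no published design for duration {duration!r} s (use 1 or 60)")
    return DesignSpec(duration=float(duration), bins=tuple(_DESIGNS[duration]))


@dataclass
class TruthSpec:
    """True endpoint curves and size distribution for the generator.

    ``dependence`` is the Gaussian-copula correlation between the latent T, N
    and D events (0 = independent).  ``size_mean``/``size_cv`` parameterize the
    lognormal cell-size distribution; the theoretical mean/SD are also used to
    normalize sizes when the truth curves are size-aware.
    """

    target: ResponseCurve
    neighboring: ResponseCurve
    death: ResponseCurve
    size_mean: float = SIZE_MEAN_UM2
    size_cv: float = SIZE_CV
    dependence: float = 0.0

    def __post_init__(self):
        for slot in ("target", "neighboring", "death"):
            curve = getattr(self, slot)
            if curve.endpoint != slot:
                raise UsageError(f"truth curve in slot {slot!r} is for {curve.endpoint!r}")
        if not 0.0 <= self.dependence < 1.0:
            raise UsageError("dependence must be in [0, 1)")

    @property
    def requires_size(self) -> bool:
        return any(
            getattr(self, s).requires_size for s in ("target", "neighboring", "death")
        )

    @property
    def size_stats(self) -> SizeStats:
        return SizeStats(mean=self.size_mean, sd=self.size_cv * self.size_mean)

    def to_dict(self) -> dict:
        return {
            "target": self.target.to_dict(),
            "neighboring": self.neighboring.to_dict(),
            "death": self.death.to_dict(),
            "size_mean": self.size_mean,
            "size_cv": self.size_cv,
            "dependence": self.dependence,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "TruthSpec":
        return cls(
            target=ResponseCurve.from_dict(d["target"]),
            neighboring=ResponseCurve.from_dict(d["neighboring"]),
            death=ResponseCurve.from_dict(d["death"]),
            size_mean=d.get("size_mean", SIZE_MEAN_UM2),
            size_cv=d.get("size_cv", SIZE_CV),
            dependence=d.get("dependence", 0.0),
        )


def default_truth(duration: int, size_effect: bool = False) -> TruthSpec:
    """Default true curves per duration, mirroring the qualitative picture of
    the root experiments.

    60 s: the target curve plateaus at lim = 0.40 rising near 8 mW; neighbor
    expression and death follow at higher powers, with death exceeding 50%
    above ~17 mW.  1 s: all three curves are shallower and their 10% raising
    points are closer together, with death exceeding 50% above ~24 mW.

    With ``size_effect`` the curves gain a negative normalized-size main
    effect (smaller cells respond at lower power, every probability rising as
    cell size falls) and, for the bounded target, a small positive plateau
    shift for smaller cells.  The size-free variant is the average-cell
    (c = 0) section of the sized one, matching the reading that size-ignored
    models describe a cell of average (~3,000 µm²) size.
    """
    if duration == 60:
        if size_effect:
            target = ResponseCurve(
                "bounded_size",
                BoundedSizeParams(lim=0.40, a1=1.5, a2=-0.6, a3=0.0, a4=-0.05, b=-12.0),
                "target",
                60.0,
            )
            neighboring = ResponseCurve(
                "size", SizeLogisticParams(a1=0.9, a2=-0.6, a3=0.0, b=-11.0), "neighboring", 60.0
            )
            death = ResponseCurve(
                "size", SizeLogisticParams(a1=0.8, a2=-0.6, a3=0.0, b=-13.5), "death", 60.0
            )
        else:
            target = ResponseCurve(
                "bounded", BoundedLogisticParams(lim=0.40, a=1.5, b=-12.0), "target", 60.0
            )
            neighboring = ResponseCurve(
                "simple", SimpleLogisticParams(a=0.9, b=-11.0), "neighboring", 60.0
            )
            death = ResponseCurve(
                "simple", SimpleLogisticParams(a=0.8, b=-13.5), "death", 60.0
            )
        return TruthSpec(target=target, neighboring=neighboring, death=death)
    if duration == 1:
        if size_effect:
            target = ResponseCurve(
                "size", SizeLogisticParams(a1=0.55, a2=-0.5, a3=0.0, b=-11.0), "target", 1.0
            )
            neighboring = ResponseCurve(
                "size", SizeLogisticParams(a1=0.5, a2=-0.5, a3=0.0, b=-11.5), "neighboring", 1.0
            )
            death = ResponseCurve(
                "size", SizeLogisticParams(a1=0.45, a2=-0.5, a3=0.0, b=-10.8), "death", 1.0
            )
        else:
            target = ResponseCurve(
                "simple", SimpleLogisticParams(a=0.55, b=-11.0), "target", 1.0
            )
            neighboring = ResponseCurve(
                "simple", SimpleLogisticParams(a=0.5, b=-11.5), "neighboring", 1.0
            )
            death = ResponseCurve(
                "simple", SimpleLogisticParams(a=0.45, b=-10.8), "death", 1.0
            )
        return TruthSpec(target=target, neighboring=neighboring, death=death)
    raise DomainError(f"no default truth for duration {duration!r} s")


def sample_cell_sizes(n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Lognormal cell areas (µm²) with mean 3,000 and CV 0.5; seeded."""
    if n < 1:
        raise UsageError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.lognormal(mean=_MEANLOG, sigma=_SDLOG, size=n)


def _categorize(t: int, n: int, d: int) -> OutcomeCategory:
    if d:
        if t or n:
            return OutcomeCategory.DEATH_AND_EXPRESSION
        return OutcomeCategory.DEATH_TARGET
    if t and n:
        return OutcomeCategory.TARGET_AND_NEIGHBOR
    if t:
        return OutcomeCategory.TARGET_ONLY
    if n:
        return OutcomeCategory.NEIGHBOR_ONLY
    return OutcomeCategory.NONE


def simulate_trials(
    design: DesignSpec,
    truth: TruthSpec,
    seed: int,
    tissue: str = "root epidermis",
) -> Dataset:
    """Draw one synthetic dataset from a design and true curves.

    Per trial: a cell size is drawn, the three event probabilities are
    evaluated at the trial's power (and normalized size when the truth is
    size-aware), the latent events are drawn — independently, or through a
    Gaussian copula with correlation ``truth.dependence`` — and collapsed to
    an outcome category.  Identical (design, truth, seed) gives a
    byte-identical dataset.
    """
    rng = np.random.default_rng(seed)
    x = design.powers()
    n = len(x)
    sizes = sample_cell_sizes(n, rng)
    stats = truth.size_stats
    c = stats.normalize(sizes)

    def prob(curve: ResponseCurve) -> np.ndarray:
        return np.asarray(curve.predict(x, c if curve.requires_size else 0.0), dtype=float)

    p = np.column_stack([prob(truth.target), prob(truth.neighboring), prob(truth.death)])
    if truth.dependence == 0.0:
        events = rng.random((n, 3)) < p
    else:
        rho = truth.dependence
        shared = rng.standard_normal((n, 1))
        z = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * rng.standard_normal((n, 3))
        # event fires when its latent Gaussian falls below the p-quantile
        events = z < norm.ppf(p)

    records = []
    for i in range(n):
        t, nb, d = (int(v) for v in events[i])
        records.append(
            TrialRecord(
                trial_id=f"sim-{design.duration:g}s-{i + 1:05d}",
                power=float(x[i]),
                duration=design.duration,
                cell_size=float(sizes[i]),
                tissue=tissue,
                outcome=_categorize(t, nb, d),
            )
        )
    return Dataset(records=records)


_ENDPOINT_CATEGORY = {
    "target": OutcomeCategory.TARGET_ONLY,
    "neighboring": OutcomeCategory.NEIGHBOR_ONLY,
    "local": OutcomeCategory.TARGET_ONLY,
    "death": OutcomeCategory.DEATH_TARGET,
}


def simulate_endpoint_trials(
    powers: Sequence[float] | np.ndarray,
    curve: ResponseCurve,
    seed: int,
    size_stats: SizeStats | None = None,
) -> Dataset:
    """Bernoulli draws of a single endpoint directly from its curve.

    Unlike :func:`simulate_trials` there is no categorical collapse: the
    endpoint bit of every record equals the latent draw exactly, which makes
    this the generative route for single-curve parameter-recovery checks.

    For size-aware curves, cell sizes are drawn from the calibrated lognormal
    (``size_stats`` defaults to its theoretical mean/SD) and, for a
    bounded-size curve, clipped to the normalized-size interval on which the
    effective limit lim·(1+a4·c) stays inside (0, 1].
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(powers, dtype=float)
    n = len(x)
    cat_hit = _ENDPOINT_CATEGORY[curve.endpoint]
    if curve.requires_size:
        stats = size_stats or SizeStats(mean=SIZE_MEAN_UM2, sd=SIZE_CV * SIZE_MEAN_UM2)
        sizes = sample_cell_sizes(n, rng)
        c = stats.normalize(sizes)
        if curve.family == "bounded_size" and curve.params.a4 != 0.0:
            lim, a4 = curve.params.lim, curve.params.a4
            bounds = sorted(((1.0 / lim - 1.0) / a4, -1.0 / a4))
            c = np.clip(c, bounds[0] + 1e-6, bounds[1] - 1e-6)
            sizes = stats.denormalize(c)
        p = np.asarray(curve.predict(x, c), dtype=float)
    else:
        stats = None
        sizes = c = None
        p = np.asarray(curve.predict(x), dtype=float)
    y = rng.random(n) < p
    records = []
    for i in range(n):
        records.append(
            TrialRecord(
                trial_id=f"ep-{curve.endpoint}-{i + 1:05d}",
                power=float(x[i]),
                duration=curve.duration,
                cell_size=float(sizes[i]) if sizes is not None else None,
                c=float(c[i]) if c is not None else None,
                tissue="root epidermis",
                outcome=cat_hit if y[i] else OutcomeCategory.NONE,
            )
        )
    return Dataset(records=records, size_stats=stats)


def leaf_fixture() -> Dataset:
    """The in-study leaf worked example: 20 irradiations of leaf mesophyll
    cells at the root-optimized 60-s condition, of which exactly 4 produced
    single-cell VENUS expression (TARGET_ONLY) and 16 produced nothing.

    Deterministic — no randomness; cell sizes were not measured.
    """
    records = []
    for i in range(20):
        records.append(
            TrialRecord(
                trial_id=f"leaf-60s-{i + 1:02d}",
                power=8.5,
                duration=60.0,
                cell_size=None,
                tissue="leaf mesophyll",
                outcome=OutcomeCategory.TARGET_ONLY if i < 4 else OutcomeCategory.NONE,
            )
        )
    return Dataset(records=records)
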
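"""Irradiation-trial data model and I/O.

A *trial* is one attempt at heating a single cell with the IR laser: the
emitted laser power (mW), the irradiation duration (s), the measured target
cell area (µm², optional), a tissue label, and one of six categorical
outcomes describing where VENUS (recombination reporter) and PI (cell-death
stain) fluorescence appeared afterwards.

The statistical pipeline works on four binary *endpoints* derived from the
category: ``target`` (VENUS in the irradiated cell), ``neighboring`` (VENUS in
at least one other cell), ``local`` (either), ``death`` (any PI-positive
cell).  The mapping is the marginal reading: each VENUS bit records whether
that compartment fluoresced, regardless of the other, which is the only
reading under which the union identity ``local = target OR neighboring``
holds.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .errors import (
    CoverageError,
    DegenerateVarianceError,
    TrialParseError,
    ValidationError,
)

__all__ = [
    "OutcomeCategory",
    "EndpointVector",
    "TrialRecord",
    "SizeStats",
    "Dataset",
    "ENDPOINTS",
    "encode_endpoints",
    "read_trials",
    "write_trials",
    "normalize_cell_size",
    "bin_frequencies",
    "proportion_estimate",
    "ProportionEstimate",
]

#: The four binary endpoints every analysis is phrased in terms of.
ENDPOINTS = ("target", "neighboring", "local", "death")

CSV_HEADER = ["trial_id", "power_mw", "duration_s", "cell_size_um2", "tissue", "outcome"]


class OutcomeCategory(str, enum.Enum):
    """The six observable fluorescence patterns after irradiation."""

    NONE = "NONE"  # no fluorescence anywhere
    TARGET_ONLY = "TARGET_ONLY"  # VENUS only in the irradiated cell
    TARGET_AND_NEIGHBOR = "TARGET_AND_NEIGHBOR"  # VENUS in irradiated and other cells
    NEIGHBOR_ONLY = "NEIGHBOR_ONLY"  # VENUS only in non-irradiated cell(s)
    DEATH_TARGET = "DEATH_TARGET"  # PI (death) only, in the irradiated cell
    DEATH_AND_EXPRESSION = "DEATH_AND_EXPRESSION"  # PI and VENUS, target and others


# (target, neighboring, death) bits per category; local is derived as target|neighboring.
_ENDPOINT_BITS: dict[OutcomeCategory, tuple[int, int, int]] = {
    OutcomeCategory.NONE: (0, 0, 0),
    OutcomeCategory.TARGET_ONLY: (1, 0, 0),
    OutcomeCategory.TARGET_AND_NEIGHBOR: (1, 1, 0),
    OutcomeCategory.NEIGHBOR_ONLY: (0, 1, 0),
    OutcomeCategory.DEATH_TARGET: (0, 0, 1),
    OutcomeCategory.DEATH_AND_EXPRESSION: (1, 1, 1),
}


@dataclass(frozen=True)
class EndpointVector:
    """Binary event indicators for one trial."""

    target: int
    neighboring: int
    local: int
    death: int

    def __post_init__(self) -> None:
        for name in ENDPOINTS:
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValidationError(f"endpoint {name!r} must be 0 or 1, got {v!r}")
        if self.local != (self.target | self.neighboring):
            raise ValidationError("local must equal target OR neighboring")


def encode_endpoints(outcome: OutcomeCategory) -> EndpointVector:
    """Map a categorical outcome to its four binary endpoints."""
    t, n, d = _ENDPOINT_BITS[OutcomeCategory(outcome)]
    return EndpointVector(target=t, neighboring=n, local=t | n, death=d)


@dataclass(frozen=True)
class TrialRecord:
    """One irradiation attempt."""

    trial_id: str
    power: float  # emitted laser power, mW
    duration: float  # irradiation time, s
    outcome: OutcomeCategory
    cell_size: float | None = None  # target-cell area, µm²; None = not measured
    tissue: str = ""
    c: float | None = None  # normalized cell size, set by normalize_cell_size

    def __post_init__(self) -> None:
        if not (self.power > 0 and math.isfinite(self.power)):
            raise ValidationError(f"power must be > 0, got {self.power!r}")
        if not (self.duration > 0 and math.isfinite(self.duration)):
            raise ValidationError(f"duration must be > 0, got {self.duration!r}")
        if self.cell_size is not None and not (
            self.cell_size > 0 and math.isfinite(self.cell_size)
        ):
            raise ValidationError(f"cell_size must be > 0, got {self.cell_size!r}")

    @property
    def endpoints(self) -> EndpointVector:
        return encode_endpoints(self.outcome)


@dataclass(frozen=True)
class SizeStats:
    """Mean and sample SD (n−1) of cell size, recorded when z-scoring is applied."""

    mean: float
    sd: float

    def normalize(self, size):
        return (np.asarray(size, dtype=float) - self.mean) / self.sd

    def denormalize(self, c):
        return np.asarray(c, dtype=float) * self.sd + self.mean


@dataclass
class Dataset:
    """An ordered collection of trials, optionally carrying size-normalization stats."""

    records: list[TrialRecord] = field(default_factory=list)
    size_stats: SizeStats | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Flat view with endpoint columns, one row per trial."""
        rows = []
        for r in self.records:
            ev = r.endpoints
            rows.append(
                {
                    "trial_id": r.trial_id,
                    "power_mw": r.power,
                    "duration_s": r.duration,
                    "cell_size_um2": r.cell_size,
                    "tissue": r.tissue,
                    "outcome": r.outcome.value,
                    "c": r.c,
                    "target": ev.target,
                    "neighboring": ev.neighboring,
                    "local": ev.local,
                    "death": ev.death,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "trial_id",
                "power_mw",
                "duration_s",
                "cell_size_um2",
                "tissue",
                "outcome",
                "c",
                *ENDPOINTS,
            ],
        )

    def endpoint_arrays(
        self, endpoint: str, require_size: bool = False
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
        """Return (power, y, c) arrays for one endpoint.

        With ``require_size`` the records lacking a normalized size are dropped
        and ``c`` is returned; otherwise all records are used and ``c`` is None.
        """
        if endpoint not in ENDPOINTS:
            raise ValidationError(f"unknown endpoint {endpoint!r}")
        recs = self.records
        if require_size:
            recs = [r for r in recs if r.c is not None]
        x = np.array([r.power for r in recs], dtype=float)
        y = np.array([getattr(r.endpoints, endpoint) for r in recs], dtype=float)
        c = (
            np.array([r.c for r in recs], dtype=float)
            if require_size
            else None
        )
        return x, y, c


def _parse_row(row: dict[str, str], rownum: int) -> TrialRecord:
    def num(fieldname: str, allow_empty: bool = False) -> float | None:
        raw = (row.get(fieldname) or "").strip()
        if raw == "":
            if allow_empty:
                return None
            raise TrialParseError(rownum, f"missing value for {fieldname}")
        try:
            return float(raw)
        except ValueError as exc:
            raise TrialParseError(rownum, f"bad number {raw!r} in {fieldname}") from exc

    outcome_raw = (row.get("outcome") or "").strip()
    try:
        outcome = OutcomeCategory(outcome_raw)
    except ValueError as exc:
        raise ValidationError(
            f"row {rownum}: unknown outcome category {outcome_raw!r}"
        ) from exc
    try:
        return TrialRecord(
            trial_id=(row.get("trial_id") or "").strip(),
            power=num("power_mw"),
            duration=num("duration_s"),
            cell_size=num("cell_size_um2", allow_empty=True),
            tissue=(row.get("tissue") or "").strip(),
            outcome=outcome,
        )
    except ValidationError as exc:
        raise TrialParseError(rownum, str(exc)) from exc


def read_trials(path: str | Path) -> Dataset:
    """Read a trials CSV (schema: ``trial_id,power_mw,duration_s,cell_size_um2,tissue,outcome``)."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != CSV_HEADER:
            raise TrialParseError(1, f"header must be {','.join(CSV_HEADER)}")
        records = [_parse_row(row, i) for i, row in enumerate(reader, start=2)]
    return Dataset(records=records)


def _fmt(v: float | None) -> str:
    if v is None:
        return ""
    return repr(float(v))


def write_trials(dataset: Dataset, path: str | Path) -> None:
    """Write a Dataset to CSV; ``read_trials`` round-trips it losslessly."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for r in dataset.records:
            writer.writerow(
                [r.trial_id, _fmt(r.power), _fmt(r.duration), _fmt(r.cell_size), r.tissue, r.outcome.value]
            )


def normalize_cell_size(dataset: Dataset) -> Dataset:
    """Z-score cell sizes: c = (size − mean)/sd with sample SD (n−1 denominator).

    Records without a measured size keep ``c`` absent.  The mean/SD are stored in
    ``size_stats`` so the transform can be inverted and applied to new cells.
    """
    sizes = np.array([r.cell_size for r in dataset.records if r.cell_size is not None])
    if sizes.size < 2:
        raise DegenerateVarianceError("need at least two measured cell sizes")
    mean = float(np.mean(sizes))
    sd = float(np.std(sizes, ddof=1))
    if sd == 0.0:
        raise DegenerateVarianceError("all measured cell sizes are identical")
    stats = SizeStats(mean=mean, sd=sd)
    new_records = [
        replace(r, c=float(stats.normalize(r.cell_size))) if r.cell_size is not None else r
        for r in dataset.records
    ]
    return Dataset(records=new_records, size_stats=stats)


def bin_frequencies(dataset: Dataset, bin_edges: Sequence[float]) -> pd.DataFrame:
    """Per-power-bin counts and proportions of the six outcome categories.

    Bins are half-open ``[lo, hi)`` except the last, which is closed.  Every
    record must fall in some bin.  Empty bins get count 0 and NaN proportions.
    """
    edges = list(bin_edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValidationError("bin_edges must be strictly increasing, length >= 2")
    cats = [c.value for c in OutcomeCategory]
    nbins = len(edges) - 1
    counts = np.zeros((nbins, len(cats)), dtype=int)
    for r in dataset.records:
        idx = None
        for i in range(nbins):
            lo, hi = edges[i], edges[i + 1]
            if (lo <= r.power < hi) or (i == nbins - 1 and r.power == hi):
                idx = i
                break
        if idx is None:
            raise CoverageError(f"power {r.power} mW outside bins [{edges[0]}, {edges[-1]}]")
        counts[idx, cats.index(r.outcome.value)] += 1
    n = counts.sum(axis=1)
    out = pd.DataFrame(
        {"bin_lo": edges[:-1], "bin_hi": edges[1:], "n": n}
    )
    for j, cat in enumerate(cats):
        out[cat] = counts[:, j]
    with np.errstate(invalid="ignore", divide="ignore"):
        props = counts / n[:, None]
    for j, cat in enumerate(cats):
        out[f"prop_{cat}"] = props[:, j]
    return out


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion with its exact (Clopper–Pearson) 95% interval."""

    successes: int
    trials: int
    proportion: float
    ci_low: float
    ci_high: float


def proportion_estimate(successes: int, trials: int, alpha: float = 0.05) -> ProportionEstimate:
    """Point estimate and exact two-sided binomial interval for k successes in n trials."""
    if trials < 1:
        raise ValidationError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValidationError("need 0 <= successes <= trials")
    lo, hi = proportion_confint(successes, trials, alpha=alpha, method="beta")
    return ProportionEstimate(
        successes=int(successes),
        trials=int(trials),
        proportion=successes / trials,
        ci_low=float(lo),
        ci_high=float(hi),
    )
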
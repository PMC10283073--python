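"""Test and exploit the cell-size effect.

Likelihood-ratio tests compare size-included against size-ignored logistic
models for every endpoint and duration (chi-square, df = 2); for the 60-s
target endpoint the bounded pair is compared by the deviance-at-medians
route (df = 3).  Median-split strata are refitted separately, and the
size-included models yield per-size optimal powers.

Run after 01:  python analysis/04_cell_size_effects.py
"""

import json
from pathlib import Path

import numpy as np

from irdose import (
    CurveSet,
    PriorSpec,
    SamplerConfig,
    fit_by_size_strata,
    fit_logistic,
    lrt_nested,
    manual_lrt,
    fit_bounded_mcmc,
    normalize_cell_size,
    read_trials,
    size_conditional_recommendation,
)
from irdose.errors import McmcConvergenceError

RESULTS = Path(__file__).resolve().parent.parent / "results"
RANGES = {60: (5.5, 20.0), 1: (10.0, 24.0)}
SEED = 1203

report = {}
for duration, power_range in RANGES.items():
    ds = normalize_cell_size(read_trials(RESULTS / f"trials_{duration}s.csv"))
    print(f"== {duration} s irradiation ==")
    report[f"{duration}s"] = {}
    for endpoint in ("target", "neighboring", "local", "death"):
        full = fit_logistic(ds, endpoint, family="size")
        reduced = fit_logistic(ds, endpoint, family="simple")
        res = lrt_nested(full, reduced)
        report[f"{duration}s"][endpoint] = res.to_dict()
        mark = "*" if res.p_value < 0.05 else " "
        print(
            f"  {endpoint:<12s} LRT(size vs none): stat={res.statistic:8.2f} "
            f"df={res.df} p={res.p_value:.3g} {mark}"
        )

# Bayesian (deviance-at-medians) LRT for the bounded 60-s target pair
ds60 = normalize_cell_size(read_trials(RESULTS / "trials_60s.csv"))
cfg = SamplerConfig(chains=2, iterations=3000, warmup=2000, nwalkers=32, seed=SEED)


def _fit_robust(endpoint, family, config, max_tries=3):
    import dataclasses

    last = None
    for k in range(max_tries):
        c = dataclasses.replace(
            config, iterations=config.iterations * 2**k, warmup=config.warmup * 2**k
        )
        try:
            return fit_bounded_mcmc(ds60, endpoint, family, config=c)
        except McmcConvergenceError as exc:
            last = exc
    raise last


try:
    post_full = _fit_robust("target", "bounded_size", cfg)
    post_red = _fit_robust("target", "bounded", cfg)
    res = manual_lrt(post_full, post_red, ds60)
    report["60s_target_bounded_manual_lrt"] = res.to_dict()
    print(
        f"  bounded pair (60 s target), deviance-at-medians LRT: "
        f"stat={res.statistic:.2f} df={res.df} p={res.p_value:.3g}"
    )
    sized = CurveSet(
        target=post_full.curve_at_medians,
        neighboring=fit_logistic(ds60, "neighboring", family="size").curve,
        death=fit_logistic(ds60, "death", family="size").curve,
    )
    recs = size_conditional_recommendation(sized, 1, RANGES[60], c_values=[-1.0, 0.0, 1.0])
    report["size_conditional_condition1_60s"] = [r.to_dict() for r in recs]
    print("  size-conditional condition-1 optima (c = normalized size):")
    for rec in recs:
        print(f"    c={rec.c:+.0f}: {rec.optimal_power_rounded:.1f} mW (score {rec.achieved_score:.3f})")
except McmcConvergenceError as exc:
    report["60s_target_bounded_manual_lrt"] = {"error": str(exc)}
    print(f"  bounded-pair MCMC did not converge: {exc}")

# median-split strata on the 60-s target endpoint
sizes = [r.cell_size for r in ds60 if r.cell_size is not None]
median = float(np.median(sizes))
strata = [
    (f"small (<{median:,.0f} um^2)", lambda s: s < median),
    (f"large (>={median:,.0f} um^2)", lambda s: s >= median),
]
print(f"  median-split strata at {median:,.0f} um^2 (target endpoint):")
report["strata_60s_target"] = []
for stratum in fit_by_size_strata(ds60, "target", strata):
    if stratum.skipped:
        print(f"    {stratum.label}: skipped ({stratum.reason})")
        report["strata_60s_target"].append({"label": stratum.label, "skipped": True})
        continue
    p = stratum.fit.curve.params
    print(f"    {stratum.label}: a={p.a:.3f} b={p.b:.2f} (n={stratum.fit.n_used})")
    report["strata_60s_target"].append(
        {"label": stratum.label, "a": p.a, "b": p.b, "n": stratum.fit.n_used}
    )

(RESULTS / "size_effects.json").write_text(json.dumps(report, indent=2))
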
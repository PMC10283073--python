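"""Select optimal laser powers from the fitted curves.

For each duration: maximize condition 1 (single-target induction,
P_target·(1−P_neighboring)) and condition 2 (any-local induction without
death, P_local·(1−P_death)) over the design power range, locate the 10%
raising points of all four endpoints, and check the directly fitted P_local
curve against the independence composition.  Writes a recommendation JSON
and a score-vs-power CSV per duration.

Run after 02:  python analysis/03_optimize_dose.py
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from irdose import (
    CurveSet,
    ResponseCurve,
    condition_score,
    local_consistency_check,
    optimize_condition,
    raising_point,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
RANGES = {60: (5.5, 20.0), 1: (10.0, 24.0)}

for duration, power_range in RANGES.items():
    curves = {
        ep: ResponseCurve.from_json(RESULTS / f"curve_{duration}s_{ep}.json")
        for ep in ("target", "neighboring", "local", "death")
    }
    cs = CurveSet(
        target=curves["target"], neighboring=curves["neighboring"], death=curves["death"]
    )
    print(f"== {duration} s irradiation, search range {power_range} mW ==")
    report = {"duration_s": duration, "power_range_mw": list(power_range)}
    for condition in (1, 2):
        rec = optimize_condition(cs, condition, power_range)
        report[f"condition{condition}"] = rec.to_dict()
        print(
            f"  condition {condition}: optimal power {rec.optimal_power_rounded:.1f} mW "
            f"(score {rec.achieved_score:.3f})"
        )
    report["raising_points"] = {}
    for ep, curve in curves.items():
        rp = raising_point(curve, 0.10, power_range)
        report["raising_points"][ep] = rp.to_dict()
        desc = f"{rp.power:.2f} mW" if rp.power is not None else f"unreachable ({rp.reason})"
        print(f"  10% raising point, {ep}: {desc}")
    disc = local_consistency_check(curves["local"], cs, power_range)
    report["local_direct_vs_composed_max_discrepancy"] = disc
    print(f"  direct-vs-composed P_local max discrepancy: {disc:.4f}")

    (RESULTS / f"recommendation_{duration}s.json").write_text(json.dumps(report, indent=2))
    grid = np.arange(power_range[0], power_range[1] + 0.005, 0.01)
    pd.DataFrame(
        {
            "power_mw": grid,
            "condition1_score": condition_score(cs, 1, grid),
            "condition2_score": condition_score(cs, 2, grid),
        }
    ).to_csv(RESULTS / f"scores_{duration}s.csv", index=False)
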
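"""Dose decision layer: union composition, condition scores, grid+refine
optimization against a brute-force oracle, raising points, and
size-conditional recommendations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irdose import (
    CurveSet,
    compose_local,
    condition_score,
    local_consistency_check,
    optimize_condition,
    raising_point,
    size_conditional_recommendation,
)
from irdose.errors import UsageError
from irdose.models import (
    BoundedLogisticParams,
    ResponseCurve,
    SimpleLogisticParams,
    SizeLogisticParams,
)

prob = st.floats(0, 1, allow_nan=False)


def simple(a, b, endpoint, duration=60.0):
    return ResponseCurve("simple", SimpleLogisticParams(a=a, b=b), endpoint, duration)


def flat_zero(endpoint, duration=60.0):
    return simple(0.0, -30.0, endpoint, duration)  # p ~ 1e-13 everywhere


@pytest.fixture
def basic_curves():
    return CurveSet(
        target=ResponseCurve(
            "bounded", BoundedLogisticParams(lim=0.4, a=1.5, b=-12.0), "target", 60.0
        ),
        neighboring=simple(0.9, -11.0, "neighboring"),
        death=simple(0.8, -13.5, "death"),
    )


@settings(max_examples=200, deadline=None)
@given(p=prob, q=prob)
def test_compose_local_union_properties(p, q):
    u = compose_local(p, q)
    assert u == pytest.approx(p + q - p * q, abs=1e-15)  # inclusion-exclusion
    assert u == compose_local(q, p)  # symmetric
    assert u >= max(p, q) - 1e-15
    assert u <= min(1.0, p + q) + 1e-15


def test_compose_local_examples():
    assert compose_local(0.5, 0.5) == pytest.approx(0.75)
    assert compose_local(0.0, 0.37) == pytest.approx(0.37)
    assert compose_local(1.0, 0.37) == pytest.approx(1.0)


def test_condition_score_definitions(basic_curves):
    import dataclasses

    x = 10.0
    s1 = condition_score(basic_curves, 1, x)
    pt = basic_curves.target.predict(x)
    pn = basic_curves.neighboring.predict(x)
    assert s1 == pytest.approx(pt * (1 - pn))
    # p_neighboring ~ 0: condition 1 equals p_target
    no_n = dataclasses.replace(basic_curves, neighboring=flat_zero("neighboring"))
    assert condition_score(no_n, 1, x) == pytest.approx(pt, rel=1e-9)
    # p_death ~ 1 kills condition 2 everywhere
    certain_death = dataclasses.replace(basic_curves, death=simple(0.0, 30.0, "death"))
    assert condition_score(certain_death, 2, x) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(UsageError):
        condition_score(basic_curves, 3, x)


def test_optimize_monotone_score_hits_upper_boundary():
    cs = CurveSet(
        target=simple(0.5, -6.0, "target"),
        neighboring=flat_zero("neighboring"),
        death=flat_zero("death"),
    )
    rec = optimize_condition(cs, 1, (5.5, 20.0))
    assert rec.optimal_power == pytest.approx(20.0, abs=1e-6)


def test_optimize_matches_fine_brute_force(basic_curves):
    rng = np.random.default_rng(42)
    for trial in range(10):
        cs = CurveSet(
            target=ResponseCurve(
                "bounded",
                BoundedLogisticParams(
                    lim=rng.uniform(0.2, 1.0), a=rng.uniform(0.3, 2.0), b=-rng.uniform(4, 16)
                ),
                "target",
                60.0,
            ),
            neighboring=simple(rng.uniform(0.2, 1.5), -rng.uniform(6, 18), "neighboring"),
            death=simple(rng.uniform(0.2, 1.5), -rng.uniform(8, 20), "death"),
        )
        condition = 1 + trial % 2
        rec = optimize_condition(cs, condition, (5.5, 20.0))
        grid = np.arange(5.5, 20.0005, 0.001)
        scores = condition_score(cs, condition, grid)
        brute = grid[np.argmax(scores)]
        assert abs(rec.optimal_power - brute) <= 0.01
        assert rec.achieved_score >= np.max(scores) - 1e-9


def test_degenerate_score_flag():
    cs = CurveSet(
        target=ResponseCurve(
            # product of lim and the sigmoid underflows to exactly 0 everywhere
            "bounded", BoundedLogisticParams(lim=1e-310, a=0.0, b=-40.0), "target", 60.0
        ),
        neighboring=flat_zero("neighboring"),
        death=flat_zero("death"),
    )
    rec = optimize_condition(cs, 1, (5.5, 20.0))
    assert rec.degenerate and rec.optimal_power == 5.5


def test_raising_point_closed_form_and_flags():
    # simple logistic (a=1, b=-ln 9) crosses 10% exactly at power 0
    curve = simple(1.0, -math.log(9), "target")
    rp = raising_point(curve, 0.10, (0.0, 50.0))
    assert rp.power == pytest.approx(0.0, abs=1e-9)

    rng = np.random.default_rng(7)
    for _ in range(50):
        lim = rng.uniform(0.15, 1.0)
        a = rng.uniform(0.3, 2.0)
        b = -rng.uniform(4, 16)
        bc = ResponseCurve("bounded", BoundedLogisticParams(lim=lim, a=a, b=b), "target", 60.0)
        t = 0.10
        x_closed = (math.log(t / (lim - t)) - b) / a
        if 0 <= x_closed <= 50:
            got = raising_point(bc, t, (0.0, 50.0))
            assert got.power == pytest.approx(x_closed, abs=1e-6)

    low = ResponseCurve("bounded", BoundedLogisticParams(lim=0.08, a=1.0, b=-10.0), "target", 60.0)
    assert raising_point(low, 0.10, (0.0, 50.0)).unreachable

    with pytest.raises(UsageError):
        raising_point(simple(-1.0, 5.0, "target"), 0.10, (0.0, 50.0))


def test_raising_point_increases_with_threshold(basic_curves):
    powers = [
        raising_point(basic_curves.target, t, (0.0, 50.0)).power for t in (0.05, 0.10, 0.20)
    ]
    assert powers[0] < powers[1] < powers[2]


def test_local_consistency_zero_for_identical(basic_curves):
    composed_vals = compose_local(
        basic_curves.target.predict(10.0), basic_curves.neighboring.predict(10.0)
    )
    # a direct curve built to equal the composition is reported as 0 discrepancy
    # (use the composition itself via a curve set whose local slot is absent)
    direct = basic_curves  # compose on demand
    # trivially: comparing the composed curve against itself
    class _AsCurve:
        endpoint = "local"

        def predict(self, x, c=0.0):
            return compose_local(
                basic_curves.target.predict(x, c), basic_curves.neighboring.predict(x, c)
            )

    disc = local_consistency_check(_AsCurve(), direct, (5.5, 20.0))
    assert disc == pytest.approx(0.0, abs=1e-15)
    assert composed_vals > 0  # sanity: nontrivial comparison


def test_size_conditional_recommendations():
    """With a positive size main effect (larger cells respond at lower power),
    the recommended power decreases with c, each value matching brute force."""
    def size_curve(a1, a2, b, endpoint):
        return ResponseCurve(
            "size", SizeLogisticParams(a1=a1, a2=a2, a3=0.0, b=b), endpoint, 60.0
        )

    cs = CurveSet(
        target=size_curve(1.5, 1.0, -12.0, "target"),
        neighboring=size_curve(0.9, 1.0, -11.0, "neighboring"),
        death=size_curve(0.8, 1.0, -13.5, "death"),
    )
    recs = size_conditional_recommendation(cs, 1, (5.5, 20.0), c_values=[-1.0, 0.0, 1.0, 3.0])
    assert len(recs) == 4
    powers = [r.optimal_power for r in recs[:3]]
    assert powers[0] > powers[1] > powers[2]
    for rec in recs[:3]:
        grid = np.arange(5.5, 20.0005, 0.001)
        brute = grid[np.argmax(condition_score(cs, 1, grid, rec.c))]
        assert abs(rec.optimal_power - brute) <= 0.01
    assert not recs[1].extrapolation_warning
    assert recs[3].extrapolation_warning  # c = 3 is outside +-2 SD

    with pytest.raises(UsageError):
        size_conditional_recommendation(
            CurveSet(
                target=simple(1.0, -10.0, "target"),
                neighboring=simple(1.0, -10.0, "neighboring"),
                death=simple(1.0, -12.0, "death"),
            ),
            1,
            (5.5, 20.0),
            [0.0],
        )


def test_curve_set_validates_slots_and_duration():
    with pytest.raises(UsageError):
        CurveSet(
            target=simple(1.0, -10.0, "neighboring"),
            neighboring=simple(1.0, -10.0, "neighboring"),
            death=simple(1.0, -12.0, "death"),
        )
    with pytest.raises(UsageError):
        CurveSet(
            target=simple(1.0, -10.0, "target", duration=1.0),
            neighboring=simple(1.0, -10.0, "neighboring"),
            death=simple(1.0, -12.0, "death"),
        )
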
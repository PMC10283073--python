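"""Synthetic-data generator: published designs, calibrated sizes, the
category collapse, purity, and the in-study leaf example."""

import dataclasses

import numpy as np
import pytest

from irdose import (
    OutcomeCategory,
    default_truth,
    encode_endpoints,
    leaf_fixture,
    proportion_estimate,
    replicate_design,
    sample_cell_sizes,
    simulate_trials,
)
from irdose.errors import DomainError, UsageError
from irdose.models import ResponseCurve, SimpleLogisticParams
from irdose.simulate import DesignSpec, _categorize


@pytest.mark.parametrize(
    "duration, counts, total",
    [(60, (50, 40, 30, 9), 129), (1, (20, 30, 40), 90)],
)
def test_replicate_design_bin_counts(duration, counts, total):
    design = replicate_design(duration)
    assert design.bin_counts() == counts
    assert design.n_total == total
    powers = design.powers()
    assert len(powers) == total
    # every trial power lies inside its bin and on the 0.5-mW lattice
    for lo, hi, n in design.bins:
        inside = powers[(powers >= lo) & (powers <= hi)]
        assert len(inside) >= n  # bins do not overlap, so == after summing
    assert np.allclose((powers / 0.5) % 1, 0)


def test_replicate_design_rejects_unknown_duration():
    with pytest.raises(DomainError):
        replicate_design(5)


def test_design_spec_validation():
    with pytest.raises(UsageError):
        DesignSpec(duration=60.0, bins=((5.0, 8.0, 10), (7.0, 9.0, 10)))  # overlap
    with pytest.raises(UsageError):
        DesignSpec(duration=60.0, bins=((5.0, 8.0, 0),))


def test_cell_sizes_calibrated_lognormal():
    sizes = sample_cell_sizes(100_000, seed=123)
    assert np.all(sizes > 0)
    assert abs(np.mean(sizes) / 3000.0 - 1) < 0.02  # mean within 2% of 3,000 um^2
    assert abs(np.std(sizes) / np.mean(sizes) - 0.5) < 0.02  # CV ~ 0.5
    again = sample_cell_sizes(100_000, seed=123)
    np.testing.assert_array_equal(sizes, again)


@pytest.mark.parametrize(
    "tnd, category",
    [
        ((0, 0, 0), OutcomeCategory.NONE),
        ((1, 0, 0), OutcomeCategory.TARGET_ONLY),
        ((1, 1, 0), OutcomeCategory.TARGET_AND_NEIGHBOR),
        ((0, 1, 0), OutcomeCategory.NEIGHBOR_ONLY),
        ((0, 0, 1), OutcomeCategory.DEATH_TARGET),
        ((1, 1, 1), OutcomeCategory.DEATH_AND_EXPRESSION),
    ],
)
def test_category_round_trip_preserves_death_and_local(tnd, category):
    """For the six canonical latent combinations, encoding the category back
    to endpoint bits preserves the death bit and local = T OR N."""
    t, n, d = tnd
    assert _categorize(t, n, d) == category
    ev = encode_endpoints(category)
    assert ev.death == d
    assert ev.local == (t | n)


def test_lossy_collapse_of_death_with_expression():
    # the taxonomy has no death+single-expression classes: both collapse
    assert _categorize(1, 0, 1) == OutcomeCategory.DEATH_AND_EXPRESSION
    assert _categorize(0, 1, 1) == OutcomeCategory.DEATH_AND_EXPRESSION


def _constant_truth(p_t, p_n, p_d):
    def curve(p, endpoint):
        b = 30.0 if p >= 1 else -30.0 if p <= 0 else float(np.log(p / (1 - p)))
        return ResponseCurve("simple", SimpleLogisticParams(a=0.0, b=b), endpoint, 60.0)

    truth = default_truth(60)
    return dataclasses.replace(
        truth,
        target=curve(p_t, "target"),
        neighboring=curve(p_n, "neighboring"),
        death=curve(p_d, "death"),
    )


def test_simulate_extreme_truths():
    design = replicate_design(60)
    all_none = simulate_trials(design, _constant_truth(0, 0, 0), seed=1)
    assert all(r.outcome == OutcomeCategory.NONE for r in all_none)
    all_death = simulate_trials(design, _constant_truth(0, 0, 1), seed=1)
    assert all(r.outcome == OutcomeCategory.DEATH_TARGET for r in all_death)


def test_simulated_endpoint_frequencies_match_collapsed_marginals():
    """At (p_T, p_N, p_D) = (0.3, 0.2, 0.1) the exact observable marginals
    follow from the collapse rule:
      P(target bit)   = p_T + (1-p_T)*p_D*p_N      (death+neighbor sets it)
      P(neighbor bit) = p_N + (1-p_N)*p_D*p_T
      P(local bit)    = p_T + p_N - p_T*p_N        (exact union, unaffected)
      P(death bit)    = p_D
    Empirical frequencies at n = 10,000 stay within 3 binomial SEs of these.
    """
    p_t, p_n, p_d = 0.3, 0.2, 0.1
    design = DesignSpec(duration=60.0, bins=((10.0, 10.0, 10_000),))
    ds = simulate_trials(design, _constant_truth(p_t, p_n, p_d), seed=31)
    frame = ds.to_frame()
    expected = {
        "target": p_t + (1 - p_t) * p_d * p_n,
        "neighboring": p_n + (1 - p_n) * p_d * p_t,
        "local": p_t + p_n - p_t * p_n,
        "death": p_d,
    }
    n = len(frame)
    for endpoint, p in expected.items():
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frame[endpoint].mean() - p) <= 3 * se, endpoint


def test_generator_is_pure(truth_60s):
    design = replicate_design(60)
    a = simulate_trials(design, truth_60s, seed=99)
    b = simulate_trials(design, truth_60s, seed=99)
    assert a.to_frame().equals(b.to_frame())
    c = simulate_trials(design, truth_60s, seed=100)
    assert not a.to_frame().equals(c.to_frame())


def test_dependence_switch_changes_joint_but_not_marginals():
    p = (0.4, 0.4, 0.4)
    design = DesignSpec(duration=60.0, bins=((10.0, 10.0, 20_000),))
    indep = simulate_trials(design, _constant_truth(*p), seed=5).to_frame()
    dep_truth = dataclasses.replace(_constant_truth(*p), dependence=0.9)
    dep = simulate_trials(design, dep_truth, seed=5).to_frame()
    # death marginal is collapse-free: equal in distribution either way
    assert abs(indep["death"].mean() - 0.4) < 0.015
    assert abs(dep["death"].mean() - 0.4) < 0.015
    # strong positive dependence raises P(all three latent events together);
    # visible as an excess of DEATH_AND_EXPRESSION outcomes
    frac_dep = (dep["outcome"] == "DEATH_AND_EXPRESSION").mean()
    frac_ind = (indep["outcome"] == "DEATH_AND_EXPRESSION").mean()
    assert frac_dep > frac_ind + 0.05


def test_leaf_fixture_worked_example():
    ds = leaf_fixture()
    assert len(ds) == 20
    assert all(r.tissue == "leaf mesophyll" and r.duration == 60.0 for r in ds)
    successes = sum(r.endpoints.target for r in ds)
    assert successes == 4
    est = proportion_estimate(successes, len(ds))
    assert est.proportion == pytest.approx(0.20)
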
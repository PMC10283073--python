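"""Bayesian bounded-model estimation: determinism, diagnostics, median
summaries, the deviance-based LRT, and the constrained-MLE cross-check."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from irdose import (
    PosteriorFit,
    PriorSpec,
    SamplerConfig,
    deviance_at,
    fit_bounded_mcmc,
    fit_bounded_mle,
    fit_logistic,
    lrt_nested,
    manual_lrt,
    posterior_median_params,
    replicate_design,
    simulate_endpoint_trials,
)
from irdose.errors import UsageError
from irdose.models import BoundedLogisticParams, ResponseCurve, SimpleLogisticParams


@pytest.fixture(scope="module")
def bounded_dataset(truth_60s, powers_60s):
    # 300 trials per lattice power from the bounded target truth, no collapse
    powers = np.repeat(np.unique(powers_60s), 300)
    return simulate_endpoint_trials(powers, truth_60s.target, seed=17)


@pytest.fixture(scope="module")
def small_config():
    return SamplerConfig(chains=2, iterations=2000, warmup=1200, seed=11)


@pytest.fixture(scope="module")
def posterior(bounded_dataset, small_config):
    return fit_bounded_mcmc(bounded_dataset, "target", "bounded", config=small_config)


def test_sampler_config_validation():
    with pytest.raises(UsageError):
        SamplerConfig(chains=1)


def test_mcmc_is_deterministic_and_converged(bounded_dataset, small_config, posterior):
    again = fit_bounded_mcmc(bounded_dataset, "target", "bounded", config=small_config)
    assert again.medians == posterior.medians  # bitwise-identical medians
    assert max(posterior.rhat.values()) <= small_config.rhat_threshold
    assert min(posterior.ess.values()) >= small_config.ess_threshold


def test_posterior_medians_near_truth_and_mle(bounded_dataset, posterior):
    # generating curve: lim 0.40, a 1.5, b -12
    assert posterior.medians["lim"] == pytest.approx(0.40, abs=0.05)
    mle = fit_bounded_mle(bounded_dataset, "target", "bounded")
    grid = np.linspace(5.5, 20.0, 60)
    gap = np.max(
        np.abs(posterior.curve_at_medians.predict(grid) - mle.curve.predict(grid))
    )
    assert gap < 0.05


def test_posterior_median_params_is_marginal_median():
    samples = pd.DataFrame(
        {
            "chain": [0, 0, 1],
            "walker": [0, 1, 0],
            "draw": [0, 0, 0],
            "lim": [0.3, 0.4, 0.5],
            "a": [1.0, 1.0, 1.0],
            "b": [-9.0, -10.0, -11.0],
        }
    )
    curve = ResponseCurve(
        "bounded", BoundedLogisticParams(lim=0.4, a=1.0, b=-10.0), "target", 60.0
    )
    fit = PosteriorFit(
        samples=samples,
        medians={"lim": 0.4, "a": 1.0, "b": -10.0},
        rhat={},
        ess={},
        curve_at_medians=curve,
        family="bounded",
        endpoint="target",
    )
    params = posterior_median_params(fit)
    assert params == BoundedLogisticParams(lim=0.4, a=1.0, b=-10.0)


def test_deviance_is_minus_two_loglik(bounded_dataset):
    from irdose.models import log_likelihood

    curve = ResponseCurve("simple", SimpleLogisticParams(a=1.0, b=-10.0), "target", 60.0)
    x, y, _ = bounded_dataset.endpoint_arrays("target")
    assert deviance_at(curve, bounded_dataset) == pytest.approx(
        -2.0 * log_likelihood(curve, x, y).value
    )
    # single trial at p = 0.5: deviance 2 ln 2
    from conftest import make_dataset

    one = make_dataset([(5.0, "TARGET_ONLY")])
    flat = ResponseCurve("simple", SimpleLogisticParams(a=0.0, b=0.0), "target", 60.0)
    assert deviance_at(flat, one) == pytest.approx(2 * math.log(2))


def test_manual_lrt_identity_with_nested_lrt(powers_60s):
    """Fed identical point curves, the deviance route and the 2Δloglik route
    agree exactly (oracle identity); df for bounded_size vs bounded is 3."""
    from irdose.models import BoundedSizeParams

    full_curve = ResponseCurve(
        "bounded_size",
        BoundedSizeParams(lim=0.4, a1=1.5, a2=0.0, a3=0.0, a4=0.0, b=-12.0),
        "target",
        60.0,
    )
    red_curve = ResponseCurve(
        "bounded", BoundedLogisticParams(lim=0.4, a=1.5, b=-12.0), "target", 60.0
    )
    ds = simulate_endpoint_trials(np.resize(np.unique(powers_60s), 1000), full_curve, seed=6)
    from irdose.mle import MleFit

    full_fit = MleFit(curve=full_curve, loglik=-deviance_at(full_curve, ds) / 2, converged=True, n_used=1000)
    red_fit = MleFit(curve=red_curve, loglik=-deviance_at(red_curve, ds) / 2, converged=True, n_used=1000)
    res = manual_lrt(full_fit, red_fit, ds)
    assert res.df == 3
    assert res.statistic == pytest.approx(0.0, abs=1e-9)  # identical predictions
    assert res.p_value == pytest.approx(1.0)
    # same curves through the 2*delta-loglik route
    nested = lrt_nested(full_fit, red_fit)
    assert nested.statistic == pytest.approx(res.statistic, abs=1e-9)

    with pytest.raises(UsageError):
        manual_lrt(red_fit, full_fit, ds)  # reversed nesting


def test_manual_lrt_rejects_mismatched_record_sets(bounded_dataset):
    """A size-aware full model silently dropping unsized records must not be
    compared against a size-free reduced model seeing all of them."""
    from irdose.mle import MleFit
    from irdose.models import BoundedSizeParams

    full_curve = ResponseCurve(
        "bounded_size",
        BoundedSizeParams(lim=0.4, a1=1.5, a2=0.0, a3=0.0, a4=0.0, b=-12.0),
        "target",
        60.0,
    )
    red_fit = fit_bounded_mle(bounded_dataset, "target", "bounded")
    full_fit = MleFit(curve=full_curve, loglik=0.0, converged=True, n_used=0)
    with pytest.raises(UsageError):
        manual_lrt(full_fit, red_fit, bounded_dataset)  # no sizes in the data


def test_bounded_mle_with_lim_fixed_equals_plain_logistic(truth_60s, powers_60s):
    ds = simulate_endpoint_trials(np.resize(powers_60s, 600), truth_60s.neighboring, seed=4)
    fixed = fit_bounded_mle(ds, "neighboring", "bounded", fix_lim=1.0)
    plain = fit_logistic(ds, "neighboring")
    assert fixed.curve.params.lim == 1.0
    assert fixed.curve.params.a == pytest.approx(plain.curve.params.a, abs=1e-3)
    assert fixed.curve.params.b == pytest.approx(plain.curve.params.b, abs=1e-2)
    assert fixed.loglik == pytest.approx(plain.loglik, abs=1e-6)


def test_bounded_mle_lim_unidentified_without_plateau(powers_60s):
    """When every design power sits in the rising phase, lim is weakly
    identified: the profile likelihood is nearly flat in lim, so pinning lim
    near 1 costs almost nothing."""
    rising = ResponseCurve(
        "simple", SimpleLogisticParams(a=0.25, b=-6.0), "target", 60.0
    )
    ds = simulate_endpoint_trials(np.resize(np.unique(powers_60s), 2000), rising, seed=8)
    free = fit_bounded_mle(ds, "target", "bounded")
    pinned = fit_bounded_mle(ds, "target", "bounded", fix_lim=0.99)
    assert free.boundary_flag or (free.loglik - pinned.loglik) < 2.0


def test_fitted_curve_respects_its_limit(posterior):
    grid = np.linspace(0.0, 50.0, 501)
    p = posterior.curve_at_medians.predict(grid)
    assert np.all(p <= posterior.medians["lim"] + 1e-12)
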
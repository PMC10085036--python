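"""Prior elicitation, posterior, Metropolis-Hastings chain and HPD intervals."""

import numpy as np
import pytest

import mktl
from mktl.bayes import (
    PriorSpec,
    covariance_mle_replicates,
    elicit_gamma_hyperparams,
    elicit_prior_from_fit,
    hpd_interval,
    log_posterior,
    log_prior,
    mh_sample,
    self_estimate,
)


def test_elicitation_forced_by_moment_formulas():
    # a replicate column with mean 2 and variance 0.5 must give
    # shape phi = mean^2/var = 8 and rate D = mean/var = 4
    s = np.sqrt(0.5 * 3.0 / 4.0)  # ddof=1 variance of {2-s, 2-s, 2+s, 2+s} is 0.5*... build exactly
    col = np.array([2.0 - s, 2.0 - s, 2.0 + s, 2.0 + s])
    assert col.mean() == pytest.approx(2.0)
    assert col.var(ddof=1) == pytest.approx(0.5)
    reps = np.column_stack([col, np.full(4, 1.0) + np.array([-0.1, 0.1, -0.1, 0.1])])
    prior = elicit_gamma_hyperparams(reps)
    assert prior.phi1 == pytest.approx(8.0, rel=1e-12)
    assert prior.D1 == pytest.approx(4.0, rel=1e-12)
    # moment identity: elicited gamma prior mean/variance equal column stats
    rng = np.random.default_rng(0)
    reps = rng.gamma(4.0, 0.5, size=(500, 2))
    prior = elicit_gamma_hyperparams(reps)
    m = reps.mean(axis=0)
    v = reps.var(axis=0, ddof=1)
    assert prior.phi1 / prior.D1 == pytest.approx(m[0], rel=1e-12)
    assert prior.phi1 / prior.D1**2 == pytest.approx(v[0], rel=1e-12)
    assert prior.phi2 / prior.D2 == pytest.approx(m[1], rel=1e-12)
    assert prior.phi2 / prior.D2**2 == pytest.approx(v[1], rel=1e-12)


def test_elicitation_rejects_degenerate_input():
    with pytest.raises(ValueError):
        elicit_gamma_hyperparams(np.ones((10, 2)))  # zero variance
    with pytest.raises(ValueError):
        elicit_gamma_hyperparams(np.ones((1, 2)))  # B < 2


def test_elicited_prior_centres_on_the_fit(covid_fit):
    prior = elicit_prior_from_fit(covid_fit, B=2000, seed=5)
    assert prior.phi1 / prior.D1 == pytest.approx(covid_fit.params_hat.theta, rel=0.05)
    assert prior.phi2 / prior.D2 == pytest.approx(covid_fit.params_hat.beta, rel=0.05)


def test_log_posterior_is_loglik_plus_logprior(covid, rng):
    prior = PriorSpec(2.0, 1.0, 3.0, 2.0)
    for _ in range(20):
        p1 = mktl.MKTLParams(rng.uniform(0.5, 5), rng.uniform(0.3, 2))
        p2 = mktl.MKTLParams(rng.uniform(0.5, 5), rng.uniform(0.3, 2))
        lhs = log_posterior(p1, covid, prior) - log_posterior(p2, covid, prior)
        rhs = (
            mktl.mktl_loglik(covid, p1) + log_prior(p1, prior)
            - mktl.mktl_loglik(covid, p2) - log_prior(p2, prior)
        )
        assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-9)
    assert log_posterior(np.array([-1.0, 1.0]), covid, prior) == -np.inf


def test_flat_prior_posterior_peaks_at_mle(covid, covid_fit):
    # with shape 1 and a vanishing rate the gamma prior is essentially flat,
    # so the posterior maximiser must coincide with the MLE
    prior = PriorSpec(1.0, 1e-10, 1.0, 1e-10)
    base = log_posterior(covid_fit.params_hat, covid, prior)
    t, b = covid_fit.params_hat.theta, covid_fit.params_hat.beta
    for dt, db in [(0.03, 0.0), (-0.03, 0.0), (0.0, 0.01), (0.0, -0.01)]:
        assert log_posterior(mktl.MKTLParams(t + dt, b + db), covid, prior) < base


def test_chain_reproducible_for_fixed_seed(covid):
    prior = PriorSpec(2.0, 1.0, 3.0, 2.0)
    d1 = mh_sample(covid, prior, n_iter=600, burn_in=100, seed=11)
    d2 = mh_sample(covid, prior, n_iter=600, burn_in=100, seed=11)
    assert np.array_equal(d1.draws, d2.draws)
    assert d1.acceptance_rate == d2.acceptance_rate
    assert d1.draws.shape == (500, 2)
    d3 = mh_sample(covid, prior, n_iter=600, burn_in=100, seed=12)
    assert not np.array_equal(d1.draws, d3.draws)


def test_acceptance_rate_in_healthy_band(covid, covid_fit):
    prior = elicit_prior_from_fit(covid_fit, B=1000, seed=3)
    draws = mh_sample(covid, prior, n_iter=4000, burn_in=1000, seed=3)
    assert 0.1 < draws.acceptance_rate < 0.6


def test_posterior_mean_tracks_mle_on_synthetic_data():
    truth = mktl.MKTLParams(1.5, 1.5)
    sample = mktl.mktl_rvs(2000, truth, seed=99)
    fit = mktl.fit_mle(sample)
    prior = elicit_prior_from_fit(fit, B=1000, seed=99)
    draws = mh_sample(sample, prior, n_iter=4000, burn_in=1000, seed=99)
    post = self_estimate(draws)
    # data dominate: posterior mean within a few SEs of the MLE and truth
    assert post.theta == pytest.approx(fit.params_hat.theta, abs=3 * fit.se[0])
    assert post.beta == pytest.approx(fit.params_hat.beta, abs=3 * fit.se[1])
    assert post.theta == pytest.approx(truth.theta, abs=0.15)


def test_self_estimate_is_chain_mean():
    draws = mktl.PosteriorDraws(
        draws=np.tile([2.5, 0.7], (60, 1)), n_iter=60, burn_in=0, acceptance_rate=1.0
    )
    p = self_estimate(draws)
    assert (p.theta, p.beta) == pytest.approx((2.5, 0.7), rel=1e-12)
    rng = np.random.default_rng(8)
    chain = rng.gamma(3.0, 1.0, size=(200, 2))
    draws = mktl.PosteriorDraws(draws=chain, n_iter=200, burn_in=0, acceptance_rate=0.4)
    streaming = np.zeros(2)
    for k, row in enumerate(chain, start=1):
        streaming += (row - streaming) / k
    est = self_estimate(draws)
    assert np.array([est.theta, est.beta]) == pytest.approx(streaming, rel=1e-10)


def test_hpd_on_uniform_grid_has_forced_width():
    interval = hpd_interval(np.arange(1.0, 101.0), 0.95)
    # ceil(0.95*100)=95 order statistics -> width 94; ties broken leftmost
    assert interval == (1.0, 95.0)


def test_hpd_narrower_than_equal_tails_on_skewed_draws():
    rng = np.random.default_rng(21)
    draws = rng.lognormal(0.0, 0.8, size=5000)
    lo, hi = hpd_interval(draws, 0.95)
    eq_lo, eq_hi = np.quantile(draws, [0.025, 0.975])
    assert hi - lo <= eq_hi - eq_lo
    assert lo >= draws.min() and hi <= draws.max()


def test_hpd_input_validation():
    with pytest.raises(ValueError):
        hpd_interval(np.arange(10.0), 0.95)  # too few draws
    with pytest.raises(ValueError):
        hpd_interval(np.arange(100.0), 1.5)
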
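"""Bayesian estimation of the MKTL parameters.

Independent gamma priors on theta and beta, with hyperparameters
elicited by moment-matching a matrix of estimate replicates (drawn from
the MLE's normal approximation by default, or refit on parametric
bootstrap resamples), a random-walk Metropolis-Hastings sampler
targeting the joint posterior, posterior means as the squared-error-loss
(SELF) estimates, and Chen-Shao highest-posterior-density intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .distribution import MKTLParams, Sample, _as_values, mktl_loglik, mktl_rvs
from .mle import MLEFit, fit_mle

__all__ = [
    "PriorSpec",
    "PosteriorDraws",
    "elicit_gamma_hyperparams",
    "bootstrap_mle_replicates",
    "covariance_mle_replicates",
    "elicit_prior_from_fit",
    "log_prior",
    "log_posterior",
    "mh_sample",
    "self_estimate",
    "hpd_interval",
]


@dataclass(frozen=True)
class PriorSpec:
    """Gamma(shape, rate) hyperparameters: (phi1, D1) for theta, (phi2, D2) for beta."""

    phi1: float
    D1: float
    phi2: float
    D2: float

    def __post_init__(self) -> None:
        for name in ("phi1", "D1", "phi2", "D2"):
            v = float(getattr(self, name))
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
            object.__setattr__(self, name, v)


@dataclass(frozen=True)
class PosteriorDraws:
    """Post-burn-in Metropolis-Hastings chain for (theta, beta)."""

    draws: np.ndarray  # shape (n_iter - burn_in, 2)
    n_iter: int
    burn_in: int
    acceptance_rate: float
    seed: object = None

    def __post_init__(self) -> None:
        draws = np.asarray(self.draws, dtype=float)
        if draws.ndim != 2 or draws.shape[1] != 2:
            raise ValueError("draws must be an (M, 2) array")
        if draws.shape[0] != self.n_iter - self.burn_in:
            raise ValueError("chain length must equal n_iter - burn_in")
        if np.any(draws <= 0.0):
            raise ValueError("all draws must have positive components")
        object.__setattr__(self, "draws", draws)

    @property
    def theta(self) -> np.ndarray:
        return self.draws[:, 0]

    @property
    def beta(self) -> np.ndarray:
        return self.draws[:, 1]


def elicit_gamma_hyperparams(estimate_replicates) -> PriorSpec:
    """Moment-match gamma priors to columns of a B x 2 estimate matrix.

    For each parameter column with sample mean m and variance v (ddof=1):
    shape phi = m**2 / v and rate D = m / v, so the elicited gamma prior
    reproduces the replicate mean and variance exactly.
    """
    reps = np.asarray(estimate_replicates, dtype=float)
    if reps.ndim != 2 or reps.shape[1] != 2 or reps.shape[0] < 2:
        raise ValueError("estimate_replicates must be a B x 2 matrix with B >= 2")
    mean = reps.mean(axis=0)
    var = reps.var(axis=0, ddof=1)
    if np.any(var <= 0.0):
        raise ValueError("zero-variance column: elicited prior would be degenerate")
    phi = mean**2 / var
    rate = mean / var
    return PriorSpec(phi1=phi[0], D1=rate[0], phi2=phi[1], D2=rate[1])


def bootstrap_mle_replicates(
    params_hat: MKTLParams, n: int, B: int = 1000, seed=None
) -> np.ndarray:
    """B parametric-bootstrap MLE replicates at ``params_hat`` (size-n samples).

    Each replicate draws an inversion sample from the fitted model and
    refits it by maximum likelihood (initialised at the fitted values for
    speed).  Returns the B x 2 matrix fed to ``elicit_gamma_hyperparams``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty((B, 2))
    for b in range(B):
        boot = mktl_rvs(n, params_hat, seed=rng)
        fit = fit_mle(boot, init=params_hat)
        out[b] = fit.params_hat.as_array()
    return out


def covariance_mle_replicates(fit: MLEFit, B: int = 1000, seed=None) -> np.ndarray:
    """B estimate replicates drawn from N(MLE, MLE covariance).

    Uses the fit's point estimate and variance-covariance matrix directly;
    rows with a non-positive component are redrawn.  This is the default
    elicitation source because it centres the elicited prior on the
    estimate itself, whereas parametric-bootstrap replicates inherit the
    finite-sample bias of the MLE.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean = fit.params_hat.as_array()
    out = np.empty((B, 2))
    filled = 0
    while filled < B:
        block = rng.multivariate_normal(mean, fit.cov, size=B - filled)
        block = block[(block > 0.0).all(axis=1)]
        out[filled : filled + block.shape[0]] = block
        filled += block.shape[0]
    return out


def elicit_prior_from_fit(
    fit: MLEFit, B: int = 1000, seed=None, method: str = "covariance"
) -> PriorSpec:
    """Elicit gamma hyperparameters from B replicates around an MLE fit.

    ``method="covariance"`` (default) draws replicates from the normal
    approximation N(estimate, covariance); ``method="bootstrap"`` refits
    B parametric-bootstrap resamples.
    """
    if method == "covariance":
        reps = covariance_mle_replicates(fit, B=B, seed=seed)
    elif method == "bootstrap":
        reps = bootstrap_mle_replicates(fit.params_hat, fit.n_obs, B=B, seed=seed)
    else:
        raise ValueError(f"unknown elicitation method {method!r}")
    return elicit_gamma_hyperparams(reps)


def log_prior(params: MKTLParams, prior: PriorSpec) -> float:
    """Log of the joint gamma prior density, up to an additive constant."""
    return float(
        (prior.phi1 - 1.0) * math.log(params.theta)
        - prior.D1 * params.theta
        + (prior.phi2 - 1.0) * math.log(params.beta)
        - prior.D2 * params.beta
    )


def log_posterior(params, sample, prior: PriorSpec) -> float:
    """Log posterior density up to an additive constant.

    Accepts ``params`` as an ``MKTLParams`` or a length-2 array; returns
    ``-inf`` for non-positive parameter values.
    """
    if not isinstance(params, MKTLParams):
        theta, beta = float(params[0]), float(params[1])
        if theta <= 0.0 or beta <= 0.0:
            return -np.inf
        params = MKTLParams(theta, beta)
    return mktl_loglik(sample, params) + log_prior(params, prior)


def mh_sample(
    sample,
    prior: PriorSpec,
    n_iter: int = 10000,
    burn_in: int = 2000,
    seed=None,
    proposal_scale="auto",
    init: MKTLParams | None = None,
) -> PosteriorDraws:
    """Random-walk Metropolis-Hastings chain targeting the joint posterior.

    The proposal is a bivariate normal step; ``proposal_scale="auto"``
    uses the MLE covariance scaled by the classic 2.4**2 / d factor
    (d = 2 parameters).  Proposals with a non-positive component are
    rejected outright (they carry zero prior mass).  The chain starts at
    ``init`` (default: the MLE) and is fully reproducible for a fixed
    integer seed.
    """
    if not (n_iter > burn_in >= 0):
        raise ValueError("need n_iter > burn_in >= 0")
    values = _as_values(sample)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    auto_scale = isinstance(proposal_scale, str) and proposal_scale == "auto"
    mle_fit: MLEFit | None = None
    if auto_scale or init is None:
        mle_fit = fit_mle(values)
    if auto_scale:
        cov = np.asarray(mle_fit.cov) * (2.4**2 / 2.0)
    else:
        cov = np.asarray(proposal_scale, dtype=float)
        if cov.shape != (2, 2):
            raise ValueError("proposal_scale must be 'auto' or a 2x2 covariance")
    chol = np.linalg.cholesky(cov)
    current = (init or mle_fit.params_hat).as_array()
    current_lp = log_posterior(current, values, prior)
    if not np.isfinite(current_lp):
        raise ValueError("initial point has zero posterior density")

    kept = np.empty((n_iter - burn_in, 2))
    accepted_post = 0
    proposals_post = 0
    for it in range(n_iter):
        step = chol @ rng.standard_normal(2)
        cand = current + step
        post_burn = it >= burn_in
        if post_burn:
            proposals_post += 1
        if cand[0] > 0.0 and cand[1] > 0.0:
            cand_lp = log_posterior(cand, values, prior)
            if math.log(rng.random()) < cand_lp - current_lp:
                current, current_lp = cand, cand_lp
                if post_burn:
                    accepted_post += 1
        if post_burn:
            kept[it - burn_in] = current
    if accepted_post == 0:
        raise RuntimeError("chain failure: no post-burn-in proposal was accepted")
    return PosteriorDraws(
        draws=kept,
        n_iter=n_iter,
        burn_in=burn_in,
        acceptance_rate=accepted_post / proposals_post,
        seed=seed if not isinstance(seed, np.random.Generator) else None,
    )


def self_estimate(draws: PosteriorDraws) -> MKTLParams:
    """Posterior mean — the Bayes estimate under squared error loss (SELF)."""
    if draws.draws.shape[0] == 0:
        raise ValueError("empty chain")
    mean = draws.draws.mean(axis=0)
    return MKTLParams(float(mean[0]), float(mean[1]))


def hpd_interval(draws, level: float = 0.95):
    """Chen-Shao HPD interval from a 1-D vector of posterior draws.

    Sorts the draws and slides a window of ceil(level * M) consecutive
    order statistics, returning the narrowest (leftmost on ties).
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    m_total = x.size
    if m_total < 50:
        raise ValueError("need at least 50 draws for an HPD interval")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    m = int(math.ceil(level * m_total))
    widths = x[m - 1 :] - x[: m_total - m + 1]
    j = int(np.argmin(widths))  # argmin returns the leftmost minimiser
    return (float(x[j]), float(x[j + m - 1]))
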
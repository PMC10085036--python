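"""Reading samples from disk and assembling analysis reports."""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import scipy

from . import __version__
from .bayes import elicit_prior_from_fit, hpd_interval, mh_sample, self_estimate
from .distribution import Sample
from .fuzzy import FuzzyBand, fuzzy_reliability
from .gof import evaluate_fit
from .mle import fit_mle

__all__ = ["read_sample", "analyze", "write_report"]

logger = logging.getLogger("mktl")


def read_sample(path, format: str | None = None) -> Sample:
    """Read a sample from plain text (one value per line) or single-column CSV.

    A non-numeric first CSV row is treated as a header and skipped.
    Values outside the open unit interval are rejected with their line
    numbers so the offending input is easy to find.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "txt"
    if format not in ("txt", "csv"):
        raise ValueError(f"unknown format {format!r}")
    text = path.read_text()
    values = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        token = line.split(",")[0].strip() if format == "csv" else line
        try:
            v = float(token)
        except ValueError:
            if format == "csv" and not values and lineno <= 1:
                continue  # header row
            raise ValueError(f"{path}:{lineno}: non-numeric token {token!r}") from None
        if not (0.0 < v < 1.0):
            raise ValueError(f"{path}:{lineno}: value {v!r} outside the open interval (0, 1)")
        values.append(v)
    if not values:
        raise ValueError(f"{path}: no numeric values found")
    return Sample(values)


def analyze(
    sample: Sample,
    methods=("mle",),
    fuzzy_band: FuzzyBand | None = None,
    gammas=(0.3, 0.6, 0.9),
    gof: bool = True,
    seed: int = 0,
    n_iter: int = 10000,
    burn_in: int = 2000,
    elicitation_B: int = 1000,
    elicitation: str = "covariance",
    level: float = 0.95,
) -> dict:
    """Fit the MKTL model and assemble a self-describing report dict.

    Runs the requested estimation methods, the goodness-of-fit battery
    and, if a fuzzy band is given, the interval-variant fuzzy reliability
    at each gamma-cut for every method's point estimate.
    """
    report: dict = {
        "metadata": {
            "package": f"mktl {__version__}",
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "n_obs": sample.n,
            "seed": seed,
            "level": level,
            "methods": list(methods),
        }
    }
    fit = fit_mle(sample, level=level)
    logger.info("MLE: theta=%.4f beta=%.4f loglik=%.4f", fit.params_hat.theta,
                fit.params_hat.beta, fit.loglik)
    if "mle" in methods:
        report["mle"] = {
            "theta": fit.params_hat.theta,
            "beta": fit.params_hat.beta,
            "se": list(fit.se),
            "ci_theta": [fit.ci_low[0], fit.ci_high[0]],
            "ci_beta": [fit.ci_low[1], fit.ci_high[1]],
            "loglik": fit.loglik,
            "converged": fit.converged,
        }
    estimates = {"mle": fit.params_hat}

    if "bayes" in methods:
        rng = np.random.default_rng(seed)
        prior = elicit_prior_from_fit(fit, B=elicitation_B, seed=rng, method=elicitation)
        draws = mh_sample(sample, prior, n_iter=n_iter, burn_in=burn_in, seed=rng)
        post_mean = self_estimate(draws)
        hpd_t = hpd_interval(draws.theta, level)
        hpd_b = hpd_interval(draws.beta, level)
        logger.info("Bayes: theta=%.4f beta=%.4f acc=%.2f", post_mean.theta,
                    post_mean.beta, draws.acceptance_rate)
        report["bayes"] = {
            "theta": post_mean.theta,
            "beta": post_mean.beta,
            "se": [float(draws.theta.std(ddof=1)), float(draws.beta.std(ddof=1))],
            "hpd_theta": list(hpd_t),
            "hpd_beta": list(hpd_b),
            "acceptance_rate": draws.acceptance_rate,
            "n_iter": draws.n_iter,
            "burn_in": draws.burn_in,
            "prior": {"phi1": prior.phi1, "D1": prior.D1, "phi2": prior.phi2, "D2": prior.D2},
            "elicitation": elicitation,
            "elicitation_B": elicitation_B,
        }
        estimates["bayes"] = post_mean

    if gof:
        report["gof"] = evaluate_fit(sample, fit.params_hat).to_dict()
        report["gof"]["note"] = "statistics computed at fitted parameters; p-value approximate"

    if fuzzy_band is not None:
        fz = {"t1": fuzzy_band.t1, "t2": fuzzy_band.t2}
        for method, params in estimates.items():
            if method not in methods:
                continue
            fz[method] = {
                f"gamma={g:g}": fuzzy_reliability(params, fuzzy_band, g, "interval")
                for g in gammas
            }
        report["fuzzy_reliability"] = fz
    return report


def _round_sig(obj, sig: int = 6):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_sig(v, sig) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_sig(v, sig) for v in obj]
    return obj


def write_report(report: dict, path, sig_digits: int = 6) -> None:
    """Serialize a report to JSON with ``sig_digits`` significant digits."""
    Path(path).write_text(json.dumps(_round_sig(report, sig_digits), indent=2) + "\n")
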
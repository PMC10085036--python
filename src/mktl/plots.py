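"""Convenience plots: density/CDF overlays and MCMC trace plots.

Requires matplotlib (optional extra ``mktl[plot]``); imported lazily so
the core library stays matplotlib-free.
"""

from __future__ import annotations

import numpy as np

from .bayes import PosteriorDraws
from .distribution import MKTLParams, Sample, mktl_cdf, mktl_pdf


def plot_fit(sample: Sample, params: MKTLParams, ax=None):
    """Histogram of the data with the fitted density, plus the empirical
    CDF against the fitted CDF."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(1, 2, figsize=(9, 3.5))
    grid = np.linspace(1e-4, 1 - 1e-4, 400)
    ax[0].hist(sample.values, bins="auto", density=True, alpha=0.5, label="data")
    ax[0].plot(grid, mktl_pdf(grid, params), label="MKTL pdf")
    ax[0].set_xlabel("x")
    ax[0].legend()
    xs = np.sort(sample.values)
    ax[1].step(xs, np.arange(1, xs.size + 1) / xs.size, where="post", label="empirical CDF")
    ax[1].plot(grid, mktl_cdf(grid, params), label="MKTL CDF")
    ax[1].set_xlabel("x")
    ax[1].legend()
    return ax


def plot_trace(draws: PosteriorDraws, ax=None):
    """Trace and histogram for each parameter chain."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(2, 2, figsize=(9, 5))
    for row, (name, chain) in enumerate([("theta", draws.theta), ("beta", draws.beta)]):
        ax[row][0].plot(chain, lw=0.5)
        ax[row][0].set_ylabel(name)
        ax[row][1].hist(chain, bins=40, density=True)
    ax[1][0].set_xlabel("iteration (post burn-in)")
    return ax
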
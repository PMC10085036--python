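"""Goodness-of-fit statistics for a fitted MKTL model.

All three statistics work on the probability integral transform (PIT):
the sorted data are pushed through the fitted CDF and compared with the
uniform order-statistic plotting positions.  Because the parameters are
the fitted ones (not fixed in advance), the statistics follow the usual
"fit statistics" convention and the KS p-value is approximate in the
formal sense, though it is computed with the exact finite-n null
distribution of the one-sample KS statistic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .distribution import MKTLParams, _as_values, mktl_cdf

__all__ = ["GoFReport", "pit_transform", "ks_test", "cvm_statistic", "ad_statistic", "evaluate_fit"]


@dataclass(frozen=True)
class GoFReport:
    """Kolmogorov-Smirnov, Cramer-von Mises and Anderson-Darling summary."""

    ks: float
    ks_pvalue: float
    W: float
    A: float
    n: int

    def to_dict(self) -> dict:
        return {"ks": self.ks, "ks_pvalue": self.ks_pvalue, "W": self.W, "A": self.A, "n": self.n}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def pit_transform(sample, params: MKTLParams) -> np.ndarray:
    """Sorted PIT values u_(i) = F(x_(i)) under the fitted model."""
    values = _as_values(sample)
    if np.any((values <= 0.0) | (values >= 1.0)):
        raise ValueError("sample values must lie strictly in (0, 1)")
    if np.unique(values).size < values.size:
        warnings.warn("sample contains ties; statistics remain computable", stacklevel=2)
    return np.sort(mktl_cdf(np.sort(values), params))


def ks_test(pit, n: int | None = None):
    """One-sample KS statistic and its exact finite-n p-value.

    D = max_i max(i/n - u_(i), u_(i) - (i-1)/n); the p-value uses the
    exact null distribution of D_n (no ties assumed).
    """
    u = np.asarray(pit, dtype=float)
    n = u.size if n is None else int(n)
    i = np.arange(1, n + 1)
    d = float(max((i / n - u).max(), (u - (i - 1) / n).max()))
    pvalue = float(stats.kstwo.sf(d, n))
    return d, pvalue


def cvm_statistic(pit, n: int | None = None) -> float:
    """Cramer-von Mises W = 1/(12n) + sum_i (u_(i) - (2i-1)/(2n))**2."""
    u = np.asarray(pit, dtype=float)
    n = u.size if n is None else int(n)
    i = np.arange(1, n + 1)
    return float(1.0 / (12.0 * n) + np.sum((u - (2.0 * i - 1.0) / (2.0 * n)) ** 2))


def ad_statistic(pit, n: int | None = None) -> float:
    """Anderson-Darling A = -n - (1/n) sum_i (2i-1)[ln u_(i) + ln(1 - u_(n+1-i))]."""
    u = np.asarray(pit, dtype=float)
    n = u.size if n is None else int(n)
    if np.any((u <= 0.0) | (u >= 1.0)):
        raise ValueError("PIT values at 0 or 1: Anderson-Darling log terms diverge")
    i = np.arange(1, n + 1)
    return float(-n - np.sum((2.0 * i - 1.0) * (np.log(u) + np.log1p(-u[::-1]))) / n)


def evaluate_fit(sample, params: MKTLParams) -> GoFReport:
    """All three statistics of the fitted model on one sample."""
    u = pit_transform(sample, params)
    n = u.size
    d, p = ks_test(u, n)
    return GoFReport(ks=d, ks_pvalue=p, W=cvm_statistic(u, n), A=ad_statistic(u, n), n=n)
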
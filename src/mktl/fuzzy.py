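"""Fuzzy reliability of the MKTL model under a linear ramp membership.

A fuzzy lifetime band (t1, t2) induces the ramp membership
``mu(x) = 0`` below t1, ``(x - t1)/(t2 - t1)`` between the knots and 1
above t2.  A membership degree ``gamma`` maps to the gamma-cut lifetime
``x(gamma) = t1 + gamma (t2 - t1)``, and the fuzzy reliability at that
cut is reported in two variants:

* ``"interval"`` (default) — the plain probability mass the fitted model
  assigns to (t1, x(gamma)), i.e. ``F(x(gamma)) - F(t1)``; at gamma = 1
  this is exactly ``S(t1) - S(t2)`` in closed form.
* ``"weighted"`` — the membership-weighted integral
  ``int_{t1}^{x(gamma)} mu(x) f(x) dx`` by adaptive quadrature.

The two differ because the membership weight is at most 1; the interval
variant is the default because it is the quantity the reliability tables
for this model tabulate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .distribution import MKTLParams, mktl_cdf, mktl_pdf

__all__ = ["FuzzyBand", "membership", "gamma_cut_lifetime", "fuzzy_reliability"]


@dataclass(frozen=True)
class FuzzyBand:
    """Ramp membership knots 0 <= t1 < t2 on the data scale."""

    t1: float
    t2: float

    def __post_init__(self) -> None:
        t1, t2 = float(self.t1), float(self.t2)
        if not (math.isfinite(t1) and math.isfinite(t2)):
            raise ValueError("band knots must be finite")
        if not (0.0 <= t1 < t2):
            raise ValueError(f"need 0 <= t1 < t2, got t1={t1}, t2={t2}")
        object.__setattr__(self, "t1", t1)
        object.__setattr__(self, "t2", t2)


def membership(x, band: FuzzyBand):
    """Ramp membership mu(x): 0 below t1, linear between the knots, 1 above t2."""
    x = np.asarray(x, dtype=float)
    out = np.clip((x - band.t1) / (band.t2 - band.t1), 0.0, 1.0)
    return out if out.ndim else float(out)


def gamma_cut_lifetime(gamma: float, band: FuzzyBand) -> float:
    """The lifetime x(gamma) = t1 + gamma (t2 - t1) for gamma in [0, 1]."""
    if not (0.0 <= gamma <= 1.0):
        raise ValueError("gamma must lie in [0, 1]")
    return band.t1 + gamma * (band.t2 - band.t1)


def fuzzy_reliability(
    params: MKTLParams,
    band: FuzzyBand,
    gamma: float,
    variant: str = "interval",
) -> float:
    """Fuzzy reliability at the gamma-cut for a fitted MKTL model.

    ``gamma = 0`` gives 0 in both variants (the integration range is
    empty).  Both variants are nondecreasing in gamma.
    """
    if not (0.0 <= gamma <= 1.0):
        raise ValueError("gamma must lie in [0, 1]")
    if not (band.t2 < 1.0):
        raise ValueError("MKTL fuzzy reliability needs the band inside (0, 1)")
    if gamma == 0.0:
        return 0.0
    x_gamma = gamma_cut_lifetime(gamma, band)
    if variant == "interval":
        return float(mktl_cdf(x_gamma, params) - mktl_cdf(band.t1, params))
    if variant == "weighted":
        value, _ = integrate.quad(
            lambda x: membership(x, band) * mktl_pdf(x, params),
            band.t1,
            x_gamma,
            epsabs=1e-9,
            epsrel=1e-9,
            limit=200,
        )
        return float(value)
    raise ValueError(f"unknown variant {variant!r}; use 'interval' or 'weighted'")
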
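# mktl — the modified Kies Topp–Leone lifetime distribution

`mktl` implements a two-parameter lifetime distribution on the open unit
interval for bounded, rate-like data — daily mortality proportions,
component failure fractions, anything that lives strictly between 0
and 1 — together with the estimation and reliability machinery an
analyst needs around it: maximum-likelihood and Bayesian fitting,
fuzzy reliability under γ-cuts, goodness-of-fit statistics, and a Monte
Carlo harness for bias/MSE/coverage studies of the estimators.

## The model

The Topp–Leone distribution has CDF `G(x; β) = [x(2−x)]^β` on (0, 1)
with shape β > 0.  Feeding it through the modified-Kies generator gives
the **modified Kies Topp–Leone (MKTL)** distribution:

    F(x; θ, β) = 1 − exp{ −[ G(x;β) / (1 − G(x;β)) ]^θ },   0 < x < 1,

with density

    f(x; θ, β) = 2βθ x^{βθ−1} (1−x) (2−x)^{βθ−1}
                 / [1 − x^β(2−x)^β]^{θ+1} · exp{ −[G/(1−G)]^θ }.

Both θ and β are dimensionless shapes.  The hazard `f/S` can be
monotone increasing, decreasing, or bathtub-shaped, which is the point:
the plain Topp–Leone family cannot produce a bathtub on a bounded
support.  The quantile function is closed-form
(`x = 1 − √(1 − G^{1/β})` with `G = w/(1+w)`, `w = (−ln(1−u))^{1/θ}`),
so random variates come from plain inversion and are exactly
reproducible from a seed.

Estimation:

* **MLE** — quasi-Newton on (log θ, log β) with an analytic score, a
  Newton polish, numerical-Hessian standard errors and Wald intervals.
* **Bayesian** — independent Gamma(φ_j, D_j) priors with
  hyperparameters elicited by moment matching (`φ = m²/v`, `D = m/v`)
  from replicates of the MLE, a random-walk Metropolis–Hastings sampler
  on the joint posterior, posterior-mean (squared-error-loss) estimates
  and Chen–Shao HPD intervals.
* **Fuzzy reliability** — a ramp membership μ(x) with knots (t₁, t₂)
  maps a membership degree γ to the lifetime x(γ) = t₁ + γ(t₂−t₁); the
  reliability at that cut is reported as the interval probability
  F(x(γ)) − F(t₁) (default) or as the membership-weighted integral
  ∫ μ(x) f(x) dx.
* **Goodness of fit** — Kolmogorov–Smirnov (with the exact finite-n
  p-value), Cramér–von Mises W and Anderson–Darling A, all through the
  probability integral transform at the fitted parameters.

## Worked example

The package ships the 27 Saudi Arabia COVID-19 daily mortality rates
from August 2021 as a fixture (`mktl.load_covid_mortality()`):

```python
import mktl

fit = mktl.fit_mle(mktl.load_covid_mortality())
print(fit.summary())
```

prints

```
MKTL maximum-likelihood fit (n = 27)
  theta = 3.7666  SE = 0.5535  95% CI (2.6818, 4.8514)
  beta  = 0.7144  SE = 0.0277  95% CI (0.6602, 0.7687)
  log-likelihood = 44.1489
```

so the mortality rates are well described by a sharply peaked MKTL
density (large θ) centred near 0.19.  The goodness-of-fit battery
(`mktl.evaluate_fit`) gives KS = 0.1254 with p = 0.743, W = 0.0536 and
A = 0.3871 — no evidence against the fitted model.  Fuzzy reliability
with band (0.12, 0.25) rises through 0.157 / 0.431 / 0.736 at
γ = 0.3 / 0.6 / 0.9: as the γ-cut widens, more of the band's
probability mass counts as "reliable".

The `examples/` directory holds one short script per capability
(`fit_mortality_data.py`, `bayesian_estimation.py`,
`fuzzy_reliability.py`, `simulation_study.py`,
`distribution_shapes.py`); each builds or loads a small input, runs the
method and explains the numbers it prints.  A thin CLI mirrors them:

```sh
mktl fit covid --method mle --fuzzy 0.12 0.25
mktl simulate --theta 3 --beta 0.5 --n 30 --n 100 --reps 1000 --seed 7
```

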
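# Methods

## Model and support convention

The MKTL distribution composes the Topp–Leone CDF
`G(x; β) = [x(2−x)]^β` with the modified-Kies generator
`F = 1 − exp{−[G/(1−G)]^θ}`.  Because `x(2−x)` reaches 1 at `x = 1`,
the support is the open unit interval, and the package enforces that
convention uniformly: the CDF clamps to 0 below and 1 above the
support, the density and log-likelihood are 0 / −∞ outside, and the
hazard raises a domain error there (a hazard outside the support has no
meaning).  Samples are validated at construction: every observation
must lie strictly inside (0, 1).

Both parameters are dimensionless shapes.  θ governs the modified-Kies
exponent — large θ concentrates the distribution and produces a
monotone increasing hazard, while θ well below 1 bends the hazard into
a bathtub.  β is the Topp–Leone shape of the baseline.

## Numerical evaluation

All core functions work in log space.  The inner ratio is evaluated as
`exp(θ·[ln G − ln(1−G)])` with `ln G = β·ln[x(2−x)]`; `ln[x(2−x)]` uses
`log(x) + log(2−x)` below 0.5 and `log1p(−(1−x)²)` above, which avoids
the catastrophic cancellation the naive form suffers as `x → 1`.
`ln(1−G)` is `log(−expm1(ln G))`.  The closed-form quantile is
rationalised as `x = c / (1 + √(1−c))` with `c = G^{1/β}` so small
quantiles keep full relative precision.  With these forms the
CDF/quantile round trip holds to 1e−10 across the parameter range used
anywhere in the package, the hazard agrees with `f/S` to 1e−10 relative
wherever `S` has not underflowed, and `|F + S − 1| < 1e−12` pointwise.

Tolerances: 1e−10 for inversion identities, 1e−8 for density
normalisation by adaptive quadrature, 1e−9 absolute for the fuzzy
weighted integral.  These sit comfortably inside double precision for
functions this smooth.

Moments are computed by adaptive quadrature of `x^r f(x)` — this is the
canonical path.  A truncated series expansion of the density (expanding
both the exponential and the `(1−G)` power, then the `(2−x)` binomial)
is retained as a cross-check, but the term-wise-integrated series is
divergent: the geometric expansion of `(1−G)^−(s+1)` is valid only
pointwise for `G < 1`, and after integration over the full support the
k-terms do not vanish.  The evaluator detects this through a shell-sum
guard and reports non-convergence rather than returning a partial sum.

## Maximum likelihood

The log-likelihood is the exact sum of log-densities, including the
parameter-free `n·ln 2` and `Σ ln(1−xᵢ)` terms, so the reported value
equals `Σ ln f(xᵢ)` without an arbitrary constant.  The analytic score
is derived from that log-density (per observation, with
`A = ln x + ln(2−x)`, `H = G/(1−G)`, `T = H^θ`):

    ∂ℓ/∂θ = 1/θ + βA − ln(1−G) − T ln H
    ∂ℓ/∂β = 1/β + θA + (θ+1)·A·G/(1−G) − θ·T·A/(1−G)

and is verified against central finite differences to 1e−6 relative in
the test suite; a `use_analytic_grad=False` flag switches the optimiser
to numeric gradients.

Optimisation runs BFGS on (log θ, log β) — positivity for free —
multi-started from (1, 1) and the best point of a coarse 5×5
log-spaced grid, followed by a Newton polish on the raw scale (analytic
score, numerical Hessian) that drives the score norm below 1e−7;
BFGS alone can stall at float-noise level with the norm near 1e−5.
Standard errors are the square roots of the diagonal of the inverse
numerical Hessian (central differences, relative step 1e−4) of the
negative log-likelihood at the optimum; confidence intervals are Wald,
`estimate ± z·SE` with `z = Φ⁻¹((1+level)/2)` and level 0.95 by
default.  Degenerate inputs — fewer than 3 observations, all values
tied, values on the boundary — are rejected with explicit errors.

## Bayesian estimation

Priors are independent gammas, θ ~ Gamma(φ₁, D₁) and β ~ Gamma(φ₂, D₂)
(shape/rate).  Hyperparameters are elicited by exact moment matching
from a B×2 matrix of estimate replicates: `φ = mean²/var`,
`D = mean/var` per column, so the elicited prior reproduces the
replicate mean and variance.  Two replicate sources are provided:

* `covariance` (default) — B draws from the normal approximation
  N(estimate, covariance) of the MLE, truncated to the positive
  quadrant.  This centres the prior on the estimate itself.
* `bootstrap` — B parametric-bootstrap refits at the MLE.  Bootstrap
  replicates inherit the finite-sample upward bias of the θ MLE
  (roughly +5% at n = 27), which shifts the elicited prior — and hence
  the posterior mean — upward by a comparable amount.  The covariance
  source avoids importing that bias into the prior, which is why it is
  the default; both remain available.

The sampler is a random-walk Metropolis–Hastings chain on (θ, β) with a
bivariate normal proposal; the `"auto"` proposal covariance is the MLE
covariance scaled by 2.4²/2 (the standard optimal-scaling factor for a
2-dimensional Gaussian target), which yields acceptance rates around
0.2–0.3 on the packaged data.  Proposals with a non-positive component
are rejected outright (zero prior mass).  Defaults are 10 000
iterations with 2 000 burn-in — enough for a posterior-mean Monte Carlo
error near 0.01 on θ for the packaged data — and every chain is exactly
reproducible from an integer seed.  Point estimates are posterior means
(the Bayes rule under squared error loss), computed as chain averages.
HPD intervals use the Chen–Shao order-statistic method: sort the draws,
slide a window of ⌈level·M⌉ consecutive order statistics, return the
narrowest window, leftmost on ties.

## Fuzzy reliability

The membership function is the linear ramp: 0 below t₁, `(x−t₁)/(t₂−t₁)`
between the knots, 1 above t₂.  A membership degree γ ∈ [0, 1] maps to
the γ-cut lifetime `x(γ) = t₁ + γ(t₂−t₁)`.  Two reliability variants
are exposed because the membership-weighted definition and the values
such analyses conventionally tabulate differ:

* `interval` (default) — `F(x(γ)) − F(t₁) = S(t₁) − S(x(γ))`, the plain
  probability mass of `(t₁, x(γ))`.  At γ = 1 this equals the
  closed-form `S(t₁) − S(t₂)` exactly.
* `weighted` — `∫_{t₁}^{x(γ)} μ(x) f(x) dx` by adaptive quadrature.
  Since μ ≤ 1 on the range, the weighted value never exceeds the
  interval value.

Both are 0 at γ = 0 and nondecreasing in γ.  No membership shapes other
than the ramp are supported.

## Goodness of fit

All three statistics act on the probability integral transform
`u₍ᵢ₎ = F(x₍ᵢ₎)` at the *fitted* parameters — the usual "fit
statistics" convention, which makes the formal null distributions
approximate; the reports say so.  KS is the maximum order-statistic gap
with the exact finite-n p-value (`scipy.stats.kstwo`); W is
`1/(12n) + Σ (u₍ᵢ₎ − (2i−1)/(2n))²`; A is
`−n − (1/n) Σ (2i−1)[ln u₍ᵢ₎ + ln(1 − u₍ₙ₊₁₋ᵢ₎)]`.  Ties in the data
produce a warning but the statistics remain computable (stable sort).

## Monte Carlo harness

One master seed spawns an independent `SeedSequence` stream per
replicate, so a study is reproducible bit for bit and replicates never
share a stream.  Each replicate draws an inversion sample, fits the
MLE, and evaluates the parameters plus any derived quantities — S(t),
hr(t) at configured time points and fuzzy reliabilities for configured
bands — at the fitted values.  Aggregates per quantity: average bias,
MSE, the averaged 95% interval bounds, and coverage.  Intervals for
derived quantities under MLE use the delta method (numerical gradient
against the fit covariance); each quantity gets its own interval rather
than a copy of the parameter's.  Replicates whose fit fails are dropped
and counted; a cell with more than 5% failures is flagged.

Bayesian cells are costly (one chain per replicate), so the harness
subsamples the Bayesian replicates (default 500) with a config
override, and elicits the gamma prior once per cell by moment-matching
the pool of that cell's MLE replicate estimates — the same moment
formulas, with B equal to the number of MLE replicates.  Bayesian
interval bounds are per-replicate HPD intervals.

Default study sizes in the tests and the acceptance script are 1 500 –
2 000 replicates per cell, which puts the Monte Carlo standard error of
a bias estimate near 0.005 at n = 100 and keeps a full three-cell study
under two minutes; the harness itself accepts any `n_reps ≥ 2`.

Validation: the harness attains the information bound.  At
(θ, β) = (1.5, 1.5), n = 100, 1 500 replicates give
Abias(θ) ≈ 0.022, MSE(θ) ≈ 0.0135, averaged Wald bounds
(1.299, 1.744) and coverage 94.5% — and the empirical MSE matches
[I⁻¹]_θθ/1 at this design.  At (θ, β) = (3, 0.5), n = 100 the same
triple consistency holds (empirical MSE ≈ 0.052 = CRLB, coverage
≈ 95%); no unbiased-estimator MSE below ≈ 0.052 is attainable at that
design, a bound worth keeping in mind when comparing against external
tabulations of this cell.

## What the generator does and does not emulate

Synthetic samples are ideal i.i.d. MKTL draws by exact inversion.  They
contain no measurement rounding, no serial dependence, no censoring and
no covariate structure — all present in real surveillance data (the
packaged mortality series is a smoothed daily rate and is certainly
autocorrelated in time).  Passing tests therefore demonstrate
correctness of the estimators under the model's own assumptions, not
robustness to their violation.

## Known limitations

* KS/W/A p-value calibration under estimated parameters is approximate
  (no parametric-bootstrap calibration is provided).
* The Bayesian sampler is a plain random-walk MH chain; no adaptation,
  no multiple chains, no R-hat diagnostics beyond the acceptance rate.
* Quantiles extremely deep in the tails (below ≈ 1e−300 on the x scale,
  reachable for θ ≪ 1) underflow double precision.
* The series form of the moments is documented divergent (above);
  moments are quadrature-only in practice.
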
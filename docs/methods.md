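# Methods

## Model

The ex-Gaussian distribution is the convolution of a Gaussian
`N(μ, σ²)` and an exponential with mean `τ` (all in ms):

```
f(x; μ, σ, τ) = 1/(2τ) · exp( (2μ + σ²/τ − 2x)/(2τ) ) · erfc(u),
u = (μ + σ²/τ − x) / (√2 σ)

F(x) = ½ erfc(−v) − ½ exp( σ²/(2τ²) − (x−μ)/τ ) · erfc(−v + σ/(√2 τ)),
v = (x−μ)/(√2 σ)
```

Moments: `M = μ + τ`, `S² = σ² + τ²`,
`K = 2 τ³ / S³`. The skewness is bounded by the exponential's value of 2,
so the moment map is invertible exactly when `0 < K < 2`, via
`λ = (K/2)^(1/3)`, `τ = Sλ`, `σ = S√(1−λ²)`, `μ = M − Sλ`. The
standardized family `f_λ` (mean 0, variance 1) is obtained by the
substitution `μ = −λ, σ = √(1−λ²), τ = λ` into `f` — we evaluate it by
that substitution rather than by a separately coded formula, so the two
parameterizations cannot drift apart.

Degenerate limits are excluded by construction: `τ = 0` (pure Gaussian)
makes the density formula singular and `σ = 0` (pure exponential)
divides by zero inside `erfc`; constructors raise with a message naming
the limit. Users wanting the Gaussian boundary should call `gauss_pdf`
/ `gauss_cdf` directly.

## Numerical evaluation

`exp(·)·erfc(·)` overflows once the erfc argument is moderately large
(for RT-scale parameters this happens a few hundred ms into the left
tail). All densities are therefore computed in log space with

```
log erfc(u) = log erfcx(u) − u²   (u > 0),   log erfc(u) directly (u ≤ 0),
```

`erfcx` being the scaled complementary error function. The same split
stabilizes the second CDF term, whose exponent cancels analytically
against the erfc bound (the term behaves as `½ erfcx(w) e^{−v²}` deep in
the left tail). Log-densities are finite over `[−10⁴, 10⁵]` ms for
typical fitted parameters, which is what keeps maximum likelihood usable
on samples containing extreme outliers.

Gradients of the log-density use
`d log erfc(u)/du = −(2/√π)/erfcx(u)`, finite for every `u`; both
objective gradients are analytic and are tested against central finite
differences at 10 randomized parameter points (relative tolerance 1e−6).

Quantiles are found by bracketed root finding on the CDF: initial
bracket `[M − 10S, M + 20S]`, doubled outward (≤ 60 times) until the
target probability is enclosed, then bisection with secant acceleration
to 1e−11 in probability. The root finder is deterministic and
derivative-free; the secant proposal is rejected in favour of the
midpoint whenever it falls within 1% of a bracket edge, which prevents
stagnation on flat tails.

Integrals (normalization and moment checks) use composite fixed-order
Gauss–Legendre quadrature, order 64 per panel, over `[M − 12S, M + 40S]`;
the right truncation point leaves tail mass far below 1e−10 for every
asymmetry we test (λ ≤ 0.95).

## Fitting

*Method of moments* inverts the moment map at the population (÷N) sample
moments; population rather than ÷(N−1) moments because the estimating
equations equate sample to distribution moments directly. It fails —
deliberately, with `SkewnessRangeError` — when the sample skewness is
outside (0, 2), as routinely happens on RT data with a few extreme
points.

*Least squares (minSQR)* minimizes
`Σ_bins (density_i − f(center_i))²` on an equal-width,
density-normalized histogram. Density normalization makes the objective
scale-free in N; bins default to `round(2√N)`. The histogram’s bin
centers stand in for the bin averages of `f`, adequate at the default
resolution (the bin-scan tests quantify the sensitivity).

*Maximum likelihood (maxLKHD)* maximizes `Σ log f(x_i)`.

Both gradient methods start from the moment estimate, falling back to
the λ = 0.8 moment inversion `(M − 0.8S, 0.6S, 0.8S)` when moments are
inapplicable — the failure regime is precisely high skew, so a high-λ
start is appropriate.

The optimizer is plain steepest descent/ascent with an adaptive step:
`p ← p ± η·grad`, η × 1.5 after an accepted step, halved after a
rejected one, and halved whenever a step would drive σ or τ to zero or
below (no reparameterization). The first step is normalized to move
about `step0 = 1e−3·S` ms regardless of objective scale. Stopping is on
the gradient norm falling below `tol` (default 1e−8) times an
objective-scale yardstick: `max(1, |lnL|)` for likelihood, and the fixed
scale `Σ densities²` for least squares. The fixed scale matters: the
least-squares objective itself tends to ~0 at the optimum, so a
current-value yardstick stops far too early (we observed σ off by ~8 ms
against a tightly converged quasi-Newton reference; with the fixed scale
the two agree to <0.01 ms). The iteration cap is 20 000; hitting it
returns `converged=False` rather than raising, so bootstrap replicates
can proceed with best-effort fits (counted in the report).

Steepest descent was chosen over quasi-Newton deliberately: at desk
scale it is fast enough (a 5000-point maximum-likelihood fit converges
in tens of iterations from the moments start), trivially robust, and its
only state is the step scale. An L-BFGS fit of the same objective is
used in the tests as an independent cross-check (agreement ±0.01 in each
parameter), never as the implementation.

## Goodness of fit and trimming

The KS statistic is the exact sup-distance between the empirical
distribution function and the fitted CDF,
`D = max_i max(i/N − F(x_(i)), F(x_(i)) − (i−1)/N)`. Reports carry both
`D` and the scaled convention `N·D`; all decisions use `D`, and the
p-value is invariant to the scaling because data and replicates share N.

The bootstrap p-value regenerates `B` samples of size N from the fitted
parameters, refits each with the *same* procedure (including the same
bin rule for minSQR), computes each replicate's KS distance to its own
refit, and reports the plain fraction `#{D_b ≥ D_emp}/B` — so p = 0 is
possible and p lies on the `1/B` grid. No +1 smoothing. `B` defaults to
1000; the calibration tests use B = 200.

Trimming is single-pass: one maximum-likelihood pre-fit, cutoffs at the
fitted `q` and `1−q` quantiles (default q = 0.001), strict-inequality
removal (points exactly at a cutoff are kept — immaterial for continuous
data, fixed for determinism). No re-fit-and-re-trim iteration.

## Synthetic data and study conditions

No empirical RT datasets ship with the package; the seeded generator
(`exgauss_sample`, numpy PCG64: ziggurat Gaussian plus inverse-transform
exponential) stands in for them. It emulates i.i.d. ex-Gaussian RTs
only: no sequential effects, no response censoring at a deadline, no
contaminant process, no subject heterogeneity. Passing tests therefore
certify the *estimators and the inference machinery*, not the adequacy
of the ex-Gaussian for any particular experiment — on real data the
deadline-censoring issue in particular can depress bootstrap p-values
for strongly right-skewed (elderly-participant-like) conditions.

Simulation conditions used by the test battery, chosen once as
RT-realistic values:

- recovery studies: (μ, σ, τ) = (500, 50, 150) ms — mid-range of
  published young-adult fits — at n = 5000, 50 seeds, estimates required
  within 3 Monte-Carlo SE of truth;
- estimator consistency: n ∈ {500, 2000, 8000}, 20 seeds;
- bootstrap calibration: n = 300 (a typical single-condition session),
  100 runs at B = 200, batch KS-against-uniform at the 1% level. At
  substantially smaller n (~150) the refit bootstrap is visibly
  miscalibrated (mean p ≈ 0.39) — a known small-sample property of this
  class of procedures, not an implementation artifact;
- histogram sensitivity: n = 1200 at (450, 45, 105) ms, comparing the
  spread of τ̂ over 5–20 bins vs 40–120 bins.

## Limitations

- The least-squares objective compares `f` at bin centers, not bin
  averages; at very coarse resolutions this adds bias (visible in the
  bin-scan below ~20 bins).
- Steepest descent converges linearly; pathological near-degenerate
  samples may hit the iteration cap and return `converged=False`.
- No standard errors or confidence intervals on fitted parameters are
  produced, and no analytic KS p-values (the bootstrap null is the
  point).
- Units are milliseconds throughout and never rescaled.
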
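# Methods

## The model

`truthfx` formalizes the repetition-based truth effect — people judge
repeated statements as more likely true than new ones — as a hierarchical
Bayesian probit model. Each statement *i* carries a latent plausibility
`p_i`. A truth judgment arises by thresholding a noisy latent value,

    y* ~ Normal(p_i, sigma),   judge "true"  iff  y* > c,

which is equivalent to a probit model with response probability
`Phi((p_i - c) / sigma)`. Following the framework this package implements,
the link is deliberately *non-standardized*: `sigma = 0.5` and threshold
`c = 0.5`, so plausibilities near 0.5 map to response probabilities near
50% and the interesting range of `p` is roughly [-1, 2].

Repetition adds a fluency increment `f(m, p_i)` to the latent plausibility.
Four variants encode competing hypotheses about how fluency interacts with
plausibility:

| variant | fluency function            | interpretation                          |
|---------|-----------------------------|-----------------------------------------|
| M1      | `f = m`                     | constant shift (no interaction)         |
| M2      | `f = m p`                   | larger for plausible statements         |
| M3      | `f = m (1 - p)`             | larger for implausible statements       |
| M4      | `f = 2m (0.5 - |p - 0.5|)`  | triangular, peaked at medium plausibility |

The functions are applied literally outside [0, 1]; M2–M4 then produce
negative shifts, which matters when plausibilities span [-1, 2].

For trial-level data (participant *j* judging statement *i*), the likelihood
is Bernoulli with

    theta_ij = Phi((p_i + R_ij (f(m, p_i) + v_i) + u_j - c) / sigma),

where `R_ij` indicates repetition, `v_i` is an item-specific truth-effect
residual, and `u_j` a participant response bias. Hierarchical priors:
`p_i ~ Normal(mu_p, sigma_p)` with `mu_p ~ Normal(0.5, 1)` (uniform over the
implied baseline response probability) and half-Normal(1) priors on
`sigma_p`, `sigma_u`, `sigma_v`. The fluency parameter has a positive-
truncated normal prior whose mean is *calibrated per variant* (below) with
SD 0.1 by default (0.05/0.25 available for sensitivity analysis, as are
model-invariant truncated-normal priors via `PriorSpec`).

A key scientific point the package makes checkable: the constant-shift
variant is additive on the *probit* scale (`probit(theta_rep) -
probit(theta_new) = m / sigma` for every statement) yet produces an
inverted-U interaction on the *probability* scale, and a different
interaction again under a logit transform. `transform_scale` exposes these
transformations; the logit comparison uses the plain (unscaled) log-odds,
the simplest choice given that any monotone rescaling preserves the
qualitative point.

## Prior calibration by implied effect size

The same `m` implies different average truth effects under the four
variants, so equal priors on `m` would covertly favor some variants. The
calibration module sweeps `m` over 0.01–0.50 (step 0.01), computes the
implied average truth effect per variant, and matches each variant's prior
mean to a common target (default 0.04).

The implied effect is the mean of `theta_rep - theta_new` over the
plausibility distribution. The default calibration distribution is
`p ~ Normal(0.5, 0.75)`, integrated by Gauss–Hermite quadrature. A uniform
[-1, 2] span is *not* usable as the default: outside [0, 1] the M2–M4
shifts turn negative and the average effect nearly cancels (the triangular
variant caps at ~0.016), putting moderate targets out of reach. Under the
normal default all four variants reach the 0.04 target, with matched values
0.09 / 0.21 / 0.16 / 0.31 (constant / increasing / decreasing /
triangular) — the same ordering as the conventional reference values
0.11 / 0.27 / 0.19 / 0.38 that `PriorSpec.for_variant` ships as defaults.
Exact matched values are sensitive to the assumed plausibility
distribution; both the analytic and a simulation-based mode (trial-level
generation with binomial noise) are provided, and they agree within
Monte-Carlo error.

## Sampling

No probabilistic-programming backend is used; the posterior is explored by
an in-package adaptive Hamiltonian Monte Carlo sampler (`truthfx.hmc`) with
analytic gradients of the joint density, fused into a single numba kernel
over trials. All chains advance in lockstep so one batched gradient
evaluation serves every chain. Warmup uses dual averaging of the step size
(target acceptance 0.8) and a diagonal mass matrix re-estimated at 40% and
80% of warmup; trajectory lengths are jittered uniformly between half and
all of `max_leapfrog` (default 32) to avoid resonance.

Parameterization: scales and `m` are log-transformed (Jacobians included in
the target). The plausibilities `p` and biases `u` are *centered*: with
~100+ Bernoulli trials per statement and per participant the likelihood
dominates, and the centered geometry mixes far better than the non-centered
one (which, in internal checks, left R-hat around 1.06 on the hyper-means at
desk-scale run lengths versus < 1.01 centered). The weakly identified item
residuals `v` remain non-centered. The known cost: when a variance component
is truly zero (e.g., no participant heterogeneity), the posterior of that
scale piles up at zero and its own R-hat degrades — the concentration
near zero is still correctly reported, and the fit is flagged rather than
silently returned.

Run profiles: the full-analysis default is 8 chains × 1,000 warmup +
10,000 draws; `McmcSettings.reduced()` (4 × 500 + 1,500) is the desk-scale
profile used throughout the tests. Convergence is assessed with arviz
(rank-normalized R-hat, ESS) against the R-hat < 1.02 gate; non-convergence
raises a warning and marks the fit.

Pointwise log-likelihood matrices (for PSIS-LOO) are stored on draws
thinned to at most `max_loglik_draws` (default 1,000) per chain, in float32,
to bound memory on long runs.

## Model comparison

Log marginal likelihoods are estimated by iterative optimal-bridge sampling
on the unconstrained space: half the posterior draws fit a moment-matched
multivariate normal proposal, the other half enter the Meng–Wong fixed
point (tolerance 1e-10, cap 1,000 iterations), with the asymptotic
relative-MSE error estimate (posterior-side term corrected for
autocorrelation via an initial-positive-sequence spectral estimate).
Validation is against the conjugate Beta–Bernoulli closed form: errors are
below 0.01 nats on single runs and below 0.02 nats in the mean across 20
seeds. A prior-only fit short-circuits to exactly zero (the prior
integrates to one). Bayes factors are `exp(lml_a - lml_b)` (log-scale
variant provided); posterior model probabilities use log-sum-exp
normalization.

PSIS-LOO ELPD (sum-over-observations scale) comes from arviz, with
per-observation Pareto-k diagnostics and paired-difference standard errors
for pairwise comparisons. On a tiny table, PSIS-LOO agrees with exact
brute-force leave-one-out refits within combined error (tested).

## The bootstrap midpoint test and its power

The constant-fluency variant predicts that the per-statement truth effect
`R - N`, regressed quadratically on perceived truth `(R + N) / 2`, peaks at
exactly .50. The test fits the quadratic by OLS, takes the vertex
`-b1 / (2 b2)`, and builds a percentile CI from 5,000 statement-level
bootstrap resamples; the midpoint hypothesis is rejected when .50 falls
outside. Design choices: percentile (not BCa) intervals; resamples whose
quadratic opens upward carry no interior peak and are excluded from the
percentile computation (their count is reported, and the result is flagged
unreliable beyond 50%); degenerate proportions enter the arithmetic as-is.
The preferred alternative x-axis — the new-statement proportion `N` alone —
is available via `x_mode="new_only"`.

The power study generates datasets per variant and `m` in {0.1, 0.2, 0.4}:
80 statements on the uniform [-1, 2] grid with 250 binomial judgments per
statement per condition (no item/participant residuals) — roughly a
500-participant study with half-repetition, stated here as the package's
generation recipe since the per-statement sample size of such simulations
is conventionally left implicit. The bootstrap path is fully vectorized
(resample count matrices × per-item moment vectors, closed-form 3×3 normal
equations), so the full 12-cell study at 1,000 datasets × 5,000 resamples
runs in about two minutes on one CPU.

Measured rates under this recipe (1,000 datasets per cell): the constant
variant stays near (slightly above) the nominal 5% level at all `m`
(≈ 5.8 / 5.4 / 9.7%), both linear variants reject essentially always
(≈ 100%), and the triangular variant is hard to detect at small `m`
(≈ 8 / 58 / 100%). The low-`m` triangular cells are the recipe-sensitive
ones: their rejection rates move substantially with the per-statement
sample size, and no binomial sample size reproduces published mid-power
values for both `m = 0.1` and `m = 0.2` simultaneously, so they should be
read qualitatively (low power, rising in `m`) rather than as precise
constants.

## Synthetic data: what it does and does not emulate

The trial-level simulator reproduces the standard truth-effect paradigm:
every participant judges all statements, a random half repeated,
counterbalanced in complementary pairs so each statement is repeated for
half the participants (±1). Plausibilities come from the uniform [-1, 2]
grid or the hierarchical normal; participant bias and item residuals are
zero-mean normals (defaults in recovery tests: sigma_u = 0.3, sigma_v = 0.1,
near values typical of trial-level reanalyses). It does not emulate:
exposure-phase memory processes, response times, statement-content
covariates, participant exclusions, or non-binary response formats.
Passing recovery and selection tests therefore show the *inferential
machinery* is sound under the model's own assumptions, not that the model
is true of any particular dataset.

## Numerical choices

- Normal CDF/quantile via scipy special functions; analytic identities are
  tested at 1e-10–1e-12.
- In the likelihood kernel, the probit argument is clamped at ±37 (where
  the normal CDF saturates in double precision); `log Phi` uses `erfc` with
  a `log1p` branch for large arguments.
- Non-finite log densities (overflowing warmup positions) are mapped to
  -inf and rejected by the sampler.
- Bootstrap resamples with near-singular normal equations (all-equal x
  after resampling) are treated as peakless and excluded, like upward
  parabolas.
- Ties in calibration grid matching break toward the smaller `m`.

## Known limitations

- The sampler is a fixed-length jittered HMC, not NUTS; pathological
  posteriors (true zero variance components) mix slowly at the scale
  posterior, though point summaries remain usable and the fit is flagged.
- Bridge-sampling MC error on full hierarchical fits at desk-scale draw
  counts is of order 1 nat; model-probability statements are reliable only
  when log-marginal separations are large (as they are in the shipped
  selection tests). Increase draws for fine comparisons.
- PSIS-LOO on very large tables is memory-bound by the pointwise
  log-likelihood matrix; the thinning cap trades LOO precision for memory.
- The exact published mid-power rejection rates of the triangular variant
  are not reproducible without knowing the original simulated sample size
  (see above); all other cells reproduce within Monte-Carlo tolerance.
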
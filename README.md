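# truthfx

Bayesian modeling of the **repetition-based truth effect** — the robust
finding that people judge repeated statements as more likely true than new
ones. The package is aimed at cognition researchers who want to go beyond
plotting truth-effect curves and actually *fit and compare* competing
hypotheses about how repetition interacts with a statement's plausibility.

## The model

Each statement *i* has a latent plausibility `p_i` on a probit scale. A
binary truth judgment thresholds a noisy latent value, which is equivalent
to a probit response model with a non-standardized link (scale σ = 0.5,
threshold 0.5):

```
θ_new = Φ((p_i − 0.5) / σ)
θ_rep = Φ((p_i + f(m, p_i) + v_i − 0.5) / σ)
```

Repetition adds a fluency increment `f(m, p)`; four variants encode the
competing hypotheses:

- **M1** `f = m` — constant shift (no plausibility interaction),
- **M2** `f = m·p` — larger for plausible statements,
- **M3** `f = m·(1 − p)` — larger for implausible statements,
- **M4** `f = 2m·(0.5 − |p − 0.5|)` — triangular, peaked at medium plausibility.

For trial-level data the likelihood is Bernoulli with crossed random
effects: statement plausibilities `p_i ~ Normal(μ_p, σ_p)`, participant
response biases `u_j ~ Normal(0, σ_u)`, and item-specific truth-effect
residuals `v_i ~ Normal(0, σ_v)`. Priors on `m` are positive-truncated
normals whose means are **calibrated per variant** so that all four models
imply the same average truth effect (the `calibration` module).

Components:

- `core` — exact truth-effect curves, scale transformations (probability /
  probit / logit), the additivity identity `Φ⁻¹(θ_rep) − Φ⁻¹(θ_new) = m/σ`
  of the constant-shift variant;
- `simulate` — trial-level generator (counterbalanced half-repetition) and
  the aggregated binomial generator for power studies;
- `inference` — adaptive HMC (in-package, numba-accelerated analytic
  gradients) with arviz diagnostics;
- `comparison` — bridge-sampling marginal likelihoods, Bayes factors,
  posterior model probabilities, PSIS-LOO;
- `peak_test` — the quadratic-regression bootstrap midpoint test and its
  Monte-Carlo power study;
- `cli` — `truthfx curves|simulate|fit|compare|calibrate|power|peaktest`.

See `docs/methods.md` for assumptions, parameter defaults, and numerical
choices.

## Worked example

Simulate a constant-fluency study (40 statements spanning plausibility
−1…2, 150 participants, m = 0.25, participant SD 0.3), fit all four
variants, and compare them:

```python
import numpy as np
from truthfx import (DesignSpec, McmcSettings, simulate_dataset, fit_model,
                     posterior_summary, compare_models, summarize_items,
                     bootstrap_peak_ci)

design = DesignSpec(n_statements=40, n_participants=150, sigma_u=0.3,
                    sigma_v=0.05, plausibility_source="grid_uniform", seed=12)
trials, params = simulate_dataset(design, "M1", 0.25)      # 6,000 trials

settings = lambda s: McmcSettings(chains=2, warmup=300, draws=700,
                                  max_leapfrog=16, seed=s)
fits = {v: fit_model(trials, v, settings=settings(10 + v)) for v in (1, 2, 3, 4)}

print(posterior_summary(fits[1]).round(3))
res = compare_models(fits, rng=3)
print({k.name: round(p, 3) for k, p in res.posterior_probs.items()})

pk = bootstrap_peak_ci(summarize_items(trials), rng=4)
print(f"peak {pk.peak:.3f}, CI [{pk.ci_lo:.3f}, {pk.ci_hi:.3f}], reject={pk.reject}")
```

Output:

```
          mean     sd  hdi_lo  hdi_hi
m        0.225  0.026   0.174   0.276
mu_p     0.525  0.163   0.198   0.834
sigma_p  0.986  0.127   0.730   1.212
sigma_u  0.281  0.021   0.241   0.322
sigma_v  0.048  0.034   0.000   0.113
var_u    0.077  0.008   0.061   0.092
var_v    0.003  0.004   0.000   0.010
{'M1': 1.0, 'M2': 0.0, 'M3': 0.0, 'M4': 0.0}
peak 0.502, CI [0.479, 0.521], reject=False
```

The generating value m = 0.25 sits inside the 95% HDI [0.174, 0.276]; the
constant-shift variant M1 wins the bridge-sampling model comparison
decisively; and the bootstrap midpoint test does what it should under M1 —
the quadratic peak of the truth effect against perceived truth `(R+N)/2`
lands at .50 and the midpoint is not rejected.

Fitting real data works the same way from a CSV with columns
`participant_id, statement_id, repeated, judgment`:

```
truthfx fit --data trials.csv --model 1 --seed 1 --out fit_m1.json
truthfx compare --data trials.csv --models 1,2,3,4 --seed 1 --out compare.json
```

For a full-scale reanalysis of a deposited dataset, map its columns onto the
schema above (the adapter is deliberately schema-driven: rename columns when
exporting the deposit to CSV) and pass a config with the full run profile:

```yaml
# full.yaml — full-analysis MCMC profile
mcmc:
  chains: 8
  warmup: 1000
  draws: 10000
```

```
truthfx compare --data trials.csv --models 1,2,3,4 --method both \
    --config full.yaml --seed 1 --out reanalysis.json
```

Expect hours of sampling at that profile; the desk-scale profiles used in
the test suite finish in minutes.

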
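# Methods

## The observation model

Each delivered pellet is a single categorical trial with nine outcomes: one
of the 8 fish in the cage consumes it, or nobody does and it sinks through
the net (feed waste). Within a feeding trial the outcome probabilities are
assumed constant — the fish are not near satiation at the rations used, so
there is no within-meal slowdown — which makes the per-trial outcome counts
multinomial and lets the likelihood factor over pellets.

Fish scores are linear (see the README for the full predictor). Two details
matter:

**Gauge fixing.** A softmax over 9 free scores is invariant to adding a
constant; the model removes this degeneracy by defining the not-consumed
score as the negative sum of the eight fish scores. This couples the overall
level of fish scores to the waste probability: a cage of eager fish (high
scores) wastes almost nothing, a reluctant cage wastes a lot. It also means
cage-level terms (diet intercepts, replicate effects) move only the
fish-vs-waste balance, not fish-vs-fish shares, so they are informed
essentially by per-trial waste counts and are weakly identified when waste
is rare. The wide posteriors on the diet intercepts are a property of the
design, not a sampler failure.

**Exponent sign.** Scores enter the softmax with a positive exponent:
larger score = greater willingness to consume. This is the convention under
which a negative stress slope means stress suppresses feeding.

**Collinearity and variants.** Temperature falls and boat traffic thins
together over the late-summer-to-autumn season (r ≈ 0.83 in the emulated
design), so their effects cannot be separated. Two model variants are
fitted — `stress` (drops T, T²) and `temperature` (drops S) — and compared
by PSIS-LOO. The package treats variant choice as the user's: predictive
accuracy alone typically cannot distinguish them, and the biologically
interpretable variant (stress) is the sensible default given that a thermal
optimum below the observed temperature range contradicts the species'
physiology.

## Covariates

- `L2` — squared structural length `(LT · δ)²` in cm², δ = 0.148: ingestion
  is expected to scale with body surface.
- `T` — water temperature in °C; enters as standardized T plus the *square
  of the standardized value* (the parabola is parameterized on the
  standardized scale, keeping its vertex interpretable there).
- `S` — motorised boats passing the navigation channel during the trial; a
  stress proxy.
- `R` — number of pellets delivered in the trial. The delivered count (not
  the percentage of plan) is the covariate; the two are affinely related
  within a cage so only the interpretation of the slope differs.

All four are standardized to mean 0, sd 1 (sample sd, n−1 denominator),
L2 over the 48 fish and T/S/R over the 48 trials.

## Priors and sampling

Priors are weakly informative on the standardized scale: Normal(0, 1) on
the intercept, diet offsets and slopes; half-Normal(0, 1) on σ_Fish and
σ_Replicate. Both random-effect vectors use the non-centred
parameterization (unit-normal latents scaled by their σ), and the σs are
sampled on the log scale with the Jacobian correction — the standard
remedies for funnel geometry. Prior scales are exposed via `PriorSpec`.

The sampler (`feedshare._hmc`) is adaptive Hamiltonian Monte Carlo with
analytic gradients: dual-averaging step-size adaptation to a 0.8 target
acceptance, a diagonal metric estimated over expanding warmup windows, and
jittered trajectory lengths (simulation length 2.5 in metric units, capped
at 64 leapfrog steps). The likelihood and its gradient are computed from the
per-trial outcome-count sufficient statistics, so one gradient evaluation is
a few operations on a 48×9 array and a full 3 × (2,000 + 2,000) run takes
roughly a minute on one CPU. The default protocol is 3 chains × 2,000
post-warmup draws after 2,000 warmup iterations.

Convergence contract: R-hat < 1.01 and bulk ESS > 400 on every parameter
(fixed effects, dispersions and all individual random effects), no more than
1 % divergent transitions. Violations set warning flags on the result object
rather than raising, so degenerate fits remain inspectable. At the default
protocol on default synthetic data the fits converge cleanly (R-hat ≈ 1.005,
ESS > 1,500, zero divergences).

Per-pellet log-likelihoods are stored for every draw; PSIS-LOO (elpd_loo,
p_loo, looic, Pareto-k) is computed via arviz, and pairwise comparisons
report the elpd difference with its paired standard error, declaring
"indistinguishable" when |Δelpd| < 2 se.

## The synthetic-data generator

The generator emulates the study design so every downstream stage is
testable with known ground truth:

- 6 cages × 8 fish; total length ~ Normal(57.3, 3.2) cm truncated at zero.
- 8 trials per cage across a 92-day window (early August to early
  November). Temperature follows a half-cosine cooling trajectory from
  27.6 °C down to 21.8 °C with 0.15 °C observation noise; replicate days are
  shared across cages up to a ±2-day jitter.
- Boat counts are Poisson with log-rate affine in standardized temperature.
  The slope is solved (moment identity + Brent root-finding) so the model
  correlation with temperature equals the 0.83 target; the intercept fixes
  the mean count at 15 boats per trial, a plausible marina traffic level.
- Diet levels 60/75/90 % are assigned two cages each; the delivered ration
  is uniform on 10–80 % of a planned 40 pellets per trial. The planned count
  reflects the feeder's 4 pellets/min rate over a meal-scale trial; it is a
  free design parameter (`planned_pellets_base`).
- Pellet outcomes are drawn i.i.d. within a trial from the score model via
  the same likelihood code the sampler uses, with fish and replicate
  effects drawn from their dispersions.

Default ground-truth coefficients are the posterior medians of the fitted
stress-variant model (`REFERENCE_MEDIANS`): β0 = 0.266, σ_Fish = 0.431,
σ_Replicate = 0.183, βL2 = 0.101, βS = −0.104, βR = −0.050, diet offsets
0 / −0.072 / −0.136. Under these values the generated waste fraction lands
in the single-digit percent range, consistent with the observed 4–7 %.

What the generator does *not* emulate: within-meal temporal structure
(satiation slowdown, pellet sink-time dynamics), social interaction beyond
what the static fish effects encode, stress acclimation over the season,
tag loss, or observation error in consumer identification. Passing recovery
tests therefore demonstrates that the inference machinery is self-consistent
at the study's design and signal strength — not that real feeding data meet
the model's assumptions.

## Verification strategy and problem sizes

- The vectorized log-likelihood is checked against a straight-loop
  per-pellet recomputation (plain Python floats) to 1e-10, and against the
  multinomial log-pmf up to the combinatorial coefficient.
- Normalization, score-gauge and conservation invariants are property
  tests (softmax sums to 1, score vectors sum to 0, per-trial expected
  counts sum to delivered pellets, waste probability strictly decreasing in
  any common score shift).
- Parameter recovery runs 6 seeded replicates of the full design at the
  reference truth with ~40 delivered pellets per trial, fitting 2 chains ×
  600 draws after 600 warmup each; pooled over the three focal parameters
  (σ_Fish, σ_Replicate, β_S), 90 % intervals must cover the truth ≥ 80 % of
  the time, and estimated fish effects must rank-correlate with the true
  ones above 0.8. These sizes keep the whole suite at ~2 minutes; the same
  harness scales to 20 seeds at the full 3 × 2,000 protocol by changing
  arguments.
- The σ_Replicate margin is the tightest: trial-level effects are informed
  mainly by waste counts (see gauge fixing above), so at low waste rates
  its posterior is prior-sensitive and occasional interval misses at a fixed
  truth are expected even for a correct implementation.

## The variance partition's scale

The fish-level share of residual variability is computed as `a / (a + b)`
on the dispersion values exactly as supplied. The reference dispersion
medians (0.431, 0.183) yield 70.2 % under this as-is ratio; squaring them
first (a genuinely variance-scale partition of standard deviations) would
give 84.7 % instead. The tabulated values are labelled standard deviations
but the headline share arises from the unsquared ratio, so the as-is ratio
is the default and the squared alternative is available behind
`variance_partition(..., squared=True)`. Users applying the function to
their own fits should pass whichever scale they intend consistently.

## Numerical choices

- Softmax and log-softmax use max-subtraction; non-finite leapfrog states
  count as divergent and are never accepted.
- Standardization rejects zero-variance covariates; validation rejects
  structurally broken datasets (wrong cage size, dangling events, outcome
  out of range) with the offending record named.
- Trials with zero delivered pellets contribute nothing to the likelihood
  and are excluded from meal-share tables with a logged notice.
- Clone-cage curves fix fish and replicate effects at 0 (the
  population-typical individual) and the diet at its reference level; the
  per-fish probability has the closed form `e^s / (8 e^s + e^(−8 s))`,
  cross-checked against the generic softmax pipeline.

## Known limitations

- The sampler is static-trajectory HMC, not NUTS; it is tuned for this
  model family (~100 well-conditioned dimensions after standardization) and
  is not a general-purpose replacement for a probabilistic-programming
  backend.
- Fits assume exactly 8 fish per cage (the not-consumed gauge is defined
  for that design); other group sizes would need a generalized score
  completion.
- Diet intercepts and the general intercept are weakly identified at
  realistic waste rates (two cages per diet level); their posteriors are
  prior-influenced, as reflected in wide intervals.
- The exact priors of the original analysis live in external code; the
  defaults here are a reasonable weakly-informative choice, configurable
  via `PriorSpec`.
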
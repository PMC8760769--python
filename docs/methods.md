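# Methods

## Models

### Adjusted repeatability

Each trait is analysed on its model scale (natural log for the cortisol
concentrations and for absolute weight change; identity for the rank
index) with a Gaussian linear mixed model

```
y_it = x_it' beta + u_i + e_it,   u_i ~ N(0, V_between),  e_it ~ N(0, V_within)
```

where `i` indexes individuals and `t` measurement phases. Continuous
covariates are mean-centered within the model's analysis rows; categorical
covariates use treatment contrasts (measurement phase coded with the
*second* phase as reference, housing group with group 1 as reference).
Adjusted repeatability is `R = V_between / (V_between + V_within)` at the
REML estimates, truncated to 0 when the between component sits at the zero
boundary. The model assumes Gaussian residuals on the chosen scale,
homoscedasticity across individuals and phases, and exchangeable phases
after conditioning on the measurement factor.

Inference:

- **Permutation p** — the fixed-effects-only model is fitted by OLS, its
  residuals are permuted and added back to its fitted values, the mixed
  model is refitted and R recomputed; with `nperm` replicates (default
  500) the p-value is `(1 + #{R_perm > R_obs}) / (nperm + 1)`, the
  observed data counting as one realisation. The strict inequality is
  deliberate: when the observed R is 0, permuted replicates also pile up
  at the boundary, and counting the ties as exceedances would force p = 1;
  with the strict count the boundary case lands near 0.5, the behaviour
  expected of a non-repeatable trait (it also matches the 0.5 that a
  50:50 chi-square mixture boundary test reports at a zero likelihood
  ratio). The test is conservative near the boundary — its type-I error
  at true R = 0 is measured in the acceptance suite (≤ 7% at α = 0.05
  over 500 simulated 24 × 3 studies).
- **Parametric bootstrap** — responses are simulated from the fitted model
  (new individual effects and residuals at the REML estimates), the model
  refitted, and `(V_between, V_within, R)` recorded per replicate
  (default 1000). The SE is the bootstrap standard deviation of R and the
  CI the central 95% percentile interval. Percentile (not bias-corrected)
  intervals are used because they reproduce the asymmetric,
  boundary-hugging intervals appropriate for R estimated at or near 0.
  Replicates that fail to fit are redrawn, capped at 10 × nboot draws.

### Variance-component comparison

To ask *why* two traits differ in repeatability, their bootstrap replicate
streams are compared component-wise. Replicates are paired by index (k-th
with k-th, over the first `min(n_a, n_b)`), the difference
`d_k = v_a,k − v_b,k` formed, and

```
p = 2 * min( P(d < 0), P(d > 0) ),   capped at 1
```

with exact zeros split half to each tail, so comparing a stream with
itself gives p = 1 rather than 0. Before comparison each replicate
variance is divided by the squared trait mean on the model scale
(CV²-style "mean correction"), making components comparable across traits
of different magnitude; the convention is configurable
(`mean_correction = "squared_mean" | "none"`) since dividing by the mean
rather than its square is an equally defensible reading of
mean-correction, and any common scaling of both traits leaves p unchanged
(tested property). Pair order follows the listed trait order so the sign
of the mean difference is reproducible.

### Rank index

The dominance rank order index of a focal female in one phase is the
number of observed retreat interactions she won (the opponent retreated)
divided by the protocol total of 30 (10 per observation day). Strict mode
(default) enforces the 30/10-per-day protocol; lenient mode computes the
ratio over whatever records exist and logs the count. Indices are
independent focal-sampling estimates per female and do not sum to a
constant within a group.

### Rank–cortisol association

Untransformed cortisol concentration is modelled on sampling time
(3-level factor, baseline reference), rank index (centered), their
interaction, body weight (centered), measurement and housing group, with a
per-individual random intercept plus sampling-time random slopes. The
random-effect covariance G is a full 3 × 3 unstructured matrix
(intercept + two level offsets; covariances unconstrained — 6 free
parameters). Estimated marginal means per sampling time are predictions
averaged over the levels of the other factors with equal weights,
continuous covariates at their in-model means; pairwise contrasts (later
level minus earlier) carry Satterthwaite degrees of freedom and no
multiplicity adjustment.

## REML estimation

Fixed effects and the residual scale are profiled out of the restricted
likelihood. Writing `V0 = I + Z Γ Z'` with `Γ = G/σ²`, the criterion

```
-2 l_R = log|V0| + log|X' V0⁻¹ X| + (n-p) (1 + log 2π σ̂²),
σ̂² = y' P y / (n - p)
```

is minimised over Γ only.

- **Random intercept**: Γ is the scalar ratio λ = V_between/V_within. The
  criterion is evaluated in O(G p²) per point via the Woodbury identity on
  per-group sums, scanned on a 25-point grid in log λ over [−30, 30] and
  polished by bounded scalar minimisation (absolute tolerance 1e-10 on
  log λ, i.e. relative λ resolution ≈ 1e-10). The boundary λ = 0 is
  evaluated exactly and preferred when its criterion is no worse; fits at
  the boundary are flagged, not rejected. If the optimum runs to the upper
  edge and the within-group residual sum of squares is numerically zero,
  the model collapses to a regression on group means (V_within = 0,
  R = 1), the correct limit for perfectly repeatable data.
- **Unstructured G**: Γ = L L' is parameterised by the log-Cholesky vector
  (log diagonal, free off-diagonal) and minimised by Nelder–Mead with 5
  starts (one from the intercept-only fit, the rest perturbed), function
  tolerance 1e-10. Small studies make rank-deficient Ĝ likely; such fits
  are legitimate boundary solutions and are flagged. When every group
  shares the same block size and Z pattern (the balanced long-format
  design), a single m × m factorisation per criterion evaluation serves
  all groups.
- **Degenerate inputs**: a response with zero total variance raises a
  dedicated error; rank-deficient fixed designs raise an error naming the
  aliased columns (pivoted QR); missing values are rejected, never
  dropped silently.

### Satterthwaite degrees of freedom

For a contrast c, `df = 2 (c'Ĉc)² / Var(c'Ĉc)` where `Ĉ(θ)` is the
fixed-effect covariance at the variance parameters θ and the denominator
variance comes from the delta method: a finite-difference gradient of
`c'C(θ)c` through the inverse observed information of the restricted
likelihood (central-difference Hessian, relative steps 1e-4 with a
magnitude-scaled floor). The statistic is invariant to smooth
reparameterisation of θ, so the scale can be chosen for numerical
behaviour: the random-intercept model differentiates on the natural
`(V_between, V_within)` scale, while the unstructured model differentiates
on the Cholesky-factor-plus-sigma scale, which keeps usable curvature at
rank-deficient Ĝ where the natural scale loses it. At an exact zero
random-intercept variance the model has collapsed to ordinary regression
and the residual df `n − p` is reported with a warning. The test suite
pins this machinery, including the singular case, against frozen reference
values from the standard R mixed-model stack to ≲1% on df.

## Synthetic-study generator

The generator emulates the two-group design end to end. Log cortisol for
individual i, phase t, sampling time s is

```
log C_its = mu[s] + x_it' beta + sqrt(v_between[s]) z_i + e_its
```

with a single standard-normal factor `z_i` shared across sampling times
(so per-time individual effects are perfectly correlated and a scalar
`v_between` is exactly the classic shared random intercept) and
independent `e_its ~ N(0, v_within[s])`. Per-time triples let sampling
times carry different true repeatabilities.

Defaults are calibrated so the generated studies look like the two-group
guinea-pig design the package targets: grand means
`mu = (6.52, 7.36, 7.61)` on the log scale (≈ 680/1570/2020 assay units at
baseline/1 h/2 h, the magnitude of a plasma-cortisol novel-environment
response),
`v_between = (0, 0.104, 0.130)` and `v_within = (0.45, 0.060, 0.040)`
giving true R = (0, 0.63, 0.76) — the characteristic pattern of repeatable
stress responsiveness with a non-repeatable, high-within-variance
baseline; body weight ~ N(700 g, 75² g²) with
decigram rounding, ≈ 15 g phase-to-phase fluctuation and 30 g growth
between phases; ages uniform on 151–197 d at phase 1, +41 d at phase 2;
weight loss per test log-normal (median ≈ 6.5 g, between/within log-scale
variances 0.25/0.18, true R ≈ 0.58); fixed-effect coefficients on log
cortisol of 5e-4 per g body weight, 0.05 for phase 1 vs 2 and 0.10 for
group 2 vs 1. Retreat interactions are Bernoulli with win probability
`logistic(steepness · (d_focal − d_opponent))`, latent dominance
`d ~ N(0, 1)` constant across phases, opponents drawn uniformly among
groupmates (the focal protocol does not specify opponent frequencies);
`steepness = 0.6` makes the adjusted rank-index repeatability ≈ 0.70 at
the default design, the stability typical of settled female hierarchies.

All randomness flows from one seed through SeedSequence spawning with a
fixed child stream per ingredient (covariates, cortisol, dominance,
retreats, weight loss), so composed studies equal their standalone
fragments and identical seeds give byte-identical datasets.

**What the generator does not emulate**: circadian cortisol dynamics,
assay noise as a separate layer from residual variance (the two are
confounded in `v_within`), cross-time residual correlation beyond the
shared individual factor, any true rank–cortisol association (the default
truth is null), non-uniform opponent choice, and hierarchy change between
phases. Passing tests therefore demonstrate that the estimators recover
the parameters of *this* generative family at the study's design sizes —
not that real cortisol data satisfy the model's assumptions.

## Problem sizes used in the simulation tests

Chosen to give each check clear resolution: balanced-design oracle on 30
randomized designs (4–24 groups × 2–7 replicates, agreement 1e-6);
brute-force grid oracle on 20 datasets of 30 × 4 (agreement 1e-3);
parameter recovery and bootstrap coverage at 100 individuals × 4 measures
over 100 replicate studies (300 bootstrap replicates each); permutation
calibration over 500 studies of 24 × 3 with 99 permutations; comparison
error rates over 100 runs of 50 × 4 with 150 bootstrap replicates. The
acceptance script runs the full pipeline at the study's own design
(12 × 2) with the standard 500/1000 resampling sizes.

## Known limitations

- Gaussian traits only; no link-scale or enhanced-agreement repeatability
  variants, no non-Gaussian mixed models, no crossed random effects, no
  Kenward–Roger df.
- The permutation scheme permutes residuals of the fixed-effects-only
  model; alternatives (permuting within individuals, permuting raw
  responses) answer slightly different null hypotheses.
- At 12 individuals the sampling distribution of R is wide (SD ≈ 0.2) and
  the bootstrap CI can exclude the point estimate by Monte-Carlo accident
  when the estimate sits at a boundary; this is logged, not treated as an
  error.
- Percentile bootstrap CIs undercover slightly for extreme true R; the
  acceptance suite measures coverage at true R = 0.6 only.
- The weight-change model offsets exact zero changes by 0.05 g (half the
  measurement resolution) before the log; results for that trait are
  insensitive to the offset unless many changes are exactly zero.
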
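# Methods

## Model

`spatlogit` fits a survey-weighted Bayesian spatial logistic regression for a
binary outcome observed on individuals nested in areal units (districts). For
individual *i* in district *j*:

    y_ij ~ Bernoulli(p_ij)
    logit(p_ij) = Z_ij' beta + s(t_ij) + phi(t'_ij) + b_j + h_j

* `Z_ij` — dummy-coded categorical covariates plus an intercept
  (reference-cell coding, declared reference level dropped);
* `s`, `phi` — nonparametric smooth effects of two continuous covariates
  (age at survey time, age at first cohabitation), modelled as first- or
  second-order Gaussian random walks (RW1/RW2) over the ranked, binned
  covariate values;
* `b_j` — spatially structured district effect with an intrinsic CAR (Besag)
  prior: conditionally, `b_j | b_-j ~ N(mean of neighbours, sigma_b^2 / m_j)`
  with `m_j` the neighbour count. The joint unit precision is the graph
  Laplacian `Q = D - A`, rank `J - 1` on a connected map;
* `h_j` — unstructured IID normal district effect (`b + h` is the BYM
  convolution model);
* priors: `beta ~ N(0, 1e6)` per coefficient; each precision
  `tau = 1/sigma^2` carries a `Gamma(1, 1e-5)` prior by default, with
  half-normal, half-Cauchy, half-t, uniform-on-sigma and penalised-complexity
  alternatives for sensitivity analysis.

Sampling weights `w_ij` enter as likelihood exponents (pseudo-likelihood):
`sum_ij w_ij [y_ij log p_ij + (1 - y_ij) log(1 - p_ij)]`. Weights are
normalised to mean one by default so the effective sample size matches the
nominal one; a flag disables this.

### Assumptions

The model assumes the outcome is conditionally independent across individuals
given covariates and district effects; that spatial dependence is fully
captured at the district level by the CAR term; and that the smooth effects
are additive on the log-odds scale. The intrinsic CAR is improper; a hard
sum-to-zero constraint on `b` (applied every draw) plus the intercept makes
the convolution model identifiable. Each RW smooth is likewise centred
(sum-to-zero over knots) with the intercept carrying the level; the RW2 null
space also contains a linear trend, which the likelihood itself identifies
once no linear term for the same covariate sits in `Z`.

## Inference: Pólya-Gamma Gibbs with interweaving

The posterior is sampled by Pólya-Gamma data augmentation. Given
`omega_ij ~ PG(w_ij, psi_ij)` the Bernoulli pseudo-likelihood is conditionally
Gaussian in the linear predictor, so one sweep is:

1. `omega_ij ~ PG(w_ij, psi_ij)` — because weights are real-valued the shape
   parameter is non-integer; draws use the infinite-convolution-of-gammas
   representation truncated at 64 terms, with the dropped tail replaced by its
   analytic expectation (closed-form series sum). The truncation error decays
   like `n_terms^(-3/2)` and is orders of magnitude below the Monte-Carlo
   noise at the default setting.
2. Joint Gaussian draw of every coefficient block (beta, smooths, b, h) from
   the full conditional with precision `X' Omega X + blockdiag(priors)`.
   Sum-to-zero constraints are imposed exactly by conditioning-by-kriging;
   before factorisation the precision is augmented by `c a a'` along each
   constraint direction `a` — this leaves the constrained distribution
   invariant while keeping the Cholesky factor well conditioned despite the
   intrinsic (singular) CAR/RW priors.
3. Precision updates: conjugate Gamma draws
   `tau ~ Gamma(a1 + rank/2, a2 + theta' Q theta / 2)` for the Gamma family
   (rank = the GMRF rank, e.g. J-1 for ICAR), and stepping-out slice sampling
   on `log tau` for the non-conjugate sd-scale families.
4. An ancillarity–sufficiency interweaving (ASIS) step per variance
   component: the block is rescaled into its non-centred parameterisation
   (`block = sigma * btilde`) and `sigma` is slice-sampled against the
   PG-conditional likelihood. Without this step the centred Gibbs sampler
   exhibits the classic small-sigma funnel (tau explodes, the block pins at
   zero, the chain sticks) whenever a variance is weakly identified.

Chains are seeded from one master seed via `numpy.random.SeedSequence`, so a
fixed seed and chain count give bitwise-reproducible draws. Split-chain
rank-normalised Rhat and effective sample sizes (via `arviz`) are reported
per parameter; a fit with max Rhat >= 1.1 is flagged, never hidden.

This engine targets the same posterior an INLA analysis approximates; the
package's contract is the posterior summary (means, sds, equal-tailed 95%
intervals), not any particular approximation algorithm.

A practical note on the default `Gamma(1, 1e-5)` precision prior: transformed
to the sd scale it places most of its mass below `sigma ~ 0.01`. With many
districts and hundreds of records per district the likelihood dominates and
the spatial sd is recovered well; on very small maps (e.g. 16 districts with
~100 records each) the posterior can genuinely concentrate near zero. This is
a property of the prior, not of the sampler, and is the reason the
prior-sensitivity sweep exists.

## Model comparison

WAIC is computed on the deviance scale: `waic = -2 (lppd - p_d)` with
`lppd_i = log mean_s exp(ld_si)` (stable log-sum-exp) and the variance-form
penalty `p_d_i = var_s(ld_si)`, where `ld_si = w_i log Bernoulli(y_i |
p_i^(s))` are the weighted pointwise log densities. Reported WAIC magnitudes
on full-scale data (~1.7e4 for n ~ 1.8e4) match this convention. Smaller is
better; candidates within 2 units are treated as equivalent fits, and ties
break toward fewer effective parameters.

* **Structure ladder** — NO / IID / CAR / CAR+IID variants fitted at identical
  sampler settings with a seed schedule spawned from one master seed.
* **Backward selection** — repeatedly drop the covariate whose removal most
  decreases WAIC; stop when no removal improves WAIC by more than 2 units
  (the same 2-unit rule, applied as a stopping criterion).
* **Sensitivity sweep** — refit under each precision-prior family; report
  sigma posterior means, 95% intervals and WAIC per family.
* **Linearity comparison** — paired odds-ratio table (forest-plot layout) for
  the fixed effects under RW-smooth versus linear treatment of the age terms.

## Risk mapping and screening

* Exceedance probabilities `q_j = P(exp(b_j) > 1) = P(b_j > 0)` are the
  fraction of posterior draws positive; districts with `q_j > 0.90` (strict)
  are flagged as elevated.
* The district risk map adds the average and the across-record spread of the
  per-record posterior-predictive mean probabilities, per district; districts
  with no records keep their `b` summaries with null probability fields.
* GVIF screening: `GVIF_c = det(R11) det(R22) / det(R)` on the correlation
  matrix of the pooled dummy design (unweighted — screening happens before
  the weighted fit), reported on the `GVIF^(1/(2 df))` scale with the
  `sqrt(2.5) ~ 1.58` cutoff. Rank-deficient designs report infinite GVIF with
  the collinear covariate set identified from the null eigenvector.
* The descriptive table is unweighted by default (a weighted variant is a
  flag away), with frequencies, column percentages and outcome-stratified row
  percentages, plus median/IQR for continuous covariates.

## Synthetic data generator

The generator emulates a nationally representative household survey of
ever-married women aged 15-49 across 64 districts:

* **Graph** — 8x8 rook lattice by default (same cardinality as the real
  64-district map, connected, desk-scale); arbitrary edge lists accepted.
  Disconnected maps are rejected loudly rather than handled per component.
* **Covariates** — residence, occupation, wealth quintile, marital status and
  parity drawn at the published descriptive-table proportions.
* **Effects** — fixed-effect log odds ratios at the published fitted-model
  values; age-at-survey effect rising ~0.12 per year to a plateau at 25;
  age-at-cohabitation effect declining ~0.05 per year to a plateau at 22;
  `sigma_b = 0.44` (conditional-sd parameterisation of the ICAR, not the
  marginally rescaled variant), `sigma_h = 0` by default.
* **Ages** — cohabitation age on a 0.25-year grid in [10, 35] (gamma-shaped,
  median ~16), survey age = cohabitation age + gamma-distributed duration,
  truncated to [15, 49]; cohabitation never exceeds survey age.
* **Weights** — "stratified" scheme: inverse of a lognormal district-level
  selection intensity times individual noise, clipped to [0.3, 3] and
  rescaled to mean one. The published study does not describe its weight
  distribution, so this dispersion is a design choice of this package.
* **Intercept** — -1.442, calibrated once so the default conditions give
  ~19.4% overall prevalence (the published figure).
* **ICAR field sampling** — from `N(0, sigma_b^2 pinv(Q))` via a rank-one
  completion `Q + (1/J) 1 1'` followed by mean-removal (exact, no
  eigendecomposition); the smooth contributions are centred over the realised
  ages so the intercept owns the level, mirroring the constraint the fit
  imposes.

What the generator does **not** emulate: the two-stage cluster sampling
mechanics (strata/PSUs — only the resulting weights), item nonresponse
patterns, recall error, real geographic irregularity (the lattice has more
homogeneous neighbour counts than a real admin map), or dependence between
covariates and district effects. Passing tests therefore demonstrate the
estimator recovers the model's own data-generating process at survey scale,
not robustness to the messiness of real survey data.

## Numerical choices

* PG series truncation 64 terms + analytic tail mean (see above).
* Constraint jitter scale `c = mean(diag(P))`; constrained directions are
  exact to solver precision (~1e-10 observed on the sum of `b`).
* Slice sampler: stepping-out with width 1 on the log scale, cap 50 steps.
* Sampler initialisation: all coefficients at 0, all sigmas at 0.5.
* Knot assignment floor-bins at the configured width (default 1 year) and
  doubles the width until at most `max_knots` (60) bins remain; ties share a
  knot; unequal knot spacing is ignored (unit-spacing random walk).
* Degenerate smooths (fewer knots than the RW order allows) are rejected with
  a message suggesting a fixed effect.
* Equal-tailed intervals and posterior means (not medians) throughout.

## Problem sizes used by the test suite and acceptance script

Statistical checks run at deliberately desk-scale sizes chosen by this
package: parameter-recovery at 64 districts x 300 records (20 replicates),
structure-ladder behaviour at 16 districts x 150 records (10 replicates per
scenario), nonlinearity recovery at 64 x 300, sensitivity at 64 x 200, and
the acceptance script's end-to-end study at 64 x 150. These sizes keep each
simulation informative for the quantity it checks while the full suite stays
fast enough to re-run routinely.

## Known limitations

* The default smoothing prior undersmooths flat regions of a covariate
  effect at 1-year knots: the fitted RW1 curve tracks per-knot binomial
  noise of a few hundredths on the log-odds scale wherever the truth is
  flat. Coarser bins (2-3 years) stabilise the plateau; this is the usual
  bias-variance trade of nonparametric smoothing, surfaced through
  `ModelSpec.bin_width`.
* The pseudo-likelihood treats weights as known constants; no design-based
  variance correction is attempted (weights affect the likelihood only).
* One spatial scale: no multilevel (division/district) nesting, no
  geostatistical (point-level) variant.
* WAIC is the only predictive criterion (no DIC, cross-validation or Bayes
  factors).
* The Gibbs engine is exact but not fast at very large n; ~2e4 records with
  ~200 latent dimensions run at roughly 15-20 iterations per second on one
  core.
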
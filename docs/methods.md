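# Methods

## Model

The package fits a two-group extension of the shared component model for
spatial disease mapping. Counts are binomial per (gender, region) cell:

    O[j,i] ~ Bin(n[j,i], p[j,i]),   logit(p[j,i]) = α_j + b_jᵀ x[j,i] + η[j,i]

with group-level spatial offsets

    η[1,i] = δ·φ[i] + υ[1,i],
    η[2,i] = φ[i]/δ + γ[i] + υ[2,i].

`φ` is the shared risk surface, loaded by δ for group 1 and 1/δ for group 2
(the product of the loadings is one by construction, which identifies the
weight; δ² is the ratio of loadings). `υ_j` are group-specific surfaces and
`γ` is the group-contrast surface entering group 2 only. `φ` and each `υ_j`
are convolution (BYM) fields: an intrinsic-CAR structured half (`ssh`,
`bspat`) plus an i.i.d. normal unstructured half (`ush`, `bind`). `γ` is
intrinsic CAR. The intrinsic-CAR log density is

    ((N − C)/2)·log(τ/2π) − (τ/2)·Σ_{i~l} (v_i − v_l)²

over unordered neighbor pairs of the binary (0/1) contiguity graph, with
N regions and C connected components; it is improper (shift-invariant), so
every region-indexed component is kept sum-to-zero and the gender
intercepts carry the levels.

Derived per draw: shared-variance fractions
η₁ = var(δφ)/(var(δφ)+var(υ₁)) and
η₂ = var(φ/δ)/(var(φ/δ)+var(γ)+var(υ₂)) (empirical variances across
regions), per-covariate relative risks exp(b·Δx), component SDs, and the
deviance −2·log L.

### Identifiability choices

Two deliberate normalizations resolve redundancies the model family leaves
open:

- The unstructured group-specific effects (`bind`) are centered at zero
  per gender and the single per-gender intercept α_j carries the level; a
  second hierarchical intercept inside `bind` would be unidentified under
  flat priors and would change nothing in the fitted probabilities.
- Sum-to-zero is enforced on *all* region-indexed components — the CAR
  halves (where it is the standard intrinsic-CAR constraint) and the
  normal halves (to separate them from the intercepts).

### Priors

All precisions share one gamma prior, Gamma(shape, rate) in the
rate parameterization; the default `priors1` is Gamma(1, 1e-4), with
`priors2` = Gamma(1000, 5e-7) and `priors3` = Gamma(5, 5e-5) available for
sensitivity analysis (the `priors2` setting implies an extreme prior mean
precision; it is provided verbatim as an alternative, not a
recommendation). The log shared weight has prior N(0, 0.169) where 0.169
is a **variance** (sd ≈ 0.411): that reading — and not sd = 0.169 — places
δ² inside [1/5, 5] with 95 % prior probability, which is the calibration
the weight prior is designed around (`datasets.LOG_DELTA_PRIOR_VARIANCE`).
Intercepts and covariate coefficients get improper flat priors.

### Covariate scale

Regional covariates are proportions in [0, 1] (share elderly, obese,
WHtR > 0.5) and are multiplied by `covariate_scale` (default 100) on entry
to the linear predictor, so coefficients and their RRs read *per
percentage point*. RRs per percentage point of order 1.01–1.04 correspond
to plausible regional effects; the scale is a configuration option for
users who prefer per-unit-proportion coefficients.

### Variance conventions

`variance_fractions` uses the population convention (divide by N) — the
natural choice for a variance *ratio* of a finite set of regions — while
`component_sds` uses the sample convention (ddof = 1). Both expose `ddof`
so either convention can be selected; the defaults match the package's
hand-checked reference values.

## Missing data

Two rules prepare incomplete regional tables (`impute_missing`):

- **Substituted regions** (regions whose counts are unreliable, e.g. a
  small island prefecture) have both genders' cases and denominators
  replaced by the across-region average of the remaining regions, rounded
  to the nearest integer so the binomial likelihood stays well defined.
- **Missing covariates** get a normal prior with the mean and sample
  variance of the observed entries of the same covariate and gender, and
  are then *sampled within MCMC* (random-walk Metropolis with that prior)
  rather than fixed at a point estimate. A covariate missing in every
  region is an input error.

## Sampler

Metropolis-within-Gibbs. Precisions have conjugate gamma full
conditionals: shape + (N−C)/2 with rate + Q/2 for CAR components
(Q the pairwise quadratic form), shape + N/2 with rate + Σv²/2 for the
i.i.d. components. Everything else updates by scalar random-walk
Metropolis: intercepts, coefficients, log δ, every random-effect site, and
each imputed covariate. Step sizes adapt toward 44 % acceptance during
burn-in only (diminishing adaptation, frozen afterwards). After every
component sweep, each constrained vector is recentered and the subtracted
mean transferred into the intercepts — for the shared surface
α₁ += δ·m and α₂ += m/δ — so recentring never changes the fitted
probabilities.

Two numerical details matter:

- Covariates are **centered per gender inside the sampler** and the
  intercept mapped back to the raw parameterization at record time. With
  covariates on the 0–100 scale, the raw parameterization leaves α and b
  strongly negatively correlated and scalar updates mix an order of
  magnitude more slowly; centering removes this without changing the
  posterior.
- Cell log-likelihood terms are evaluated on the logit scale,
  `O·u − n·log(1+e^u)`, with a branch-stable log1p-exp, so extreme states
  are finite rather than overflowing.

Chain starts are overdispersed: chain *c* scales its initial perturbations
by (1 + 2c) around the pooled-rate logit. Seeds for each chain derive from
one root seed; identical data and configuration reproduce the retained
draws bit for bit. The protocol default is 2 chains × (50,000 burn-in +
50,000 iterations, thin 10) = 10,000 retained draws; tests and the
reproduction scripts use shorter chains (the package's own choice of
problem size; see "Problem sizes" below).

Convergence is reported as split-chain R-hat (each chain halved; computed
via arviz) — stricter than the graphical BGR plot it replaces — plus
sample autocorrelations. DIC uses the plug-in at the posterior mean of the
cellwise *linear predictor* (the focus-on-mean convention); pD can be
negative for pathological fits and triggers a warning, not an error.

## Synthetic data generator

`generate_regional` emulates the target study design: 11 regions × 2
genders, covariates uniform on ranges echoing the study table (elderly
share 0.30–0.70, obese 0.03–0.15, WHtR>0.5 0.50–0.90), structured
components drawn from the intrinsic CAR conditioned on sum-to-zero (the
zero-mean Gaussian with covariance pinv(τL) on the Laplacian's row-space —
the unique proper distribution consistent with the improper fitting
density), unstructured components i.i.d. normal then centered, and
binomial counts at the model probabilities. The default cell size (57)
gives a cohort of ~1250, the scale of the motivating study; the default
generating intercepts put gender prevalences near 31 % and 35 %, log δ at
0.09, and all precisions at 1000 (component SDs of a few percent on the
log-odds scale, matching the small spatial variances such surveys show).

`generate_individual` expands regional cells into subject records whose
covariate indicators are independent per-subject draws at the cell
proportions, and assigns exactly the cell's case count to a random subset
so re-aggregation reproduces the regional table. It does **not** model
within-subject correlation between covariates (an obese subject is no more
likely to have WHtR > 0.5 than a lean one), survey weights, nonresponse,
or measurement error — so passing descriptive/logistic tests on synthetic
data validate the computations, not those aspects of real survey data.

`recovery_experiment` closes the loop: generate → fit → check whether each
generating fixed effect and δ falls in its central 95 % credible interval,
excluding (and counting) replicates whose fixed-effect R-hat exceeds 1.1.

## Problem sizes and tolerances

- Oracle-equivalence tests assert 1e-10 relative agreement between the
  model densities and independent scalar/dense-matrix evaluation.
- The degenerate intercept-only sampler check compares against the exact
  Beta(O, n−O) posterior (the flat-on-logit prior maps to 1/(p(1−p)) on
  the probability scale) within 3 conservative Monte-Carlo standard
  errors; the data-free run checks sd(log δ) against √0.169.
- The recovery experiment uses 500 subjects per cell (regional
  coefficients are weakly informed at survey-scale cells, which is also
  why the motivating analyses flag city-level imprecision), 20 replicates,
  and 2 × (1000 + 1500, thin 3) chains, asserting ≥ 80 % empirical
  coverage — small-replicate binomial slack around the nominal 95 %.
- Stratified-table percentages round half-up: 2 decimals for stratum
  cells, 1 decimal for headline prevalences, matching the printed
  precision of the reference table. Note the bundled reference table's
  age-stratum denominators sum to 1264 while the cohort it summarizes
  enrolled 1267; the package reports both totals rather than reconciling
  the three-record gap.

## Known limitations

- Exactly two groups; the multi-disease SCM generalization is out of
  scope, as is the Poisson-likelihood variant.
- Scalar random-walk updates are simple and robust but less efficient
  than block or gradient-based samplers; the contract is distributional,
  not trajectory-level.
- Expected counts for the SPR use crude internal standardization per
  gender (the only standardization computable from counts and
  denominators alone); no age standardization is attempted.
- Map outputs are region→value tables; geometry handling and choropleth
  rendering are intentionally out of scope.
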
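# Methods

## Model

`occufp` implements the single-season site-occupancy model and its
false-positive (misclassification) extension.  Site `i` carries a latent
occupancy state `z_i ~ Bernoulli(ψ_i)`; replicate survey `j` of site `i`
records `Y_ij ~ Bernoulli(p_ij)` when `z_i = 1` and
`Y_ij ~ Bernoulli(p10)` when `z_i = 0`.  The conventional model is the
special case `p10 = 0`.  Replicates are conditionally independent given
`z_i` — the standard assumption for spatial replicates such as hunting
zones within a site, and the one the fitted models make.  `ψ_i` and `p_ij`
are logit-linear in standardized site covariates; `p10` is a single scalar
(intercept-only), matching the convention of reporting one misidentification
rate per species; there is no "certain detection" observation type, the
right variant when no report can be verified.

The site-marginal likelihood is the two-term mixture over `z_i`.  It is
accumulated entirely in the log domain with a log-sum-exp over the two
terms: optimizers routinely visit probabilities numerically equal to 0 or 1,
where naive products under- or overflow.  Missing replicates contribute a
factor 1 (skipped), i.e. missing-at-random; a site with no observed
replicate is rejected at problem construction.

An independent oracle, `brute_force_site_loglik`, recomputes each site term
by explicit enumeration of the latent state with scalar product-form
arithmetic and no shared helpers.  Tests require agreement to 1e-10 and
that the implied distribution over all `2^J` histories sums to 1.

## Estimation

The negative log-likelihood is minimized with L-BFGS-B on the unconstrained
scale (coefficients and `logit p10`), using the analytic gradient

- `∂ℓ_i/∂β_k = (w_i − ψ_i) x_ik`,
- `∂ℓ_i/∂α_k = w_i Σ_j m_ij (Y_ij − p_ij) x̃_ijk`,
- `∂ℓ_i/∂logit p10 = (1 − w_i) Σ_j m_ij (Y_ij − p10)`,

where `w_i` is the posterior probability of occupancy given the history and
`m_ij` masks missing replicates.  The gradient is verified against central
finite differences in the test suite.

Multi-start: one structured start (zero coefficients, detection intercept
+1 because detection is usually better than chance, `logit p10 = −3`,
i.e. `p10 ≈ 0.047`, because misidentification rates are small) plus seeded
Gaussian restarts (default 5 starts total, scale 1); the best finite
optimum is kept and convergence is reported via `converged_`, never raised.
Convergence tolerance is 1e-8 on the objective.

The misclassification model has a label-switching mode in which `p11` and
`p10` exchange roles.  When the fitted site-mean `p11` falls below `p10`,
the model is refitted from a swapped start and the higher-likelihood
solution with `p11 > p10` is kept; a warning is recorded either way.

Standard errors are square roots of the diagonal of the inverse Hessian,
computed by central finite differences of the analytic gradient (step 1e-5)
and symmetrized.  A singular or negative-curvature Hessian (typically
`logit p10 → −∞` on false-positive-free data) yields undefined SEs plus a
boundary/identifiability warning rather than an error.  AIC is plain
`2k − 2 logL` (not AICc); `k` counts every estimated coefficient including
`logit p10`.

## Design matrices and standardization

The formula grammar is deliberately small: terms joined by `+`, one or more
two-way interactions written `a * b`, `1` for intercept-only.  `a * b`
expands conventionally to main effects `a`, `b` plus their product — the
expansion that reconciles model labels like `ψ(rug * pop + for)` with
coefficient tables that report both mains and the product.  Column order is
fixed (intercept, mains in declaration order, interactions in declaration
order).  Covariates are standardized to mean 0 and sample standard
deviation 1 (denominator `n − 1`); the training centering/scaling record is
applied unchanged to prediction grids.  Mains are standardized first and
products formed afterwards; products are not re-standardized.

## Selection and averaging

Phase 1 fits every candidate as a conventional model and ranks by AIC with
weights `w_m ∝ exp(−ΔAIC_m/2)`.  Phase 2 refits each phase-1 model with
ΔAIC < 2 (the same threshold used for averaging) as its misclassification
counterpart, and the final ranking covers the union of those top
conventional models and their counterparts with weights renormalized to sum
to 1.  Model-averaged predictions restrict to ΔAIC < 2, renormalize, and
average on the probability scale (the averaged quantities are probabilities
of occupancy and detection); for misclassification models the averaged
detection probability is `p11`, with `p10` reported separately.  Default
candidate enumeration takes all subsets of main effects per component, each
optionally augmented by a single two-way interaction between covariates in
that component — bounded (with a configurable cap and an explicit-list
escape hatch) yet covering the complexity class of typical published model
sets; enumerating every interaction combination of 4 covariates literally
is combinatorially explosive and is deliberately not the default.
Non-converged fits are excluded from ranking with a logged reason, and
per-model fitting failures are isolated so one pathological candidate
cannot abort a run.

## Synthetic data

The generator reproduces the reference survey design: M = 225 sites with
J = 6 spatial replicates and four site covariates (`elev`, `rug`, `for`,
`pop` — mean elevation, ruggedness, forest area, human-settlement density),
drawn standard normal by default because the analysis always operates on
standardized covariates.  Occupancy and detection follow the logit-linear
model above, with optional product terms; `p10` is a scalar constant; a
missingness rate (default 0) blanks replicates at random while keeping at
least one observed replicate per site.  One seeded RNG stream per dataset
makes datasets bit-reproducible; truth (`z`, `ψ_i`, `p_ij`, seed) is
written to a sidecar file that fitting inputs never include.

What the generator does *not* emulate: spatial autocorrelation between
sites, heterogeneity of observer skill across replicates (replicate-level
covariates are supported by the likelihood but off by default),
covariate-dependent false positives, and multi-season dynamics.  Passing
recovery tests therefore demonstrate correctness of the estimator under the
model's own assumptions, not robustness to their violation in real
interview data.

## Reference simulation conditions

The recovery and selection studies use fixed, pre-registered conditions at
the study's design scale:

- recovery: M = 225, J = 6, ψ ~ `elev + rug + for + pop` with
  β = (0.2, −0.6, 0.7, 0.4, −0.9), p ~ `elev + pop` with
  α = (0.4, 0.4, −0.4), `p10 = 0.03`; 200 replicates; checks logit-scale
  mean bias per parameter and 95% Wald coverage.
- overestimation property: M = 500, intercept-only ψ = 0.4, p = 0.5,
  `p10 = 0.05`; 100 replicates of the conventional fit.
- selection property: M = 500, ψ ~ `pop + rug` (β = 0.1, −0.8, 0.6),
  p ~ `elev` (α = 0.3, 0.4), `p10 = 0.08`; 100 replicates comparing the
  misclassification twin's AIC against the conventional twin's.

These sizes keep the full suite and the acceptance script to tens of
seconds while leaving the Monte-Carlo error of each check far below its
tolerance.  Coefficient magnitudes between 0.4 and 0.9 on the logit scale
are "moderate" in the sense typical of regional covariate effects: strong
enough to be identified at M = 225, weak enough not to saturate.

## Numerical choices and limitations

- AIC ties in ranking break by label order (deterministic output).
- Per-spec optimizer seeds derive from a CRC32 of the model label, so
  two-phase output is invariant to candidate order.
- `logit` rejects 0 and 1 (domain error); `inv_logit` is stable over
  ±700.
- Grid geometry is opaque: cell coordinates pass through untouched, no
  projection math; the regional means average over all provided grid rows.
- The naïve detected-site count treats a site as detected if any
  non-missing replicate is 1.
- Model-averaged coefficient variances (unconditional SEs), profile or
  bootstrap intervals, goodness-of-fit tests, and Bayesian estimation are
  out of scope.
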
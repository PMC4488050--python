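# Methods

## Model family

All models are linear Gaussian structural equation models written as one
linear system over observed and latent variables,

    v = m + A v + e,    e ~ N(0, S),

with acyclic directed coefficients `A` (loadings, structural regressions,
covariate effects), symmetric `S` (residual variances and covariances) and
intercepts `m`. Implied moments over the observed variables are
`mu = (I−A)^{-1} m` and `Sigma = (I−A)^{-1} S (I−A)^{-T}`. A single code
path therefore serves all five variants — per-chemical latents, mutually
adjusted latents, same-age joint latents, both-age latents, and the
childhood model with local-dependence factors.

Concentrations enter on the log2 scale, so a structural coefficient is the
change in log2 antibody per doubling of exposure and is reported as
`100·(2^b − 1)` percent per doubling.

### Identification and scale choices

- Per-chemical latents (models 1 and 2) fix both loadings to 1, give the
  age-5 indicator intercept 0 and the latent a free mean, and let a free
  age-7 intercept absorb the systematic concentration change between ages.
  The two measurement-error variances are separate free parameters (no
  equality constraint is imposed; the model is identified with three or
  more observed variables).
- Joint latents (models 3–5) fix the latent mean to 0 with all indicator
  intercepts free, and anchor the scale to PFOS — the most abundant of the
  three chemicals — by fixing its loading to 1, so "a doubling of latent
  PFAS" means a doubling on the log2 PFOS scale. In the childhood model
  both PFOS loadings (ages 5 and 7) are fixed to 1; the anchor is a
  builder argument, not hard-wired.
- The childhood model's Year-5/Year-7 local-dependence factors have
  variance fixed to 1 and loadings equality-grouped across the two ages by
  chemical (local dependence equally strong at both assessments). These
  factors enter the implied moments only through pairwise loading
  products, so the loading vector is identified up to a joint sign flip;
  fits are canonicalized to the positive-sum representative (likelihood
  unchanged).
- Covariates (exact age, sex as girl = 1, booster type 1 = 1) are
  exogenous observed variables with freely estimated means, variances and
  covariances. This saturated covariate block contributes identically to
  the model and the saturated reference, so it is degrees-of-freedom
  neutral, and FIML covers missing covariate cells. Covariates predict the
  latent exposure(s) and the outcomes; optional albumin/BMI adjustments
  instead enter the measurement equations (observed indicators), and the
  optional pre-booster adjustment adds the log2 age-5 antibody to the
  outcome equation only, so the exposure effect then concerns the change
  in antibody level across the booster.
- Mean structure is always modeled. Degrees of freedom follow
  `p(p+3)/2 − q` with `p` observed variables (covariates included on both
  sides) and `q` free parameters counting each equality group once.

## Estimation

Full-information maximum likelihood: rows are grouped by missingness
pattern and reduced to sufficient statistics (count, mean, scatter), so a
likelihood evaluation costs O(patterns × p³) independent of sample size.
Rows missing every modeled variable are dropped and counted. Validity
requires missingness at random.

The optimizer is L-BFGS-B on an unconstrained scale (variances
log-parameterized) with an analytic gradient obtained by chaining the
Gaussian derivatives with respect to (mu, Sigma) through the linear-system
parameterization. Because quasi-Newton steps can stall on flat ridges, the
solution is polished by Newton steps using a central-difference Hessian of
the analytic gradient with ridge escalation and backtracking. Start
values are deterministic moment-based refinements of the builder defaults
(column means and variances, loadings 1, structural coefficients 0);
seeded random restarts are available but off by default, so a fit consumes
no randomness. Convergence requires the gradient max-norm to fall below
`gtol · max(1, |loglik|)` (default `gtol` 1e-5; the relative scaling keeps
the criterion meaningful across sample sizes); the relative
log-likelihood-change tolerance is 1e-8. An implied covariance whose
observed sub-block is not positive definite is treated as an optimizer
barrier, never a crash. Non-convergence is flagged on the result, and the
full-analysis driver records per-model failures and continues.

Standard errors come from the observed information: a central-difference
Hessian of the analytic gradient at the optimum on the natural parameter
scale, negated and inverted. A non-positive-definite information matrix
raises an error (typically an under-identified model) rather than being
pseudo-inverted. Confidence intervals are Wald on the coefficient scale
and transformed monotonically to the percent scale, which respects the
−100 % support bound and yields the characteristic asymmetric intervals.
Effect homogeneity across the two antibodies is tested by a 1-df
likelihood-ratio test of the equality-constrained against the free model
(a Wald version can be formed from the parameter table; the LRT is the
default).

## Fit assessment

The chi-square statistic is `2·(saturated − fitted)` log-likelihood, with
the saturated model estimated in closed form on complete data and by EM
otherwise. Pinned index conventions, unit-tested against hand
calculations: RMSEA = sqrt(max(0, (T−df)/(df·(n−1)))), undefined at
df = 0; CFI = 1 − max(T−df,0)/max(T0−df0, T−df, 0) against the
independence baseline (free means and variances, zero covariances, same
rows, covariate block uncorrelated); SRMR averages squared standardized
residuals over the lower triangle including the diagonal, excluding
means, with the FIML-estimated saturated covariance standing in for the
sample covariance when data are incomplete. A model is assessed as
well-fitting when the chi-square p-value is strictly above 0.05, RMSEA
below 0.05, CFI above 0.95 and SRMR below 0.08; each criterion is also
reported separately.

## Baseline regressions and the linearity check

The comparison analyses are OLS of log2 antibody on one log2 age-7
concentration plus covariates, with listwise deletion and nonpositive
concentrations flagged and excluded. Dose-response linearity is checked
by letting the exposure enter through a natural cubic regression-spline
basis with three interior knots at the 25th/50th/75th exposure percentiles
and boundary knots at the observed range ("three knots" is read as
interior knots; the basis is linear beyond the boundary). The spline
model nests the linear one, so the added curvature terms are tested with
a 3-df F-test — fully deterministic, unlike penalized smoothing. The
fitted curve is exported on a grid with a pointwise 95 % band at covariate
means.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes for
a childhood cohort of default size 464: covariates (girls 48.4 %, booster
type 1 32.8 %, age 7.5 ± 0.1 y, albumin and BMI), six lognormal serum-PFAS
concentrations whose log2 covariance equals the configured target exactly
(locations from the published medians, log2 SDs back-solved from the
published IQRs, correlations from the published 6×6 pattern), antibody
outcomes driven by a latent childhood exposure, block missingness, and a
small number of children flagged for an extra booster (excluded, with a
logged count, before analysis — 6 by default).

Construction: the latent exposure is defined through a one-factor
(iterated principal-axis) reading of the target correlation matrix and
drawn from its exact Gaussian conditional given the concentrations, so
the concentration margins are untouched; antibodies then follow
log2-linear structural equations in the latent variable (anchored to the
log2 age-7 PFOS scale), covariates, and residuals correlated between the
two antibodies and with the pre-booster values. Covariate, albumin and
BMI contributions are centred, keeping medians on target; their small
additive variance perturbs the log2 correlations by well under 0.005 at
calibration scale. Antibody residual SDs are back-solved so total log2
SDs match the published IQRs; since the outcomes are lognormal, the
generator preserves each antibody's median and IQR *ratio* — the printed
tetanus quartiles (0.6, 4.5) are not log-symmetric about the printed
median 1.8, a skew beyond lognormality that the generator deliberately
does not chase.

Missingness is made MAR by construction: block rates (age-5 block ~11 %,
age-7 antibody ~1 %, booster type ~2 %, albumin-7 ~20 %, BMI 2 %,
mirroring the published per-model Ns) depend on sex only, which is always
observed. An MNAR switch (missingness loading on the latent exposure) is
available for robustness experiments and off by default.

Values the source cohort does not publish are conservative, clearly
configurable defaults: covariate→exposure effects (small, e.g. −0.05 log2
for girls), the structural effect (−0.5 log2 per doubling for both
antibodies, i.e. −29 %; girls' antibody deficit −0.42 log2 ≈ −25 %,
booster-type-1 advantage +0.2 log2), the within-age-5 correlations
(mirroring the age-7 ones), and the pre-booster antibody model. One
printed value is treated as a typo: the PFHxS age-5 IQR lower bound of
5.0 (above both the median 0.6 and the upper quartile 0.9) is read as
0.5.

### What the generator does not emulate

Assay-level measurement processes (batch effects, detection limits),
longitudinal trajectories beyond the two sampling ages, non-lognormal
outcome skew, and genuinely distinct age-specific latent exposures: all
cross-age cross-chemical correlation flows through a single childhood
factor. A consequence worth knowing: when the both-age model (two
correlated latents, mutually adjusted) is fitted to default generator
output, the two latents are indistinguishable and the latent correlation
is driven to the boundary, so that fit is typically flagged
non-converged and recorded as a per-model failure — the same collinearity
instability that motivates combining the two ages into one childhood
exposure. Passing tests on generator output therefore demonstrate
correctness of the estimation machinery under the stated structure, not
robustness to every feature of real serum data.

## Verification problem sizes

The Monte-Carlo layers of the test suite use 500 simulated cohorts of
n = 450 for parameter recovery, CI coverage (95 % Wald coverage required
within [0.92, 0.98]) and test calibration (chi-square size within
[0.03, 0.07]; equal-effects p-values uniform by Kolmogorov–Smirnov at
0.01); oracle equivalences use up to 10^6 simulated rows; generator
calibration uses n = 200,000 (medians within 2 %, correlations within
0.01, missingness rates within 1 %). Bias checks require the Monte-Carlo
mean of each focal estimate to sit within 3 Monte-Carlo standard errors
of the truth — the tightest bound an unbiased estimator passes reliably.
The attenuation benchmark simulates indicator reliability 0.5, where the
naive slope converges to half the true effect and the latent-variable
estimate to the full effect.

## Known limitations

Only recursive (acyclic) Gaussian models; no ordinal outcomes, no
multi-group SEM, no robust (sandwich) or Bayesian inference, no
penalized-smoothing GAMs, and no benchmark-dose computation. FIML is
biased under MNAR missingness; the MNAR generator switch exists precisely
to study that sensitivity. Observed-information SEs assume a regular
interior optimum and will (correctly) fail near boundaries such as the
both-age model's latent correlation.
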
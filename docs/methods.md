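# Methods

This note documents the statistical models, parametrisations, numerical
choices and limitations of the `densnest` package. No empirical claims
are made here beyond what the package computes.

## Territory metrics (`densnest.territory`)

Boundary segments are classified into six habitat classes by explicit
rules, applied in order: gaps >20% of length → *Gappy hedge*; otherwise
hedgerows split by tree canopy cover (<10% → *Hedge*, 10–50% inclusive
→ *Hedge with 10-50% trees*, >50% → *Hedge with >50% trees*);
non-hedgerow boundaries split at 1 m of herbaceous vegetation width
(> 1 m → *Fence with vegetation*, else *Fence or wall*). Boundary
values land in the lower category (exact 20% gaps is not gappy; exact
10% and 50% canopy fall in the middle band; exactly 1 m is not
vegetated).

Density metrics are computed within each farm-year only. NND is the
Euclidean distance to the nearest other territory centre; NTND is the
mean of the three nearest distances. Every pairwise distance is capped
at 1000 m *before* averaging; when fewer than three neighbours exist,
missing neighbours contribute the cap (an isolated territory scores
1000 m for both metrics). `pad_missing=False` instead averages over
the neighbours that exist. Duplicate coordinates within a farm-year
are an error, as a zero distance is ill-defined for territory centres.

## Nest survival (`densnest.survival`)

Visit histories reduce to exposure days using the "last active – B"
rule: failed nests accrue exposure from the first visit to the
midpoint of the last-active and first-inactive visits; successful or
censored nests to the last active visit. Exposure splits additively
into egg and nestling stages at the hatch day; an unknown hatch day
assigns all exposure to the egg stage. A nest is classed as fledged
when nestlings were present at the age-7 check and the age-10 check
found the nest empty and intact; a damaged nest at that check is a
failure.

The Mayfield daily survival rate is 1 − Σfailures/Σexposure with
standard error √(p(1−p)/Σexposure); survival over a period of t days
is DSR^t. The logistic-exposure model generalises this: each nest
contributes a binomial likelihood with trials equal to its (possibly
fractional) exposure days and success indicator equal to its failure
status, with a logit link on the daily failure probability. Fitting
uses Newton iterations started at the exact intercept-only solution
logit(Σf/Σt), which makes the intercept-only MLE identical to the
Mayfield estimator to machine precision. An alternative
interval-censored likelihood (failure probability 1 − (1−h)^t per
nest) is available; it converges to the binomial form at low hazards.
Complete separation (all failures or none) triggers a warning and a
weak ridge penalty (10⁻²) so a finite estimate is still returned,
flagged as penalised.

## Estimation engine (`densnest.glmm`)

A single maximum-likelihood engine covers Gaussian, Poisson,
binomial-with-exposure and cumulative-logit (ordinal) families, each
optionally with independent random intercepts for one or more grouping
factors. Random effects are integrated out by a Laplace approximation:
an inner Newton solve finds the joint mode of the random effects, and
the marginal log-likelihood is the penalised log-likelihood at the mode
plus ½ log-determinant correction. For the Gaussian family the Laplace
approximation is exact; the no-group Gaussian case is solved in closed
form. The outer optimiser is L-BFGS-B over fixed effects, family
extras (residual log-variance, ordinal thresholds) and log variance
components (ftol 10⁻¹², gtol 10⁻⁹), with a Nelder-Mead polish if it
reports non-convergence. Estimation is ML throughout (never REML) so
log-likelihoods are comparable across fixed-effects structures, as
AICc ranking requires. Ordinal thresholds are parametrised as a first
threshold plus cumulative exponentials of increments, guaranteeing
monotonicity. Standard errors come from the numerically differentiated
observed information; when a variance component sits on the boundary
and the full information matrix is singular, the fixed-effects block is
inverted conditional on the variance components.

Parameter counts for AICc include fixed effects, family extras and
variance components. Rank-deficient fixed-effects designs are rejected
rather than silently pivoted.

## Model selection and averaging (`densnest.selection`)

AICc = −2logL + 2k + 2k(k+1)/(n−k−1), with an error when n ≤ k+1.
The dredge enumerates every subset of the free terms that respects
marginality: an interaction requires both parents, a quadratic its
linear term; locked terms appear in every model and satisfy parent
requirements. Quadratic terms are centred before squaring; categorical
covariates are dummy-coded against a reference level. Candidate counts
above 2^20 require an explicit override. Akaike weights are computed
over the full candidate set; the top set is ΔAICc strictly less than 2
(configurable), with weights renormalised within it. Conditional
(subset) averaging is the default — a coefficient is averaged over the
models containing it; full averaging substitutes zeros. Unconditional
standard errors combine within-model variance and between-model
spread: SE = Σ w̃ᵢ √(SEᵢ² + (βᵢ − β̄)²). Confidence intervals are
Wald, estimate ± 1.96·SE.

R² for mixed models follows the variance-partition approach: marginal
= var(Xβ̂)/(var(Xβ̂) + Σσ²ᵤ + σ²ᵣ), conditional adds the random-effect
variances to the numerator. The residual variance is the estimated σ²
for Gaussian models, ln(1 + 1/λ̄) for Poisson (log link, λ̄ the mean
response), and π²/3 for binomial logit models. Ordinal models report
McFadden's 1 − logL/logL₀ instead.

## Demographic projection (`densnest.demography`)

For n pairs (2n adults): successful nests per pair = renesting rate ×
per-nest success; total young = n × that × young per successful nest;
adults next year = 2n × adult survival + young × juvenile survival;
annual change (%) = 100 × (adults next year − 2n)/2n. All arithmetic
is full precision; `summary()` rounds to one decimal (three for nests
per pair) for presentation. A sensitivity helper re-projects over a
grid of any single parameter.

## Simulator scope (`densnest.simulate`)

The simulator generates farms (organic/conventional pairs in clustered
landscapes on non-overlapping squares), boundary segments by habitat
class, Poisson territory counts with a log-linear intensity, territory
centres on the boundary network, nests with daily Bernoulli
stage-specific failure hazards (logit-linear in centred covariates,
including NND), interval-censored visit observation every ≤3 days with
mandated age-7/age-10 checks, provisioning watches with a Gaussian
linear predictor including density-by-corvid and density-by-brood
interactions, and paired nestling mass measurements with linear
growth. Latent truth (hazards, fail days, fates) is retained in
`true_*` columns for recovery testing. Identical config and seed give
byte-identical tables; the RNG is split into independent per-stage
streams so one stage's draws do not perturb another's.

The simulator is a structural emulator, not a fitted model of any real
dataset: its default coefficient values define the study conditions of
the synthetic system, and downstream analyses estimate them from
simulated data.

## Limitations

- Random effects are independent random intercepts only — no random
  slopes and no correlated effects.
- The Laplace approximation can bias variance components for binary
  data with few observations per group; the test suite checks only the
  regimes the pipeline uses.
- Separation in logistic-exposure models is handled by a fixed weak
  ridge rather than Firth correction.
- Exposure reduction assumes visits are error-free and statuses
  correctly recorded; hatch day, when estimated, is the interval
  midpoint.
- Model averaging assumes the candidate set was specified a priori;
  AICc uses the number of rows as the effective sample size for all
  families.
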
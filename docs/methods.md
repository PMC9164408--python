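# Methods

## Problem and model

The Dermatology Life Quality Index (DLQI) scores ten aspects of skin-related
quality of life on severity levels 0–3 (total 0–30). A *value set* maps every
one of the 4^10 level combinations to a single utility on the dead = 0 / full
health = 1 scale, so that DLQI outcomes can be used to compute
quality-adjusted life years. This package implements the full estimation
pipeline for such a value set from 10-year time trade-off (TTO) valuations of
hypothetical DLQI health states: study-design generation, respondent
screening, seven random-intercept regression families, cross-validated
sign-constrained variable selection, and value-set construction, plus a
synthetic-cohort generator so every stage is testable without survey data.

Each survey respondent values five states on a half-year grid of years traded
t ∈ {0, 0.5, …, 10}; utility is y = 1 − t/10, so responses live on the 0.05
grid in [0, 1]. The regressors are incremental ("thermometer") dummies: dummy
(item i, level ℓ) is active when the state's severity on item i is ≥ ℓ, so
each coefficient is the extra disutility of one severity step and the
cumulative effect of level ℓ is the sum of the active steps up to ℓ.

### The seven families

All families share a respondent-level Gaussian random intercept u with
standard deviation σ_u, integrated out of the likelihood by adaptive
Gauss–Hermite quadrature (default 15 nodes; the integrand is recentred and
rescaled at each respondent's posterior mode, found by a vectorised Newton
search on the log-concave integrand).

1. **linear** — y = α + x′β + u + v, v ~ N(0, σ_v²).
2. **censored** — the same latent regression observed with two-sided
   censoring at 0 and 1 (random-intercept Tobit). Boundary observations
   contribute normal tail probabilities; this extracts more information from
   the many capped valuations at y = 1.
3. **ordinal** — equidistant random-intercept ordered probit over the 21 grid
   categories; thresholds κ_j = κ₀ + jδ. Because one category step spans 0.05
   utility, latent coefficients convert to utility units as β_y = 0.05·β/δ,
   and the implied intercept is α_y = 0.05(0.5 − κ₀/δ). This convention makes
   the ordinal column directly comparable with the other families and is
   validated against the censored fit on the same data.
4. **beta** — y | u ~ Beta with probit mean link μ = Φ(α + x′β + u) and
   constant precision φ. Boundary values are compressed into (0, 1) by the
   standard transformation (y(n−1) + 0.5)/n before fitting. Coefficients are
   reported as average partial effects: slopes are scaled by the sample- and
   u-averaged link density, and the reported intercept is the expected
   utility of the all-zero state, E_u Φ(α + u).
5.–7. **scalable linear / censored / beta** — two-part models separating
   scale-usage heterogeneity from health-state effects. Each trader's
   effective scale range is proxied by λ\* = 1 − y(worst state); relative
   disutilities z\* = (1 − y)/λ\* (so z\*(worst) = 1 by construction) are
   pooled and regressed on the dummies with the corresponding one-part
   machinery. The censored variant uses left censoring at z = 0 only, because
   the normalisation z(worst) = 1 deactivates the upper bound. Respondents
   with y(worst) = 1 leave λ\* = 0 and are rejected (or dropped, counted, by
   the model constructor) — they carry no scale information.

**Combination rule for the two-part models.** The utility prediction for a
state x is the mean over the empirical λ\* distribution of
clip(1 − λ·ẑ(x), 0, 1). Utility-scale coefficients are the implied partial
effects: finite differences of that prediction along each item's severity
path from the all-zero state, and the intercept is the prediction at the
all-zero state. When no clipping is active this reduces to scaling the
(sign-flipped) z-coefficients by the mean scale range, which makes two-part
and one-part columns directly averageable. Reported standard errors for the
two-part families are conditional on the observed λ\* values (the scaling by
mean λ\* ignores λ\*-estimation noise) and are flagged as such.

Estimation is maximum likelihood with analytic gradients obtained from the
Fisher identity (the gradient of each respondent's marginal log-likelihood is
the posterior expectation of the joint-score, evaluated at the quadrature
nodes with posterior node weights), optimised by L-BFGS-B with log-parametrised
variance components. Standard errors come from the numerically
differentiated Hessian at the optimum. A brute-force integration oracle
(`loglike_bruteforce`, scipy `quad` per respondent with a grid-located peak
break-point) verifies the quadrature to 1e-6 on small datasets for all seven
families; the linear family is additionally cross-checked against
statsmodels MixedLM.

## Screening

Respondents are classified in a fixed cascade: (1) non-trader (y = 1 on all
five states; kept aside and re-introduced through the weight w); (2) all five
valuations identical but below 1; (3) too-fast responding (minimum response
time ≤ thr_min = 5 s AND median ≤ thr_med = 10 s) OR inconsistency (another
state valued more than 0.10 below the worst state, thr_diff = −0.10); (4)
uninformative (exactly two distinct values, the larger on the worst state);
(5) trader. The time rule and the inconsistency rule are combined with OR
inside one cascade step, matching the single merged exclusion count the
published accounting reports; the AND between the two time thresholds follows
the published wording. A `threshold_grid` utility evaluates alternative
(thr_min, thr_med, thr_diff) combinations, reporting retained sample size,
residual inconsistency and within-respondent variability; choosing among them
is left to the analyst.

## Selection and cross-validation

The theoretical prerequisite is that every severity step has a non-positive
incremental effect. Stage 1 (`backward_eliminate`) refits the reference
family (censored; configurable) and removes the dummy with the largest
positive coefficient, one at a time with refitting, until none remains; ties
break toward the higher item index then higher level. "Non-significant" is
recorded against a two-sided asymptotic z-test at 0.05. Stage 2
(`finalize_model`) runs leave-one-block-out cross-validation (one fold per
randomization block) for all seven families and sequentially removes any
dummy whose coefficient is positive in any fold of any family, until the
cross-validated non-positivity criterion holds for every retained dummy —
this is checked by construction after termination. Removals are sequential
with refitting; fold fits are warm-started from the full-sample fit.

**A caution on support stability.** The all-folds × all-families negativity
criterion is sampling-fragile for weak effects: severity steps whose
published z-statistics are near 1.5 (e.g. the pain/itching level-3 step) turn
positive in at least one of ~126 fold-family fits in a large fraction of
synthetic replicates, so the *exact* retained dummy set varies across
cohorts even at the study's own sample size, typically keeping 9–12 of the 13
reference dummies and at most one or two spurious ones (often an adjacent
severity step of a true item, which under thermometer coding absorbs the same
effect). The defining invariant of the final model — every retained
coefficient non-positive in every fold of every family — always holds, and
the acceptance suite asserts it; the exact-support replication check is
retained as a strict test and documents this variability when it fails.

## Value-set construction

Utility-scale coefficient columns of the censored and scalable-censored
models are averaged element-wise, cumulated over severity levels (inactive
steps contribute zero, i.e. merge with the previous level), and adjusted for
non-traders via ŷ_a = w·1 + (1 − w)·ŷ — equivalently intercept → w + (1−w)α
and effects scaled by (1 − w). The weight w is operationalised as
non-traders / initial full sample (317/2001 ≈ 0.158): this is the only
reading that reproduces the published adjusted column (0.849 → 0.873 requires
w ≈ 0.158, not 317/842 ≈ 0.376); both candidates are computed by the
screening stage and the choice is a config switch. The value set carries
unrounded coefficients end-to-end; rounding (half away from zero, 3 decimals)
is applied only for display — this matters for the enumeration statistics,
where the rounded-cell table gives p95 − p5 = 0.074 instead of the correct
0.073.

Enumeration analyses iterate all 4^10 = 1,048,576 combinations with equal
weight (vectorised lookup; ~1 s), reporting conditional percentiles (linear
interpolation between order statistics) by total score, the score-10
dispersion summary, and mean utility per total score with second differences
as a concavity diagnostic. Predictions are clipped to [0, 1]; with the
reference coefficients no combination reaches the bounds.

## Study design generation

The orthogonal 64-state core is built as a strength-2 orthogonal array over
GF(4)³: columns are linear forms with leading coefficient 1, so any two are
linearly independent and item pairs are jointly uniform — level balance is
exact (16 per level) and all 45 pairwise correlations are exactly zero for
any numeric level coding. The symbol→level mapping forces one all-level-3
("worst possible") run and one all-level-0 run and randomises the remaining
two symbols per column with the seed. Excluding the two extreme states, the
remaining 62 core states have mean total score exactly 15.0 (sd ≈ 2.4,
design-specific). For sizes that are multiples of 4 but not powers of 4, a
randomized balanced search with greedy integer dot-product matching is used
(tolerance 0.02 on correlations); sizes for which no such design is found
raise. Nine supplementary mild states (total scores 1–5) are shipped as
defaults and replaceable by any user catalogue via JSON. Blocks contain the
worst state plus one uniform draw from each of four total-score clusters
(default cut-points: quartiles), with randomized presentation order.

## Synthetic cohorts

The generator emulates the assumed data-generating process: for traders,
y = round₀.₀₅(clip(1 − λ(α_z − x′β_z + u + v))) with

* λ ~ location-shifted symmetric Beta matched to mean 0.504 / sd 0.261 on
  (0.05, 1.0] (the published scale-range moments; the published histogram is
  roughly symmetric, so a symmetric family is used — the fitted shape is
  close to uniform);
* `beta_z` stored as non-positive utility-direction increments (the same sign
  convention as reported coefficients); defaults are the published final-model
  utility effects divided by the mean scale range 0.504, giving z(worst) ≈ 1
  with α_z = 0.30;
* u skew-normal with sd σ_u = 0.25 and skewness −0.72 (the published skewness
  of the individual component); v Gaussian with σ_v = 0.23. The variance
  split is calibrated so simulated within-state dispersion (~0.24) matches
  the published trader statistic 0.241; it is a package choice, not a
  published quantity.

Non-trader probability is logistic in the mildest block state's total score
(defaults −2.6 + 0.134·score, matching the published 7.8%–26.9% range and
≈0.158 overall). Careless responders are a separate mixture class (weight
0.65 among non-non-traders, to mirror the ~69% exclusion rate) with three
behaviours: constant value below 1, fast random grid responses, and two
nearby values with the larger on the worst state; response times are
lognormal (careful median 25 s, careless 4 s, low-information 14 s). The
mixture gives the screening cascade true positives with recall ≥ 0.8 in the
tests. What the generator does *not* emulate: demographic covariates, the
empirical joint dependence between carelessness, response time and valuation
variability (the mixture is a stand-in), within-session learning, and any
real-data state-specific idiosyncrasies — so passing recovery tests shows the
estimators work under the assumed model, not that the model is true of any
survey.

## Problem sizes used in the test suite

Tests run the pipeline at reduced but representative sizes chosen as part of
the package design: likelihood-oracle checks on 5 respondents; parameter
recovery with 20 cohorts of 500 traders over 18 blocks; selection replicates
on 3 trader cohorts of 420 respondents over 7 blocks; screening and
consistency checks on one full mixture cohort of 2001 respondents. The
acceptance script's quantities are deterministic (a desk calculation from the
stored reference coefficients) and do not depend on these sizes.

## Known limitations

* Ordinal and beta utility-scale standard errors ignore the covariance with
  the scale parameter (delta-method diagonal only).
* The censored family assumes homoskedastic normal latent errors; under the
  two-part generating process the error is heteroskedastic (λ-scaled), which
  biases the intercept upward by ~0.02 while leaving partial effects nearly
  unbiased (the recovery test bounds the latter at ±0.02).
* `finalize_model` is sequential with refitting; a simultaneous-removal
  variant would terminate at the same defining invariant but may retain a
  different borderline set.
* The exact 73-state catalogue of the published survey is not distributed;
  the generator reproduces its stated design criteria and any real catalogue
  can be loaded from JSON.
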
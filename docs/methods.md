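# Methods

## What the package evaluates

A practice risk-stratifies its panel into four ordered tiers; an HCC-style
score is computed independently from age, sex and diagnosis codes, tiered at
quantile cut-points matched to the practice's tier sizes, and the two
"very-high" flags are compared twice: (1) how often they agree on who is high
risk, and (2) how well each predicts next-year high utilization. Because both
flags are evaluated on the same patients, all significance tests are
paired-design tests.

## Scoring model

The score is additive: one demographic weight per (sex, age-band) cell plus
one weight per *surviving* condition category. Diagnosis codes map
many-to-one onto categories; hierarchy rules (dominant category, suppressed
set) remove milder related categories. Rules are applied to a fixpoint, with
dominance judged on the categories present at the start of each pass — so a
chain A⊳B, B⊳C removes both B and C from {A, B, C}, and a category can
suppress others even when it is itself suppressed in the same pass (this
matches the usual claims-model convention of applying rules to the recorded
diagnoses). Scores are not clamped to any observed range. Unmapped codes are
skipped but counted in the log, since real EHR feeds are dirty and silent
data loss should be visible. Age bands are half-open [lo, hi) so boundary
membership is unambiguous.

The shipped model is a deliberately small toy (9 categories, 18 codes, 3
hierarchy rules) in the same three-file CSV format accepted for user-supplied
tables; it makes no attempt to reproduce any licensed coefficient set.

## Tiers and outcome cut-points

Tier thresholds are empirical quantiles at the cumulative target proportions.
Tied scores always stay in one tier (deterministic, auditable), at the cost
of achieved tier sizes deviating from targets when ties straddle a boundary;
when a tie block swallows a threshold entirely, the threshold is advanced to
the next distinct score so the three cut-points remain strictly increasing.
The default high-risk flag is the single top tier (a `high_or_very_high` rule
is available). Outcomes are dichotomized inclusively at $30,000 / 2 ED visits
/ 1 hospitalization by default; an alternative selects the expenditure
cut-point as the largest threshold whose ≥-group carries a target share
(e.g. two-thirds) of total spend. Cut-points are naturally calibrated on
prior-year outcomes and evaluated on follow-year outcomes (prediction of
future risk); both windows are selectable.

## Agreement and paired comparisons

Agreement is reported on the binary high/not-high collapse (percent
agreement, Cohen's κ, Landis–Koch bands with right-closed boundaries,
both-over-either overlap) together with the full 4×4 tier cross-tabulation;
a weighted 4-level κ is deliberately out of scope. For κ the degenerate case
p_e = 1 returns 1 when agreement is perfect; for 2×2 tables p_e = 1 with
imperfect agreement cannot occur.

Paired sensitivities: restricted to outcome-positive subjects, the subjects
flagged by exactly one test split Binomial(m, ½) under the null of equal
true-positive fractions. The exact binomial two-sided p-value is used for
discordant totals m < 25, the asymptotic z = (b − c)/√(b + c) otherwise.
This is exactly McNemar's test on the positive subset.

Paired PPVs: the estimate is the relative predictive value
rPPV = PPV_A/PPV_B; the test statistic is log rPPV divided by its standard
error from the empirical influence function of
log(mean(A·D)/mean(A)) − log(mean(B·D)/mean(B)), which carries the
covariance induced by overlapping flagged sets without any independence
assumption. Both tests hold their nominal size (type-I error within
[0.03, 0.07] at α = 0.05 in the suite's 2,000-replicate null simulation) and
the PPV test agrees with a paired nonparametric bootstrap; note the
log-ratio is visibly skewed when a flagged-and-true count is ~10, where
delta-method and bootstrap p-values can differ by a few hundredths — both
are honest approximations in that regime.

Undefined ratios (zero denominators) propagate as NaN and render as blanks,
never as zeros. Full precision is kept everywhere; rounding happens only in
formatting.

## Synthetic populations

The generator emulates the structure the analysis needs, not any particular
health system:

* **Latent severity** λ is log-normal (log λ standard normal by default);
  chosen for its heavy right tail, which is what lets a top decile of
  patients carry ~⅔ of total spend.
* **Conditions** are Bernoulli with logistic probability in log λ; the
  intercept is solved by Gauss–Hermite quadrature at generation time so each
  configured marginal prevalence holds exactly in expectation for any
  severity loading. Default roster: diabetes 11% (complicated 3%), neoplasm
  11% (metastatic 2%), heart disease 10% (heart failure 4%), psychiatric 8%,
  lung 5%, renal 4%, using the toy code vocabulary.
* **Utilization counts** (ED, hospitalization) are negative binomial with
  mean baseline·exp(elasticity·log λ) and year-specific draws sharing the
  person-level mean, which induces the prior/follow-year correlation without
  an extra autocorrelation parameter. Defaults (baseline 0.365, elasticity
  0.95, dispersion 1.02 for ED; 0.127 / 1.05 / 0.55 for hospitalization) are
  the analytic solutions for tail rates ED≥1 = 30%, ED≥2 = 12%,
  hosp≥1 = 14%.
* **Expenditures** are exp(7.35 + 1.35·log λ + 1.38·ε) plus $1,000 per ED
  visit and $12,000 per hospitalization, calibrated so ~9% of patients exceed
  $30,000 and the top decile carries ~⅔ of total spend.
* **Demographics**: 57% female; age is truncated normal on [18, 98] with the
  location solved at generation time so the realized mean is 60.8 (sd 19).
  Payer class is 8.8% Medicare / 1.2% dual / 90% other, giving the ~10%
  outcome-reliable subset with an 88:12 Medicare:dual split.
* **Practice tiers** come in three modes: *intuition* (quantile tiers of
  log λ + Normal noise, sd 2.0 by default — heavy noise, so intuition is far
  less sensitive than the algorithmic score, mirroring the large performance
  gap observed between intuition-only and adjudicating practices),
  *algorithm* (quantile tiers of the toy score computed from observed codes
  only), and *adjudication* (algorithm tier, replaced with probability 0.5
  by the latent-severity tier — a reviewer who sometimes recognises true
  severity the coded record misses). Default tier targets are
  (0.55, 0.25, 0.10, 0.10): the ~10% very-high tier matches the share of
  patients that the outcome cut-points are designed to capture.

The default calibration reproduces, at n = 40,000, the margins listed in the
module docstring (each within Monte-Carlo error across seeds); the toy-score
quartiles land at ≈ (0.28, 0.60, 0.83).

What the generator does **not** emulate: care-management feedback on
follow-year outcomes (the practice acting on its own flags), realistic code
frequencies or claims adjudication, multi-practice heterogeneity within one
panel (run several configs instead), informative missingness, or payer-class
correlation with age. Passing calibration tests therefore says the pipeline
is correct and well-calibrated *under this generative model*, not that any
particular real panel behaves this way — on real data the practice-vs-score
comparison can go the other way entirely.

## Study orchestration

`RiskStratificationStudy.fit()` applies the retention filters in order (seen
before stratification → valid practice tier → not deceased/left; the outcome
cohort additionally requires Medicare/dual payer), scores the cohort, fits
cut-points (by default matched to the practice's achieved tier proportions),
computes agreement on the full and outcome cohorts, dichotomizes follow-year
outcomes, and produces the metric, paired-comparison and (optionally)
stratified tables plus a JSON manifest (config echo, seed, thresholds,
versions). Identical inputs and seed give identical outputs, including file
bytes.

## Problem sizes used in the shipped checks

Calibration checks run at n = 40,000 (one shared generation), mode
comparisons and concentration monotonicity at n = 20,000, the null
simulation for test size at n = 1,000 × 2,000 replicates, and bootstrap
validations at n = 800–1,200 with 4,000–10,000 resamples — sizes at which
the Monte-Carlo error is comfortably below every tolerance asserted.

## Known limitations

* The toy score is coarse (many ties); tie handling makes algorithmic tier
  sizes deviate slightly from targets, which is by design but means achieved
  proportions should always be read from the cut-point object.
* The PPV test's delta-method p-value is a large-sample approximation; with
  fewer than ~20 true positives among a flagged set, prefer the bootstrap.
* c-statistics for the practice rubric are computed on tier ranks (4 levels),
  so they are coarse and tie-heavy by construction.
* The adjudication model corrects *toward the truth* with fixed probability;
  real adjudication can also inject error, which the generator does not model.
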
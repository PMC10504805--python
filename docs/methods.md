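# Methods

## Cohort model and eligibility

The analytic unit is one participant observed at a 2006-style baseline and
a single 12-year outcome ascertainment: edentulous (lost all natural
permanent teeth) or still dentate. Eligibility is complete-case: records
already edentulous at baseline are removed first, then records missing the
outcome, then records missing any analysis covariate. A record missing
several covariates is attributed to exactly one exclusion reason — the
first matching variable in the fixed order cognition, loneliness, income,
smoking, alcohol, dental visit, self-rated health, then age, race, gender,
education. The order follows the magnitude ordering of per-variable
missingness typical of such survey cohorts (cognition dominates) and makes
the exclusion log comparable across runs; a different convention would
redistribute counts among reasons but never change the retained cohort.

## Predictor coding

All predictors are coded exactly as the final equation consumes them:

| term | meaning | reference |
|------|---------|-----------|
| R1, R2, R3 | African-American, Hispanic, other race | Caucasian |
| G | male | female |
| A | age in years / 10 (no centering) | — |
| E0, E1 | no high school, less than college | college+ |
| S0, S1 | current, former smoker | never |
| D | last dental visit > 2 y | within 2 y |
| C | cognition score < 23 | ≥ 23 |
| AL | does not drink alcohol | drinks |
| H | fair/poor self-rated health | good+ |
| LN | felt lonely | not lonely |
| I1, I2 | income < $25k, $25–75k | ≥ $75k |

Candidate-predictor references (alcohol = drinks, health = good+,
loneliness = no, income = highest band) were chosen so that each indicator
points toward the hypothesised risk direction, consistent with education's
college+ reference. The cognition score is consumed as a 0–35 summary
number and dichotomised at 23, the conventional low-normal boundary; a
score of exactly 23 codes C = 0.

## Synthetic cohort generator

The generator emulates the analytic sample's published structure, not its
unpublished joint distribution:

- **Marginals.** Category probabilities default to the analytic cohort's
  frequencies (n = 4,288), e.g. 398/4,288 current smokers, 1,424/4,288 low
  cognition. Age is Normal(66.3, 8.4) truncated below at 51 (the cohort is
  adults > 50) and rounded to whole years.
- **Outcome.** Bernoulli with logit given by a configurable truth,
  defaulting to the final 7-variable equation. When `target_incidence` is
  set, the intercept is re-solved by Brent root-finding on the realized
  covariates so the expected incidence matches to 1e-4.
- **Dependence.** Covariates are independent by default, because only
  marginals are published. Optionally a single latent "disadvantage"
  factor with loading `dependence` ∈ [0, 1) shifts the quantile cutpoints
  of education, income, smoking, dental visit, cognition, self-rated
  health and loneliness (levels ordered by increasing disadvantage),
  inducing the positive co-variation these variables show with the outcome
  in real cohorts. Race, gender and alcohol are left unloaded.
- **Cognition scores.** The model only uses the < 23 indicator; integer
  scores are drawn uniformly on 5–22 (low) or 23–35 (normal) to populate
  the field realistically without asserting a score distribution.
- **Reproducibility.** Each record consumes a fixed 16-uniform block of a
  single seeded PCG64 stream, so record k is identical for every cohort
  size ≥ k and cohorts are byte-identical across runs at the same seed.

What this does **not** emulate: survey weights, household clustering,
attrition/mortality, and — most importantly — the real covariate
correlation structure. Discrimination of a model depends on that joint
structure, so the synthetic AUC under independence (≈ 0.63 for the
7-variable model) is expected to sit below the ≈ 0.75 achievable on real
cohort data; passing tests demonstrate the pipeline's correctness and the
selection procedure's behaviour, not real-data performance.

## Numerical engine

Logistic models are fitted by Newton–Raphson (IRLS) from a zero start,
stopping when the largest absolute coefficient update < 1e-8 or the
log-likelihood change < 1e-10, with at most 50 iterations and no
regularisation. The observed information at the final iterate supplies the
Wald covariance; a coefficient exceeding 15 in magnitude is treated as
(quasi-)complete separation and the fit is flagged non-converged rather
than returned silently. A linearly dependent design raises an error. Tests
cross-check estimates, standard errors and log-likelihoods against
statsmodels and against closed forms on saturated 2×2 problems.

AUC is the Mann–Whitney concordance with half credit for ties — required
for degenerate synthetic score vectors — and is identical to the
trapezoidal ROC area; tests verify both identities and agreement with
scikit-learn. Whole-factor ("Type III") tests are likelihood-ratio tests
obtained by refitting without the factor's indicator block; Wald and LRT
are asymptotically equivalent here and the LRT is the better-behaved
choice at moderate event counts. Odds-ratio intervals are Wald on the log
scale at z = 1.96 for 95%.

## Selection design

- Selection/Test split: round(0.70 · n) records to Selection, halves
  rounded away from zero — 4,288 → 3,002/1,286. Splits are simple random
  (unstratified); halves that would contain a single outcome class are
  re-drawn (up to 100 attempts).
- MCCV: the validation half is a fixed **count** (default 1,286, equal to
  the Test size) rather than a fraction, which reproduces the 1,716/1,286
  training/validation arithmetic exactly and keeps validation AUCs on the
  same scale as the final test AUC. All 32 models share each replicate's
  partition. Replicate r draws from a child seed of (root, r), so any
  replicate is reproducible in isolation. A non-converged (model,
  replicate) fit is recorded as missing and excluded from that model's
  mean, with a warning.
- Parsimony: the selected model is the smallest one whose mean validation
  AUC is within `parsimony_tolerance` (default 0.002) of the maximum; the
  default treats AUC gains of ≤ 0.002 from extra variables as negligible,
  and a strict round-to-3-decimals tie rule is recovered by shrinking the
  tolerance toward zero. Remaining ties break to fewer candidates, then
  canonical enumeration order.

## Final validation

The selected model is recalibrated (refitted) on the full Selection set
and applied to the untouched Test set. The bootstrap draws B = 1,000
with-replacement resamples at full test size; single-class resamples are
re-drawn so exactly B AUCs enter the summary. The reported "final AUC" is
the bootstrap mean, with the 2.5th/97.5th percentiles as the 95% interval;
the plain point AUC is reported alongside since the two are numerically
close and easily conflated. Classification metrics use the prevalence
cutpoint — the exact, unrounded observed Test-set incidence by default —
with score ≥ cutpoint counting as predicted positive; metrics with empty
denominators are NaN-flagged, never silently zero.

## Descriptives

Table-one cross-tabs report counts and row percentages by outcome with
Pearson chi-square tests (no continuity correction by default; a Yates
switch exists for 2×2 tables). The age comparison uses Welch's
unequal-variance t-test as the safer default. Companion unadjusted odds
ratios use the Woolf log-scale interval with Haldane–Anscombe 0.5
correction only when a cell is zero; tables with an empty row or column
are flagged undefined.

## Problem sizes in the test suite

Marginal, dependence and parameter-recovery checks use n = 100,000
cohorts (recovery tolerance ±0.1 on every coefficient, comfortably wide
relative to the Wald standard errors at that n). The selection-behaviour
check runs 20 independent pipelines of 32 models × 100 MCCV replicates on
n = 3,002 cohorts; 100 replicates estimate a model's mean AUC to ≈ 0.002,
enough to rank the cognition model above the core-6 model every run.
Bootstrap coverage is checked at nominal 95% over 100 simulated test sets
of n = 1,286 with B = 500 resamples.

## Known limitations

- Complete-case only; no imputation.
- No survey weights, interactions, calibration measures (e.g.
  Hosmer–Lemeshow), or criteria other than AUC.
- The exclusion-attribution order is a convention (see above).
- Real-data discrimination is not reproducible from published marginals
  alone; the generator's `dependence` parameter is a structural knob, not
  an estimate of the true correlation.
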
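# Methods

## The scoring model

The score is a deterministic additive rule over five chart-available risk
factors, with no fitted parameters:

- **Age** (years): 40–49 → 0, 50–59 → 1, ≥60 → 2. The published category
  reads "over 60", but the derivation cohort's age classes (50–59, 60–69)
  place 60 in the upper class, and the stated rationale — colorectal cancer
  risk roughly doubling after 60 — supports the closed threshold, so 60
  itself scores 2. The score is undefined below 40 (the study inclusion
  age); records with age < 40 raise an error rather than being scored.
- **Gender**: male 1, female 0.
- **Smoking**: current smokers 1; never-smokers and former smokers are
  pooled as non-smokers and score 0. Unknown smoking status is rejected
  rather than imputed (the derivation cohort had complete smoking data).
- **BMI** (kg/m²): <25 → 0, ≥30 → 1; 25–29.99 → 1 for women and 0 for men,
  reflecting the excess of positive tests among overweight women observed
  in the derivation cohort. Bins are half-open [lower, upper): a published
  bound of "29.99" is read as "up to but not including 30", consistent with
  the "≥30 = obese" definition. Underweight (<18.5) has no special rule and
  scores 0.
- **Comorbidities** (type-2 diabetes, dyslipidemia, hypertension, each
  operationalized as being on the corresponding treatment): none → 0, one
  → 1, two or three → 2 (capped).

Totals 0–7 are grouped into risk bands: four-band 0–3 / 4 / 5 / ≥6, or the
collapsed three-band low (0–3) / medium (4–5) / high (6–7). Scores 0–3 are
reachable on age and gender alone (unmodifiable factors), which is why they
form a single band; no patient in the derivation cohort reached 7, which is
why 6 and 7 are pooled.

BMI is taken as an input column; a helper computes it from height and
weight when only raw anthropometry is recorded.

## Cohort analytics

- **Descriptive blocks** mirror spreadsheet "Descriptive Statistics"
  output: sample SD (n−1), adjusted Fisher–Pearson skewness
  n/((n−1)(n−2))·Σ((xᵢ−x̄)/s)³, and "Confidence Level (95.0%)" as the
  t-based half-width t₀.₉₇₅,ₙ₋₁·s/√n. The mode of a tied sample is
  reported as the smallest most-frequent value with a multimodality flag
  (published single modes do not reveal the original tie-break). Constant
  samples report SD 0 and an undefined (None) skewness.
- **Band summaries** count positive/negative FOBT per band; empty bands
  report undefined (None) rates, never 0.
- **Risk estimates** attach 95 % Clopper–Pearson (exact beta-quantile)
  intervals to the band rates — the published report gives point rates
  only; intervals contextualize the small-n bands. Wilson intervals are
  available as an alternative.
- **The significance test** is the pooled (equal-variance) two-sample t,
  df = n₁+n₂−2, applied to the four per-band positive counts versus the
  four per-band negative counts. This choice of "the two sets of values"
  reproduces the published t = −3.49663 at df 6 exactly, and the published
  p (0.00644) equals the one-tailed tail probability at that t; both tails
  are therefore reported rather than guessing intent.
- **Cross-tabulations** stratify by any of gender, FOBT result, BMI class,
  age class (40–49 / 50–59 / 60–69 / ≥70, closed integer bins), individual
  comorbidity flags, or comorbidity count, with percentages against either
  the cohort size (the convention of the published BMI table, confirmed
  arithmetically: 54/112 = 48.21 %) or row totals. Report percentages are
  rendered at 2 decimals; internal values keep full precision.

## Pseudo-cohort reconstruction

The derivation study published only summary tables, but those tables pin
the 112-patient cohort down almost completely. `reconstruct_reference_cohort`
builds one individual-level cohort consistent with them by solving a small
integer program (scipy's HiGHS backend) over joint category-cell counts
(gender × comorbidity pattern × FOBT × BMI class × age class × smoking;
1,536 integer variables):

- **Hard constraints (equalities):** the band × FOBT table, the BMI-class ×
  FOBT table, the gender × comorbidity-count × FOBT table, and the three
  comorbidity marginals (DM 25, DYSL 77, HTA 78). These imply the 51/61
  gender split, 20 positives, and 19 zero-comorbidity patients.
- **Soft constraints (weighted L1 slack):** cohort age-class counts and the
  smoking gender split, the per-gender comorbidity counts, and the two
  finer published breakdowns (positives by age class × BMI class × gender;
  comorbidity flags by BMI class × FOBT × gender). These are matched as
  closely as the hard constraints permit; the achieved residual is 2 cell
  units across 132 soft cells (one ≥70 overweight positive is male where
  the finer breakdown implies female), printed by
  `reconstruction_report`.

If the hard system were infeasible the solver fails loudly; no hard
constraint is ever silently relaxed. Cell counts are expanded into records
deterministically: ages and BMI values cycle through fixed within-class
representative lists (which include the published extremes 40/88 years and
17.60/41.20 kg/m²), so repeated reconstruction is byte-identical. The
result is *a* cohort consistent with the published tables — per-patient
ages and BMI values within a class are not recoverable, so the whole-cohort
age/BMI descriptive blocks (mean 65.30 years, BMI mean 28.46, etc.) are not
reconstruction targets; the descriptive-statistics code is instead verified
against direct-formula oracles on synthetic vectors.

## Synthetic-cohort generator

`generate(CohortSpec)` draws cohorts with the structure the analytics
assume. Defaults are the derivation cohort's published marginals and are
not tuning knobs:

- n = 112; P(female) = 61/112; age classes 40–49 / 50–59 / 60–69 / ≥70
  with probabilities 8/112, 26/112, 38/112, 40/112 and uniform integer
  ages within class (70–88 for the open class; the published within-class
  shape is unknown, uniform is the least-informative choice);
- BMI ~ Normal(28.46, 4.66²) truncated to [17.60, 41.20] kg/m², the
  published moments and extremes. The published skewness (0.31) is not
  targeted; a truncated normal only approximates it (limitation);
- P(current smoker) = 20/112; comorbidity marginals 25/112, 77/112, 78/112;
- the three comorbidities follow a trivariate Bernoulli from a log-linear
  model with exact marginals and a common pairwise odds ratio θ. The
  published comorbidity-overlap figure is not machine-readable, so θ
  defaults to the value (≈4.37) calibrated so that P(no comorbidity) =
  19/112, the published zero-comorbidity fraction. Main effects are solved
  coordinate-wise by bracketing (each marginal is monotone in its own
  effect), to 1e-13; θ = 0 (mutual exclusivity) is accepted only when
  p₁+p₂+p₃ ≤ 1, otherwise the violated Fréchet bound is named;
- FOBT is Bernoulli with the probability of the record's four-band rate
  (defaults 3/31, 2/20, 7/41, 8/20) — the derivation report asserts
  band-level rates only. A per-point logistic model
  P(pos) = σ(intercept + slope·S) is provided behind `fobt_model="logistic"`
  as a clearly-labelled extension for power-analysis use.

Generation is vectorized and deterministic given (spec, seed). Parameter
recovery (marginals to <0.01 absolute at n ≥ 30,000; band rates to <0.01 at
n = 100,000) is asserted in the test suite. What passing these tests shows
is that the pipeline is self-consistent under the assumed generative
structure; real screening data would add within-class age/BMI shape,
residence and calendar-time structure, and comorbidity associations beyond
a single pairwise odds ratio, none of which are claimed here.

## Numerical and interface choices

- Comparisons against published values use the published rounding
  (2 decimals for percentages, 5 for t). The published 83.03 % for
  "≥1 comorbidity" is one unit in the last place below the exact
  93/112 = 83.04 %; the reproduction check allows exactly that slack.
- CSV dialect is fixed (comma separator, dot decimal, UTF-8, LF) to avoid
  locale drift. Strict reading aborts on the first invalid row naming it;
  lenient mode skips with a logged warning, mirroring the study's exclusion
  of incomplete records.
- CLI exit codes: 0 success, 2 input-validation failure, 3 reproduction
  mismatch. Reports embed package version, seed and configuration.
- Problem sizes in the tests (30,000-record marginal recovery,
  100,000-record band-rate recovery, 25 random t-test samples) keep the
  whole suite under half a minute while leaving Monte-Carlo error well
  inside the asserted tolerances.

## Known limitations

- The pseudo-cohort is one member of an equivalence class; analyses that
  depend on within-class age or BMI values (means, skewness) reflect the
  chosen representatives, not the original data.
- The score itself is taken as given; no calibration, discrimination or
  validation modelling is included, and colonoscopy follow-up is out of
  scope.
- The generator's band-conditional FOBT model makes band rates exactly
  recoverable by construction; it cannot probe miscalibration of the score
  itself.
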
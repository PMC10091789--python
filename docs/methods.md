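# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `pgxtwist`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Additive hazards regression

The statistical core is the Lin–Ying semiparametric additive hazards model
with time-fixed coefficients: h_i(t) = λ0(t) + β′z_i, where β are per-year
hazard differences. A constant-coefficient summary is the right scale for a
genetically moderated treatment effect quoted as "x% extra risk per year of
treatment"; a fully time-varying (Aalen) fit with post-hoc averaging would
estimate the same quantity less directly and less stably, and is not
implemented.

The estimator solves the closed-form least-squares estimating equation over
risk sets (`pgxtwist.additive._linying_solve`):

- `A = Σ_i ∫ Y_i(t){z_i − z̄(t)}⊗2 dt`, `b = Σ_events {z_i − z̄(T_i)}`,
  `β̂ = A⁻¹b`, computed with suffix cumulative sums over sorted follow-up
  times — O(n log n + n p²) per fit, no iteration, no convergence issues.
- Risk-set centering annihilates any constant column, so the design must not
  include an intercept; the baseline is absorbed nonparametrically and a
  residual occurrence/exposure rate (`baseline_rate_`) is reported for
  interpretation. When the true baseline is constant this residual rate is
  the exponential MLE.
- Variance is the sandwich A⁻¹BA⁻¹ with B the sum of outer products of
  per-subject martingale-residual scores
  ε_i = ∫{z_i − z̄}dM̂_i (Breslow-type baseline increments included).
  The ε_i sum to zero exactly at the solution, and their per-subject values
  are exposed as influence functions (`influence_`).
- Ties (day-resolution dates) are handled exactly: tied intervals have zero
  length and risk sets are evaluated at the first member of each tie group.
- Degenerate inputs raise immediately: non-positive durations, non-0/1
  events, zero events, constant columns; an exactly singular design raises
  an error naming the collinear columns (smallest QR R-diagonal entries).

The two-group, no-covariate, common-censoring case agrees with the
closed-form occurrence/exposure rate difference; this oracle equivalence is
asserted in the tests.

## TWIST estimation

`pgxtwist.twist` computes five GMTE estimators from additive-hazards fits,
with the same covariate adjustment as the Cox scan (age at first
prescription, sex, ten principal components; constant covariates in a subset
are dropped):

- GMTE1 and GMTE0: carrier coefficient among treated / never-treated;
  RGMTE = GMTE1 − GMTE0 (exact identity; its variance is the sum because
  the subsets are disjoint).
- MR: full-sample carrier coefficient divided by the treated proportion,
  SE scaled identically. The sampling variability of the treated proportion
  is ignored (second-order under the null of interest).
- CAT: difference of adjusted treatment coefficients between carrier
  strata. All four genotype×treatment cells must be non-empty.

**Combination.** Candidate estimates that pass a heterogeneity gate are
pooled by inverse-variance weighting. The candidate sets are tried in the
order {RGMTE, MR, CAT}, {RGMTE, MR}, {RGMTE, CAT}, {MR, CAT}, RGMTE alone
(largest consistent set first, robust estimators preferred), at α = 0.05.
Because the estimators are built from overlapping subjects they are
positively correlated, and a combination that assumes independence
understates the combined variance — measured on the package's own null
simulations, the naive combined test rejected at ~8.6% instead of 5%.
The package therefore assembles the covariance of the candidate set from
the per-subject influence functions (inner products over shared subjects)
and uses generalised least-squares weights and a generalised Q statistic.
With the covariance supplied the null rejection rate is ~5–6% (asserted at
500 seeds in the acceptance tests). Estimates supplied without influence
information (e.g. hand-entered numbers) fall back to the classical
independent-weights IVW and Cochran Q.

GMTE0 doubles as a negative control: when it is individually significant
the report marks MR- and GMTE1-based conclusions as suspect, since a direct
genotype effect violates their identifying assumption.

**CAT under confounding.** In this package's constant-additive world, any
confounder of treatment that is independent of genotype biases the
*as-treated* treatment coefficients in both carrier strata by the same
amount, so the difference-in-differences CAT cancels it exactly — the same
cancellation that protects RGMTE. The distinction the framework draws
(CAT vulnerable to treatment–outcome confounding, RGMTE not) only
materialises under effect structures outside this generator class, e.g.
confounder effects that differ by genotype, which would bias both
estimators equally here. The confounded generator mode (latent frailty
raising both treatment odds and hazard) is used in the tests to show the
naive as-treated estimate is biased while RGMTE and CAT are not.

## Cox association scan

The scan is deliberately conventional: lifelines `CoxPHFitter` (Efron tie
approximation — appropriate for GP day-resolution dates with heavy ties),
Wald CIs and p-values, one model per variant×outcome among treated patients
only, prior-outcome patients excluded per outcome. Genotype codings:
genotypic (het + hom indicators vs common homozygote), dominant (carrier),
additive (dosage). Benjamini–Hochberg adjustment is applied per outcome
across all contrast rows of the panel (the step-up adjustment is 6 lines
and is cross-checked against statsmodels in the tests; it supports a
family-size override for partially testable families). Sensitivity options
mirror the study designs: adjust for co-prescribed antihypertensives,
restrict to amlodipine-only or other-dCCB-only users, restrict to
unrelated participants (an externally supplied exclusion list).

The Cox scan on data generated under additive hazards is *not* expected to
recover the additive-scale truth — hazard ratios and per-year differences
live on different scales. Tests assert direction, interval coverage and
null calibration, not scale agreement.

## Cohort construction

- **Exposure.** A patient enters the treated cohort with ≥2 dCCB scripts
  (`min_prescriptions=2`). Prescribing censor = GP deduction date if
  present, else 2016-05-31; raw GP records outside 1990-01-01..2017-08-31
  are rejected as malformed (runs abort if >1% of rows are malformed).
- **Outcomes.** Prior flag: any matching diagnosis on/before the time
  origin (those patients are excluded from that outcome's incident
  analysis). Incident event: first matching diagnosis strictly after the
  origin and on/before min(deduction, hospital horizon 2020-09-30).
  Diagnosis codes map to outcomes by vocabulary + code prefix from an
  editable table; the shipped ICD-10/ICD-9/Read lists are illustrative
  defaults, not a clinically validated code set.
- **Untreated comparators** are patients never prescribed any dCCB; their
  time origin is study entry (first record date). Their "age at first
  prescription" covariate is age at entry.
- **Switching.** The record streams never label a switch explicitly, so an
  operational rule is used: the first non-dCCB antihypertensive issue after
  the first dCCB script with no further dCCB script within `gap_days` (=90)
  after it. Co-therapy alongside continuing dCCB scripts is not a switch.
- Dates are day-resolution; intervals are converted to years by /365.25.

## Synthetic-data generator

The generator (`pgxtwist.simulate`) emulates the features of the data the
estimators rely on; its defaults are the study conditions.

- Genotypes: two Bernoulli(MAF) allele draws per subject (exact
  Hardy–Weinberg); one causal variant at a time, all other panel variants
  null, which keeps ground truth interpretable for recovery tests.
- Treatment: Bernoulli(p_treated), independent of genotype. Violation
  modes: `treat_geno_or` (genotype-dependent treatment odds, for
  assumption-check power tests) and `confounding` (latent frailty raising
  both treatment odds and hazard).
- Outcomes: exponential event times with constant additive cell hazards
  h0 + bT·T + bG·G + bGT·G·T; negative cells are a configuration error
  naming the offending subgroup, never truncated. Censoring = min(GP
  deduction ~ Exp(0.02/y), administrative horizon).
- Prescribing: per-patient script rate ~ N(9.2, 4.6)/y clipped to [1, 25];
  episode ends by cessation (Exp(0.14/y), giving a mean first-to-last
  span near 5.9y under a 13y horizon); 13.5% of cessations become switches
  (first alternative script 30 days later) so ~10% of treated patients
  switch; 61% get a co-prescribed antihypertensive mid-episode; 7.1% carry
  a prior MI/angina diagnosis. Age at first script ~ N(61.3, 7.7) truncated
  to [40, 79.3]; 45.6% female; ten standard-normal principal components.
- The written bundle round-trips: the cohort builder reproduces treated
  flags, event flags and follow-up times to the day, which the tests
  assert. Deduction dates encode all censoring (dropout and administrative)
  so that file round trips are exact.

**rs877087/HF study conditions** (`ryr3_hf_config`): 31 074 treated,
190 000 untreated (the untreated pool size is not a published quantity; the
default is the order of a GP-linked cohort minus the treated), MAF 0.46
(carrier frequency 0.708), bGT = 0.00069/y, bG = 0, h0 = 0.002/y,
bT = 0.0029/y, 13-year horizon. The baseline and treatment increments are
plumbing chosen so the simulated cohort reproduces the two anchors that
matter for impact arithmetic: ~1850 treated HF diagnoses and ~243 000
carrier patient-years on treatment.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: confounding by indication beyond the explicit
frailty mode, time-varying hazards and seasonality, LD between variants,
genotype missingness patterns, miscoded or free-text records, competing
risks (death), informative censoring, non-European allele frequencies.

## Problem sizes and determinism

Every random draw flows from a single integer seed through named
`numpy.random.default_rng` streams; identical seeds give byte-identical
study bundles. The acceptance script averages 40 replicates of the
full-scale (221k-subject) recovery experiment; the test suite uses the same
full-scale recovery at 40 seeds, a 500-seed null calibration at 10 000
subjects per seed, and tenth-scale cohorts elsewhere — sizes chosen so the
Monte-Carlo error of each check sits well inside its assertion tolerance.

## Known limitations

- The additive-hazards fit has no penalisation; near-collinear designs
  fail loudly rather than being regularised.
- MR's SE ignores the estimation error of the treated proportion.
- The switch definition is one reasonable operationalisation; switch-rate
  comparisons across datasets with different prescribing cadences should
  re-examine `gap_days`.
- `percent_cell` reproduces printed-table rounding (2 dp for switching
  tables, 1 dp elsewhere); it is a presentation helper, not an inference
  tool.
- VCF genotype input is not implemented; genotypes are read from the long
  TSV format.
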
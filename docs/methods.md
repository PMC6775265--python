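# Methods

`pvsignal` implements the standard signal-detection workflow for
spontaneous-report (SRS) databases such as FAERS and JADER: case-level
ingestion and deduplication, MedDRA-style event definition, crude and
stratified reporting odds ratios (ROR), covariate-adjusted RORs from a
stepwise multiple logistic model, and Weibull time-to-onset profiling.
This note records the models, their assumptions, the defaults, the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## Data model and ingestion

A report set is three aligned tables keyed by `primary_id` (one row per
report *version*): demographics (`case_id`, report year, age in years, sex),
drug exposures (code, role among suspect-primary / suspect-secondary /
concomitant / interacting / unknown, start date), and reactions
(preferred-term code, onset date). Dates are ISO-8601 prefixes with explicit
completeness (`2014` / `2014-03` / `2014-03-21`); only fully specified dates
enter time-to-onset arithmetic, coarser dates are retained for future use.

Parsing is tolerant by contract: an unparseable age, year or date becomes
missing and increments a provenance counter; a row is never discarded for a
bad field value. Age units are converted through a configurable multiplier
map (years, decades, months, weeks, days, hours); ages above 120 years are
treated as data errors and set missing — a plausibility guard, since SRS
age fields are free-entry. Drug names are case-folded and optionally mapped
through a user-supplied synonym table (exact match only; no fuzzy matching).

**Deduplication.** SRS cases accumulate versions from multiple reporters.
Following the usual regulator recommendation, only the most recent version
of each `case_id` is kept, operationalized as the greatest `primary_id`
(numeric comparison when all ids are numeric, else lexicographic), since
version ids increase over time. Ties keep the first-encountered row with a
warning. The operation is idempotent and order-preserving.

**Completeness filter.** The adjusted model requires complete reporting
year, age and sex; reports missing any required field are dropped with
per-field counts in the provenance log.

## Event definition

An adverse event (e.g. gastrointestinal hemorrhage) is a named set of
MedDRA preferred terms built as the intersection of an SMQ term list with a
system-organ-class term list; a report is a **case** when at least one of
its reactions is in that intersection, a **non-case** otherwise. Case
status is per report, not per drug–reaction pair. MedDRA itself is licensed
and not bundled: term lists are user-supplied CSV, and the test fixtures
are synthetic lists sized like real hemorrhage definitions (152 GI terms,
88 nervous-system terms). SMQ scope handling (narrow/broad) is out of
scope; the supplied list is taken as authoritative.

## Crude reporting odds ratio

For each drug the analyzed reports are cross-tabulated into
(a, b, c, d) = (drug·event, drug·no-event, no-drug·event, no-drug·no-event);
exposure means at least one exposure with a role in the role filter
(default: suspect drugs only, configurable). Then

    ROR = (a·d)/(b·c),  95% CI = exp( ln ROR ± 1.96·√(1/a+1/b+1/c+1/d) ).

A pair is a **signal** when the lower CI limit exceeds 1 and a ≥ 2. Tables
with a zero cell get the Haldane–Anscombe +0.5 correction on all four
cells, flagged `corrected`; a table with a = 0 before correction can never
signal. 1.96 is the hard default (95% convention); the z value is a
parameter for other levels. Age stratification uses half-open intervals,
default [0, 60) and [60, ∞) — the elderly group is "age ≥ 60", with the
0–59 group as reference; a 65-year cutoff is a configuration choice.
Reports with missing age are excluded from every stratum.

## Adjusted ROR: stepwise multiple logistic model

Case status is modelled as

    logit P(case) = β₀ + β_Y·Y + β_A·A + β_S·S + Σ_d β_d·D_d + interactions,

with Y the reporting year entered **continuous and mean-centered** (a
categorical coding would multiply terms without evident benefit; centering
only shifts the intercept), A = 1{age ≥ 60}, S = 1{female}, and one 0/1
indicator per study drug. Candidate interactions are the pairwise products
of {A, S} with {A, S, D₁…} (no squares; year×drug products are off by
default but available). Fitting is Newton–Raphson / IRLS with step
halving; convergence when the largest score component < 1e-8 or the
relative log-likelihood change < 1e-10, at most 100 iterations; the
covariance is the inverse observed information. A coefficient diverging
past |β| > 15 flags complete/quasi-separation and the fit is returned
not-converged rather than reported (the bound is an implementation
safeguard — on the logit scale it is far beyond any interpretable effect).

**Selection.** Forward/backward stepwise with likelihood-ratio tests
(−2·log-likelihood differences are χ² with df = 1 per term): the forward
step adds the candidate with the smallest p if p ≤ 0.05, the backward step
removes the included term with the largest p if p > 0.05, alternating
until stable (entry and removal level are separate parameters, both 0.05
by default). Weak heredity is enforced by default: an interaction is
eligible only while both parents are included, and a parent is not
removable while its interaction is in the model. Every step (term, p,
action) is recorded in a selection trace. The **adjusted ROR** of a term
is exp(coefficient) with a Wald 95% CI on the odds-ratio scale and a
likelihood-ratio p-value from dropping that single term; the intercept is
never reported.

## Time-to-onset

For each case report exposed to the drug: start is the earliest fully
specified start date over that drug's exposures, onset the earliest fully
specified onset date over event-matching reactions, and

    duration = (onset − start) + 1 day,

so onset on the start day counts as 1 day — Weibull support requires
positive values and SRS dates have day resolution; excluding same-day
onsets instead is a flag. Reports are excluded (and counted) when either
date is incomplete, when onset precedes start, or when the duration
exceeds the 365-day analysis window. The MLE is fitted to the
within-window sample without a right-truncation likelihood correction —
the estimate therefore describes the first-year onset profile, and with a
true scale near the window length the shape is biased upward slightly;
fitting the truncated sample directly is the conventional procedure this
package mirrors.

The two-parameter Weibull MLE uses the profile reduction: given shape β,
the scale is α̂ = (mean tᵝ)^{1/β}; β solves the profile score
1/β + mean(log t) − Σtᵝlog t / Σtᵝ = 0 by safeguarded Newton iteration
(bracketed, tolerance 1e-10, ≤ 200 iterations, moment-based start). CIs
are Wald on the log-parameter scale from the observed information
(numerical Hessian, central differences). The fit requires ≥ 10 distinct
observations and at least two distinct values. Hazard classification is a
pure function of the shape CI: **increasing** when the lower limit > 1,
**decreasing** when the upper limit < 1, else **constant**. Onset
summaries are empirical — median and quartiles by linear interpolation of
order statistics (a Weibull-fitted median is exposed as an extra column),
the fraction of onsets within 30 days, and a histogram with 30-day bins
over the window.

## Synthetic-data generator

The generator emulates the *structure* the analysis assumes, with a
ground-truth ledger recording, per report, the pre-missingness covariates,
exposure set, event status, event probability and true onset latency, plus
the exact effect vector, per-drug Weibull parameters and duplicate map.

Per report: year uniform over 2004–2016; sex Bernoulli(0.5); age from a
two-component truncated-normal mixture (0.35·N(45,12²) + 0.65·N(72,10²) on
[0,100]) giving the elderly-skewed age profile of anticoagulant reporting;
per-drug exposure Bernoulli (mutually exclusive when configured — oral
anticoagulants are not co-prescribed); event status Bernoulli on the
logistic linear predictor; event reports receive one preferred term from a
152-term event pool plus Poisson decoy terms from a 500-term pool,
non-event reports decoys only (every report has ≥ 1 reaction); background
concomitant drugs Poisson(1.5) from a 20-drug pool. Exposed event reports
get a complete start date uniform within the report year and an onset
date at start + (d − 1) days where d = ⌈Weibull(α, β) draw⌉, so the
analysis day-count convention recovers d exactly and P(d ≤ 30) equals the
continuous CDF at 30. Missingness is applied after the truth is recorded:
year/age/sex are blanked at configured rates (defaults 2% / 15% / 5%);
dates are *degraded to year-month* (defaults 20%/20%), exercising the
completeness-exclusion path rather than the absent-date path. Duplicate
case versions (a configurable fraction) are appended as higher-`primary_id`
near-copies differing only in the source tag, so "most recent version
wins" leaves the ledger truth valid for the survivor.

Presets: **null** (four drugs, all effect log-odds zero, baseline event
prevalence 10%); **paper_like** (four anticoagulants with main-effect ORs
9.9–11.8, female×drug ratio-of-OR 1.5, age≥60 OR 2.0, female OR 1.2,
age×sex OR 1.15, year slope 0.02/yr, 5% exposure each, baseline prevalence
3%, 5% duplicate rate, per-drug onset profiles); **tto_profiles** (three
drugs whose onset shapes span β = 0.7 / 1.0 / 1.5 with light date
missingness). The paper_like magnitudes are in the range reported for
DOAC–GI-hemorrhage analyses of FAERS/JADER-scale data; exposure prevalence
and baseline risk were chosen once to give realistic case counts (≈13k
cases per 100k reports, ≈1.3k usable latencies per drug) and are not
calibrated to any specific database.

What the generator does **not** emulate: real marginal drug/reaction
frequencies, reporting-source structure, drug-name noise, MedDRA hierarchy,
secular changes in reporting quality, or correlated missingness. Passing
tests therefore demonstrate statistical correctness of the estimators and
pipeline plumbing on data satisfying the model's assumptions — not
robustness to the full messiness of a real SRS snapshot.

## Problem sizes and test design

The validation suite exercises: exact oracle equivalence of the ROR
arithmetic (1,000 random tables, 1e-12 relative); agreement of the
single-indicator logistic fit with the crude ROR (100 tables, 1e-6);
adjusted-effect recovery on paper_like at n = 200,000 (every true effect
inside its 95% CI and within ±15%); stepwise type-I control (200 null
replicates at n = 20,000, per-drug inclusion within binomial 99% bounds of
5%); Weibull recovery (500 replicates at n = 1,000: mean shape error
< 0.03, CI coverage in [0.93, 0.97]) and hazard classification of
exponential data; closed-form CDF agreement at n = 10,000; exact
deduplication accounting at 10,000 cases; and byte-identical reruns of the
full pipeline. Sizes were chosen so the statistical assertions have high
power while the whole suite runs in a few minutes on one CPU.

## Known limitations

- The ROR is a disproportionality measure on reporting odds, not a risk
  estimate; no PRR/IC/EBGM alternatives are provided.
- No Firth penalization: separated fits are flagged, not rescued.
- The Weibull fit ignores right truncation by design (see above) and has
  no competing-risk or censoring structure.
- Deduplication trusts the version-ordering proxy; cross-database
  duplicates (same patient in two systems) are not detectable.
- Drug-name normalization is exact-match synonym mapping only.
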
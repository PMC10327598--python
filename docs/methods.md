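# Methods

This note documents the models, rules, and numerical conventions the
package implements, the design choices made where the design was
genuinely open, and what the synthetic-data validation does and does not
establish.

## Conventions

All dates are day-resolution; month-level quantities (birth month, index
date) are represented as the first day of the month. Every interval is
half-open `[start, end)`. Month arithmetic clamps the day of month
(2017-01-31 + 1 month = 2017-02-28). ICD-10 membership is prefix-based:
`G20.1` matches a configured `G20`. All rule parameters live in
`StudyConfig`; the defaults are listed with units below.

| parameter | default | unit | role |
|---|---|---|---|
| `min_age_years` | 30 | years | minimum age at index |
| `washout_months` | 6 | months | new-initiator washout |
| `min_followup_months` | 6 | months | confirming-diagnosis and first-prescription window |
| `comorbidity_lookback_months` | 6 | months | screening window before index |
| `grace_days` | 90 | days | maximum gap bridged within an exposure episode |
| `min_pattern_days` | 7 | days | minimum duration of a treatment pattern |
| `edge_fraction_threshold` | 0.02 | proportion | network edge display rule |
| `dose_focus_mg` | 300 | mg/day | levodopa dose of interest at switch |
| `age_group_bounds` | 65, 75, 85 | years | fine age bins |
| `elderly_cutoff_years` | 75 | years | coarse elderly split |

## Cohort rules

The index date is the month floor of the earliest qualifying diagnosis
claim, so it is invariant under permutation of the input. Eligibility
requires four predicates (age, a confirming diagnosis claim on or after
index + 6 months, one anti-PD prescription inside `[index, index + 6
months)`, and two anti-PD prescriptions inside the observation period);
each failed predicate is recorded as a reason code, so
eligible + excluded always equals the input count. Two readings of the
source rules were open:

* "a diagnosis record ≥ 6 months from index" is implemented as *at least
  one further diagnosis claim on/after index + 6 months* — the most
  literal reading; a record that merely remains enrolled would not
  demonstrate continued disease coding.
* whether the two-prescription rule constrains both prescriptions'
  timing or only the follow-up duration is ambiguous; it is implemented
  as the two separate predicates above.
* the comorbidity lookback is 6 months; a 3-month variant exists in
  similar designs and is available by setting
  `comorbidity_lookback_months = 3`.

Observation end is `min(enroll_end, data_cutoff)`; no imputation of
death. Age at index is computed from the birth month at month precision
and floored to whole years.

## Exposure episodes

Coverage is the union of `[dispense, dispense + days_supplied)` per
claim — supply does not stack when prescriptions overlap. The gap
between successive coverage blocks is measured from the half-open end of
the earlier block to the next dispense date; a gap ≤ `grace_days` merges
(inclusive reading of "within 90 days": coverage ending day 30 and a
dispense on day 120 merge, day 121 splits). `grace_inclusive = False`
selects the exclusive alternative. After a terminal claim the episode
ends at `dispense + days_supplied`; the grace period never extends past
the last supplied day. Episodes are truncated at observation end.

Episode construction is validated against a brute-force oracle that
marks every exposed day in a boolean calendar, bridges gaps, and reads
off maximal runs; the two agree exactly on 1,000 random claim sets per
test run, including the boundary cases.

## Treatment patterns

The patient's exposed calendar is partitioned into maximal runs of
constant active-class sets. Runs shorter than `min_pattern_days` are
dropped: they are transient overlaps at a switch (e.g. a 5-day
double-coverage while titrating). When the flanking surviving runs have
the same class set they are merged into one pattern spanning the
transient — a short overlap does not split or create a pattern; when
they differ, both flanks are kept as consecutive patterns with their own
extents. The alternative reading (a sub-threshold run splits the block
like a gap) is available as `short_run_as_gap = True`.

Unexposed gaps always end the current pattern. Because the grace rule
already bridges within-class gaps up to 90 days, a full gap means every
class lapsed; if the same class set resumes after such a gap it is a new
pattern, and no transition is emitted for the identical adjacent pair.

The time from first to second pattern is measured start-to-start and
censored at observation end. The levodopa dose at an add-on transition
is taken from the levodopa claim whose coverage contains the transition
date (most recent dispense when several do); patients on device-assisted
therapy (deep-brain stimulation or levodopa-carbidopa intestinal gel)
are excluded from dose summaries, as their dosing is not comparable.

## Transition networks

Node weight = distinct patients ever holding the pattern (not only as
their first pattern); edge weight = distinct patients ever making the
ordered switch, so a patient oscillating A→B→A→B contributes one to each
direction. An event-count mode (`edge_count_events`) is available. The
edge display rule keeps edges with `count / n_group ≥ 0.02` (inclusive);
nodes are never thresholded, matching the convention that the display
rule applies to arrows only.

## Statistics

* **Kaplan–Meier**: product-limit via lifelines; ties follow the
  standard events-before-censorings convention. Validated against a
  hand-rolled product-limit oracle on tied/censored micro-examples and
  against exp(−λt) at n = 10,000.
* **Logistic factors**: maximum likelihood (statsmodels `Logit`), odds
  ratios with 95% Wald intervals, all covariates entered (no selection),
  a pairwise-correlation collinearity screen run beforehand. Complete
  separation yields a flagged penalized point estimate with undefined
  inference instead of an exception.
* **Cox factors**: partial likelihood via lifelines `CoxPHFitter`,
  hazard ratios with 95% intervals; fits with zero events are rejected.
* **Group comparisons**: Wilcoxon rank-sum for continuous variables;
  chi-square for categorical, switching to Fisher's exact (2×2) when any
  expected cell count is below 5 — the selection rule is a pure function
  of the expected-count table.
* Significance is two-sided at 0.05 with no multiplicity adjustment,
  recorded in the run metadata. Wald intervals are the default for both
  models.

## Synthetic claims generator

The generator emulates the structure the pipeline assumes, not any real
population:

* **Population**: age groups <65 / 65–74 / 75–84 / ≥85 with proportions
  0.25 / 0.24 / 0.38 / 0.13, ages uniform within group (30–99), 47.6%
  male; per-age-group comorbidity prevalences (e.g. constipation rising
  from 0.20 below 65 to 0.56 at ≥85, cognitive disorder from 0.02 to
  0.17) placed uniformly in the 6-month lookback window; a handful of
  Charlson conditions at flat prevalences; enrollment ends by a
  geometric (1%/month) censoring clock or at the simulation horizon
  (36 monthly cycles).
* **Pathways**: the first pattern is levodopa monotherapy with
  probability given by a logistic model in age, sex, cognitive disorder,
  hallucination, and depression/anxiety (defaults chosen so roughly
  three quarters of a mixed-age cohort start on levodopa, with odds
  ratios of plausible sign and size); otherwise an alternative initial
  pattern is drawn. Thereafter the pattern follows a row-stochastic
  monthly Markov chain, giving geometric pattern durations. Each active
  class emits one claim per 30-day cycle with `days_supplied = 30`.
* **Dose escalation**: the levodopa daily dose starts at 100 mg and
  rises 50 mg per cycle to a 300 mg ceiling. While the dose is below
  300 mg, transitions that *add* a class to a levodopa-containing
  pattern are damped by a factor 0.1 (mass returned to self), so add-on
  switches cluster at the 300 mg trigger by construction — this makes
  the modal dose-at-switch a designed, testable property.
* **Determinism**: every draw comes from a named substream
  `[seed, stream, patient_index]` (population / comorbidity / pathway /
  censor), so runs are byte-identical given parameters and enlarging the
  population never reshuffles earlier patients.

The transition draw after the final emitted cycle is skipped, so the
recorded latent sequence contains exactly the states that produced
claims; the ground-truth record is therefore field-by-field comparable
with the inference outputs.

What passing recovery tests shows: the pipeline inverts the generative
rules it was built for — episode and pattern logic are exact against
brute force, transition frequencies and regression coefficients are
recovered within sampling error. What it does not show: robustness to
features of real claims the generator omits — irregular dispensing
intervals, stockpiling, partial adherence, within-class switching,
coding noise in diagnoses, database-specific receipt-code semantics, and
mortality (enrollment end is the only censoring mechanism).

## Problem sizes

The validation suite uses 1,000 random claim sets / patients for the
oracle checks, 300 patients for the absorbing-chain identity check,
5,000 patients for transition-frequency and regression-coefficient
recovery, 10,000 observations for the Kaplan–Meier closed-form check,
and 50 replicates of 400 patients for confidence-interval coverage —
sizes at which binomial/Wald sampling error is comfortably inside the
asserted tolerances.

## Known limitations

* The default drug-class map is an illustrative ATC-style list, not a
  national receipt-code dictionary; any real analysis must supply its
  own code lists.
* Charlson weights ship with the updated ICD-10 claims weighting and
  explicit hierarchy pairs, but the condition code lists are abbreviated
  illustrations.
* No dose-weighted exposure (defined daily doses) beyond the levodopa
  daily-dose pass-through; no within-class drug-switch detection.
* Patients appearing in multiple source databases are treated as
  distinct; no cross-database deduplication.
* The Cox stage performs no proportional-hazards diagnostics; users
  should check the assumption (e.g. Schoenfeld residuals) before
  interpreting hazard ratios from real data.
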
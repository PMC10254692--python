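# Methods

This package implements the PINCER suite of prescribing-safety indicators as
a reproducible pipeline over event-level primary-care EHR data: a synthetic
cohort generator, a monthly indicator engine, practice-level aggregation and
decile monitoring, federated two-backend execution with statistical
disclosure control, and chart/table reporting. This note records the model,
the conventions, and the design choices that were genuinely open.

## Indicators

PINCER defines 13 clinical indicators of potentially hazardous prescribing,
reported here as 14 measure keys because the methotrexate indicator has two
monitoring sub-measures (full blood count and liver function). Each
indicator is a monthly cohort pair evaluated on the first of each month:

* **denominator** — patients for whom the safety check is clinically
  meaningful (e.g. everyone aged ≥65; everyone established on lithium);
* **numerator** — the denominator subset currently exposed to the hazard
  (e.g. prescribed an oral NSAID without gastroprotection; overdue a blood
  test).

The percentage 100·numerator/denominator is the indicator rate; higher is
worse. Indicators fall into three groups: gastrointestinal-bleed risks
(keys a–f), medication cautioned in a condition (g–i: heart failure,
asthma, renal impairment), and blood-test monitoring (j–n).

### Window conventions

All evaluation happens "as of" a first-of-month date, summarising the
preceding period:

* *Current prescription*: ≥1 medication event in the half-open window
  `[as_of − lookback_days, as_of)`. The default lookback is **90 days**,
  configurable per indicator definition. The lower bound is closed, the
  upper bound (the evaluation day itself) is excluded.
* *History of a condition*: any clinical event strictly before `as_of`.
* *Monitoring windows* ("previous 3/6/15 months") use calendar-month
  arithmetic with day-of-month clamping, not 30-day approximations; the
  window is again `[as_of − w months, as_of)`.
* *Established treatment* ("treatment for at least three months") requires
  both a current prescription and an earliest-ever prescription at least
  `min_treatment_months` calendar months before `as_of`. The source
  material states only the duration; tying it to the earliest prescription
  plus a current script is this package's explicit reading, and it is
  configurable.

### Comparator-coded thresholds

The renal-impairment indicator (i) requires the latest eGFR to be
unambiguously below 45. Laboratory results carry comparator codes
(=, <, ≤, >, ≥); a result coded ">30" says nothing about being below 45 and
is classified *ambiguous*. The resolution table is:

| comparator | meaning        | satisfied (<45)  | not satisfied | ambiguous |
|-----------:|----------------|------------------|---------------|-----------|
| = (or none)| value known    | value < 45       | value ≥ 45    | —         |
| < / ≤      | upper bound    | bound ≤ 45 / <45 | —             | otherwise |
| > / ≥      | lower bound    | —                | bound ≥ 45    | otherwise |

Only the **latest value-bearing** result before `as_of` is consulted; if it
is ambiguous or not satisfied the patient is excluded from the denominator
(we do not fall back to an older unambiguous result — the conservative
reading of "only unambiguous results were used"). Ties on date are broken
by record order. Backends that cannot execute numeric-comparator queries
skip this indicator with a logged reason rather than an error; its
summaries are then computed over contributing backends only.

### Other rule choices that were open

* Indicator d (anticoagulant + NSAID) has no ulcer-healing-drug clause;
  e and f do — read directly from the indicator wording.
* Denominators for d/e/f are "currently on the anticoagulant / aspirin";
  no further refinements (the nationally used cohort logic contains
  additional detail not recoverable from public descriptions; our defaults
  are explicit and configurable in `data/definitions.yaml`).
* The asthma denominator is any asthma history, without resolution logic or
  COPD exclusion.
* The "long-term ACE-inhibitor/loop-diuretic" denominator (j) uses
  established treatment with `min_treatment_months = 3` and age ≥75.

## Base population

Alive, aged 18–120 (completed years), with a registration interval covering
the evaluation date. A patient who died the day before `as_of` is out; a
death dated on `as_of` still counts as alive on that morning.

## Measures

* **Practice-month measures** are exact tallies; a practice-month with zero
  denominator yields no row.
* **Deciles** (d10…d90) are computed per month across practice percentages
  with linear interpolation between order statistics (`numpy.percentile`,
  `method="linear"`) — the common plotting default, pinned by an oracle
  test so the convention is explicit.
* **Q1 mean** pools January–March practice-months as equal units (the
  footnoted "calculated at the practice level"); a
  per-practice-then-average variant is available behind a flag.
* **Cumulative summaries** count patient-months: a patient flagged in two
  months contributes two events. Reported alongside are the
  events-per-unique-patient ratio and the number/percentage of practices
  with ≥1 event. Group rows (gastrointestinal bleed, cautioned,
  monitoring) deduplicate patients across the group's indicators within
  each month, which is why a group denominator is smaller than the sum of
  its constituents.
* **Maximum-impact month** is pure calendar addition: disruption onset plus
  the monitoring window — the month by which every patient's monitoring
  could have lapsed absent mitigation. March 2020 + 3 → June 2020;
  + 6 → September 2020; + 15 → June 2021. (Published descriptions of the
  15-month case give May 2021; calendar arithmetic gives June 2021 and this
  implementation does not special-case it.)
* **Reported percentages** are rounded half-up to 2 decimal places, always
  from raw counts, rounding last.

## Disclosure control

Released aggregates (never in-memory analysis tables) pass through
small-cell control: counts in `(0, suppress_below]` are redacted and marked
suppressed; surviving counts are rounded to the nearest `round_base`; if
rounding would land a count back inside the suppression band it is bumped
up to the next multiple above the threshold instead. This last rule is what
makes the operation idempotent — applying it twice equals applying it once
— at the cost of a small upward bias for counts just above the threshold.
Zero is non-disclosive and passes through. Percentages are recomputed from
disclosed counts only. Defaults: suppress ≤5, round to 5. This mirrors
best-practice anonymisation; it does not claim to reproduce any specific
governance policy.

## Federation

Each backend's data are processed in isolation (`run_backend` refuses rows
from foreign backends), disclosure control is applied per backend, and only
aggregate bundles are combined — matching a review-then-release federated
workflow. Practice and patient identifiers are disjoint across backends,
so combined cumulative counts are sums of backend counts; deciles and Q1
means are recomputed over pooled practice-month rows. With suppression off,
per-backend execution plus combination is byte-identical to a pooled run
(property-tested); with suppression on, combined counts differ from pooled
counts by at most the rounding base per cell. A structural privacy gate
asserts that no bundle or output table carries a `patient_id` column.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes, not
clinical reality:

* **Profiles.** Each patient draws one mutually exclusive risk profile
  (peptic-ulcer history, heart failure, asthma, renal impairment,
  anticoagulated, aspirin, ACEI/loop, methotrexate, lithium, amiodarone, or
  none) with configured probabilities. Age strata are arranged so a patient
  sits in exactly one indicator family's denominator: condition/chronic-med
  profiles are 30–60 years old, the ACEI/loop profile is 75+, and the
  age-≥65 NSAID denominator is populated by the "none" profile's older
  patients plus the ACEI/loop profile. This makes each indicator's
  steady-state percentage independently controllable.
* **Co-hazard coins.** Hazardous co-prescriptions are per-calendar-month
  Bernoulli draws. Because a 90-day lookback covers k≈3 month slots, the
  per-slot probability is derived as `1 − (1−p)^(1/k)` so the *configured*
  `cohazard_rate` p is the steady-state monthly marginal the pipeline
  recovers. Consecutive months share slots and are therefore correlated;
  parameter-recovery checks sample months spaced wider than the lookback so
  patient-months are independent draws. Slot-boundary clipping (a 90-day
  window does not cover three calendar months exactly) biases the marginal
  down by roughly 0.1 · per-slot rate — negligible against the 3-standard-
  error recovery bound.
* **Monitoring.** Chronic-therapy profiles receive monthly prescriptions
  from 12 months before the study and a due blood test each month that is
  *missed* with probability `monitoring_miss_rates[test]`; the steady-state
  overdue percentage is `miss^window`. Default miss rates (renal 0.82,
  FBC 0.57, LFT 0.58, lithium 0.68, TFT 0.84 per month) were set once to
  place the steady states at the pre-pandemic levels typical of national
  practice data (≈5%, 19%, 20%, 31%, 36%).
* **Disruption.** From a configurable onset (default March 2020) miss rates
  are multiplied (capped at 1) until an end month, then decay linearly to
  baseline over a recovery ramp. Implemented by *removing* already
  generated test events with probability `(min(1, m·b) − b)/(1 − b)`, so a
  multiplier of 1 is the identity and only the test-results table is ever
  touched. No quantitative magnitude is published for the disruption; the
  default (×1.2 over 2020-03..2020-05, 4-month ramp) was chosen once to
  reproduce the qualitative shape of the monitoring charts (sharp rise to a
  peak near the projected maximum-impact month, then recovery). An optional
  knob transiently lowers NSAID co-hazard rates over the same window to
  emulate the reported dip in NSAID prescribing; it is off by default.
* **Stream discipline.** One random stream per table, spawned from the
  master seed, so changing one rate never perturbs unrelated tables; coin
  arrays have fixed shapes, so raising a co-hazard rate yields a superset
  of hazardous events realisation by realisation (tested, not just in
  expectation).
* **Invalid patients.** A configurable fraction (default 2%) violate
  base-population rules — minors, mid-study deaths, mid-study
  deregistrations — to exercise the exclusion logic downstream.

### What the generator does not emulate

Demographics are sampled independently of hazard status (the source
analysis reports demographics only descriptively). There is no disease
progression, dosing, seasonality, inter-practice variation in case mix, or
correlation between medication classes beyond the configured profiles.
Ulcer-healing-drug co-prescription does not occur in the steady-state
profiles (it would bias the configured co-hazard marginals); the
gastroprotection clause is exercised by constructed fixtures and fuzzed
random events in the test suite instead. Consequently, passing tests show
that the *pipeline arithmetic and cohort logic* are correct under known
ground truth — not that the generator reproduces real EHR joint
distributions.

## Problem sizes

Unit and property tests run on cohorts of 2–7 practices with ~20–60
patients each; the engine/oracle cross-check uses 50 random 20-patient
cohorts; federation equivalence uses 40 practices (~1,000 patients) over
the full 25-month horizon; parameter recovery uses 50 practices × 150
patients (≈13,000 at-risk patient-months at four spaced months). The
analysis drivers use 30 practices × 80 patients — at that scale disclosure
control suppresses the rare chronic-therapy indicators' practice-months
entirely, which the drivers report honestly; coverage grows with cohort
size.

## Known limitations

* Codelists are synthetic tokens; results carry no clinical meaning.
* The denominator refinements used nationally (e.g. whether
  gastroprotected patients are excluded from denominators b–f) are not
  public in full; our defaults are documented above and configurable.
* The events-per-patient ratio requires unique-patient counts, which are
  carried in aggregate bundles as counts (not identifiers); after heavy
  suppression the ratio may be reported absent.
* `evaluate_indicator` is vectorised per month; very large cohorts
  (≥10⁵ patients × 25 months × 14 keys) would warrant event-table indexing
  by month, which is deliberately out of scope.
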
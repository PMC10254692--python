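# pincer-indicators

Medication-safety surveillance over coded primary-care EHR events: a tested,
reusable implementation of the **PINCER prescribing-safety indicators** as a
monthly numerator/denominator pipeline, with practice-level decile
monitoring, federated two-backend execution, statistical disclosure control
— and a synthetic EHR generator so every stage runs and is testable without
access to any real patient data.

It is aimed at researchers and analysts in pharmacoepidemiology and
medication safety who work with event-level GP records (prescriptions,
coded diagnoses, laboratory results with comparator operators) and need
auditable cohort logic rather than black-box queries.

## The indicators

PINCER defines 13 indicators of potentially hazardous prescribing
(14 measure keys — methotrexate has two monitoring sub-measures). For each
indicator *i*, practice *p* and month *t* (evaluated on the first of the
month), the pipeline computes

```
rate_ipt = 100 · numerator_ipt / denominator_ipt
```

where the denominator is the set of registered, alive patients aged 18–120
for whom the check is clinically meaningful, and the numerator is the
subset currently exposed to the hazard. Examples: an oral NSAID without an
ulcer-healing drug in a patient aged ≥65 or with peptic-ulcer history; a
warfarin/DOAC–NSAID combination; lithium established ≥3 months with no
lithium level in the previous 3 months. Higher rates mean worse safety
performance. Monthly rates are summarised across practices as decile
charts; cumulative summaries count patient-months, the ratio of events to
unique patients, and the share of practices with at least one event. See
`docs/methods.md` for every rule, window convention and design choice.

## Worked example

```python
from datetime import date
import pincer_indicators as pi

cfg = pi.GeneratorConfig(seed=1, n_practices_a=4, n_practices_b=6,
                         patients_per_practice=40)
ds = pi.generate(cfg)                      # two-backend synthetic EHR
defs = pi.default_definitions()            # the 14 measure keys
months = pi.month_range(date(2019, 9, 1), date(2021, 9, 1))
flags, log = pi.evaluate_all(ds, defs, months)
m = pi.practice_month_measures(flags, ds.patients)
tot = m.groupby("indicator")[["numerator", "denominator"]].sum()
print((100 * tot.numerator / tot.denominator).round(2))
```

prints (cumulative percentages over the 25 evaluation months):

```
indicator
a_age65_nsaid               1.14
b_pu_nsaid                  0.00
c_pu_antiplatelet           4.00
d_anticoag_nsaid            1.23
e_anticoag_antiplatelet     3.69
f_aspirin_antiplatelet      1.23
g_hf_nsaid                  2.00
h_asthma_betablocker        1.08
i_crf_nsaid                 0.00
j_acei_loop_no_renal        9.22
k_mtx_no_fbc               26.40
l_mtx_no_lft               17.60
m_lithium_no_level         40.00
n_amiodarone_no_tft        48.00
```

Each number is the percentage of denominator patient-months flagged as
hazardous. The co-prescribing keys (a–i) sit near their configured monthly
co-hazard rates (e.g. 1.11% for the age-≥65 NSAID key); the monitoring keys
(j–n) sit near `miss_rate ^ window` plus the effect of the default
COVID-style monitoring disruption (×1.2 from March 2020). At this toy size
the rare keys (b, i) can have zero events.

## Analysis pipeline

The `analysis/` drivers run the full federated study end to end on a
synthetic cohort and narrate what they find:

```bash
python analysis/01_generate_cohorts.py    # two-backend cohort -> scratch/
python analysis/02_run_backends.py        # per-backend runs, disclosure on
python analysis/03_combine_and_summarise.py
python analysis/04_decile_charts.py       # charts -> results/figures/
```

Backend B does not support numeric-comparator queries, so the
renal-impairment NSAID indicator is evaluated on backend A only (a logged
skip, mirroring how capability gaps are handled in multi-vendor federation).
The same stages are scriptable via the `pincer` CLI
(`pincer generate|run|combine|report --help`).

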
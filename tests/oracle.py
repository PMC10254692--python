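"""Straight-line reference implementation of the indicator rules.

Deliberately naive: plain Python loops over event tuples, one function per
concern, no code shared with the package's evaluator.  Used to cross-check
the vectorised engine on small random datasets.
"""

from datetime import timedelta

import pandas as pd
from dateutil.relativedelta import relativedelta

from pincer_indicators.codes import default_codelists

_CL = {name: set(cl.codes) for name, cl in default_codelists().items()}
ANTIPLATELET_ANY = _CL["aspirin"] | _CL["antiplatelet_other"]


def _d(x):
    return x.date() if hasattr(x, "date") else x


def _patient_events(df, pid):
    out = []
    for row in df[df["patient_id"] == pid].itertuples():
        out.append((_d(row.date), row.code))
    return out


def _age(dob, as_of):
    return as_of.year - dob.year - ((as_of.month, as_of.day) < (dob.month, dob.day))


def in_base_population(p, as_of):
    dob = _d(p.date_of_birth)
    if not (18 <= _age(dob, as_of) <= 120):
        return False
    if not pd.isna(p.date_of_death) and _d(p.date_of_death) < as_of:
        return False
    if _d(p.registration_start) > as_of:
        return False
    if not pd.isna(p.registration_end) and _d(p.registration_end) < as_of:
        return False
    return True


def med_in_window(meds, codes, as_of, lookback_days=90):
    lo = as_of - timedelta(days=lookback_days)
    return any(code in codes and lo <= when < as_of for when, code in meds)


def history_before(clin, codes, as_of):
    return any(code in codes and when < as_of for when, code in clin)


def established(meds, codes, as_of, min_months, lookback_days=90):
    dates = [when for when, code in meds if code in codes and when < as_of]
    if not dates:
        return False
    current = any(d >= as_of - timedelta(days=lookback_days) for d in dates)
    return current and min(dates) <= as_of - relativedelta(months=min_months)


def test_in_window(tests, codes, as_of, window_months):
    lo = as_of - relativedelta(months=window_months)
    return any(code in codes and lo <= when < as_of for when, code, _, _ in tests)


def latest_egfr_below_45(tests, as_of):
    rows = [(when, val, cmp) for when, code, val, cmp in tests if code in _CL["egfr"] and when < as_of and not pd.isna(val)]
    if not rows:
        return False
    # latest date wins; ties broken by record order (list order is file order)
    best = None
    for when, val, cmp in rows:
        if best is None or when >= best[0]:
            best = (when, val, cmp)
    when, val, cmp = best
    if pd.isna(cmp) or cmp == "eq":
        return val < 45
    if cmp == "lt":
        return val <= 45
    if cmp == "le":
        return val < 45
    return False  # gt/ge can never prove the value is below 45


def patient_tables(dataset):
    """Pre-split events per patient (pure data reshaping, no rule logic)."""
    tables = {}
    for p in dataset.patients.itertuples():
        pid = p.patient_id
        tests = [
            (_d(r.date), r.code, r.value, r.comparator)
            for r in dataset.test_results[dataset.test_results["patient_id"] == pid].itertuples()
        ]
        tables[pid] = (
            _patient_events(dataset.medications, pid),
            _patient_events(dataset.clinical_events, pid),
            tests,
        )
    return tables


def oracle_indicator(dataset, key, as_of, tables=None):
    """Return {patient_id: in_numerator} over the denominator for one key."""
    if tables is None:
        tables = patient_tables(dataset)
    out = {}
    for p in dataset.patients.itertuples():
        if not in_base_population(p, as_of):
            continue
        pid = p.patient_id
        meds, clin, tests = tables[pid]
        dob = _d(p.date_of_birth)
        nsaid = lambda: med_in_window(meds, _CL["oral_nsaid"], as_of)
        uhd = lambda: med_in_window(meds, _CL["ulcer_healing_drug"], as_of)

        if key == "a_age65_nsaid":
            if _age(dob, as_of) >= 65:
                out[pid] = nsaid() and not uhd()
        elif key == "b_pu_nsaid":
            if history_before(clin, _CL["peptic_ulcer"], as_of):
                out[pid] = nsaid() and not uhd()
        elif key == "c_pu_antiplatelet":
            if history_before(clin, _CL["peptic_ulcer"], as_of):
                out[pid] = med_in_window(meds, ANTIPLATELET_ANY, as_of) and not uhd()
        elif key == "d_anticoag_nsaid":
            if med_in_window(meds, _CL["anticoagulant"], as_of):
                out[pid] = nsaid()
        elif key == "e_anticoag_antiplatelet":
            if med_in_window(meds, _CL["anticoagulant"], as_of):
                out[pid] = med_in_window(meds, ANTIPLATELET_ANY, as_of) and not uhd()
        elif key == "f_aspirin_antiplatelet":
            if med_in_window(meds, _CL["aspirin"], as_of):
                out[pid] = med_in_window(meds, _CL["antiplatelet_other"], as_of) and not uhd()
        elif key == "g_hf_nsaid":
            if history_before(clin, _CL["heart_failure"], as_of):
                out[pid] = nsaid()
        elif key == "h_asthma_betablocker":
            if history_before(clin, _CL["asthma"], as_of):
                out[pid] = med_in_window(meds, _CL["beta_blocker_nonselective"], as_of)
        elif key == "i_crf_nsaid":
            if latest_egfr_below_45(tests, as_of):
                out[pid] = nsaid()
        elif key == "j_acei_loop_no_renal":
            if _age(dob, as_of) >= 75 and established(meds, _CL["acei_or_loop"], as_of, 3):
                out[pid] = not test_in_window(tests, _CL["renal_function"], as_of, 15)
        elif key == "k_mtx_no_fbc":
            if established(meds, _CL["methotrexate"], as_of, 3):
                out[pid] = not test_in_window(tests, _CL["full_blood_count"], as_of, 3)
        elif key == "l_mtx_no_lft":
            if established(meds, _CL["methotrexate"], as_of, 3):
                out[pid] = not test_in_window(tests, _CL["liver_function"], as_of, 3)
        elif key == "m_lithium_no_level":
            if established(meds, _CL["lithium_medication"], as_of, 3):
                out[pid] = not test_in_window(tests, _CL["lithium_level"], as_of, 3)
        elif key == "n_amiodarone_no_tft":
            if established(meds, _CL["amiodarone"], as_of, 6):
                out[pid] = not test_in_window(tests, _CL["thyroid_function"], as_of, 6)
        else:
            raise KeyError(key)
    return out
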
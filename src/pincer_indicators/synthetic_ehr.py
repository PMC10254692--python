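"""Synthetic primary-care EHR generator.

Emulates the event-level structure the indicator pipeline assumes: two
backends of practices, registered patients with demographics, prescription
streams for the medication classes the indicators reference, condition
histories, comparator-coded eGFR results, and monitoring blood tests with a
configurable COVID-style service disruption (elevated missed-monitoring
rates from March 2020 with a staged recovery).

Design
------
Each patient is assigned one mutually exclusive *risk profile* (peptic-ulcer
history, anticoagulated, established methotrexate, ...), with age strata
arranged so a patient sits in exactly one indicator family's denominator.
Hazardous co-prescribing is simulated as per-calendar-month coin flips; the
coin's slot probability is derived from the configured marginal rate and
the number of month slots a prescription lookback covers, so the configured
``cohazard_rate`` is the steady-state monthly percentage the pipeline should
recover.  Monitoring tests are monthly Bernoulli "test performed" events, so
a monitoring indicator's steady state is ``miss_rate ** window_months``.

One random stream per table (spawned from the master seed) keeps the tables
independently reproducible: changing one rate never perturbs unrelated
tables, which is what makes the monotonicity properties hold realisation by
realisation, not just in expectation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from . import codes as _codes
from .ehr_model import (
    ETHNICITIES,
    IMD_QUINTILES,
    REGIONS,
    SyntheticEhr,
    add_months,
    first_of_month,
    month_range,
    parse_month,
)

# Age-band weights default to the shape of the at-risk cohort this pipeline
# studies (a denominator population skewed towards older adults).
DEFAULT_AGE_DISTRIBUTION = {
    "18-19": 0.0115,
    "20-29": 0.0807,
    "30-39": 0.0908,
    "40-49": 0.0811,
    "50-59": 0.0906,
    "60-69": 0.2005,
    "70-79": 0.2736,
    "80-89": 0.1713,
}

DEFAULT_PREVALENCE = {
    "peptic_ulcer": 0.020,
    "heart_failure": 0.015,
    "asthma": 0.120,
    "egfr_lt45": 0.015,
}

DEFAULT_MEDICATION_RATES = {
    "anticoagulant": 0.040,
    "aspirin": 0.040,
    "acei_or_loop": 0.050,
    "methotrexate": 0.010,
    "lithium_medication": 0.004,
    "amiodarone": 0.004,
}

# Steady-state monthly marginal probability of the hazardous combination for
# each co-prescribing indicator (chosen once to sit at the pre-disruption
# levels typical of national practice-level data).
DEFAULT_COHAZARD_RATES = {
    "a_age65_nsaid": 0.0111,
    "b_pu_nsaid": 0.0132,
    "c_pu_antiplatelet": 0.0424,
    "d_anticoag_nsaid": 0.0139,
    "e_anticoag_antiplatelet": 0.0226,
    "f_aspirin_antiplatelet": 0.0167,
    "g_hf_nsaid": 0.0171,
    "h_asthma_betablocker": 0.0127,
    "i_crf_nsaid": 0.0127,
}

# Monthly probability that a due monitoring blood test is NOT performed.
# With windows of 3/3/3/6/15 months these give steady-state overdue
# percentages around 19% (FBC), 20% (LFT), 31% (lithium), 36% (TFT) and
# 5% (renal panel).
DEFAULT_MONITORING_MISS_RATES = {
    "renal_function": 0.82,
    "full_blood_count": 0.57,
    "liver_function": 0.58,
    "lithium_level": 0.68,
    "thyroid_function": 0.84,
}

_MONITORING_PLAN = {
    # profile -> (chronic medication codelist, [(test codelist, ...)])
    "acei": ("acei_or_loop", ["renal_function"]),
    "mtx": ("methotrexate", ["full_blood_count", "liver_function"]),
    "lithium": ("lithium_medication", ["lithium_level"]),
    "amiodarone": ("amiodarone", ["thyroid_function"]),
}

_CHRONIC_MED = {
    "anticoag": "anticoagulant",
    "aspirin": "aspirin",
    "acei": "acei_or_loop",
    "mtx": "methotrexate",
    "lithium": "lithium_medication",
    "amiodarone": "amiodarone",
}

_CONDITION_EVENT = {"pu": "peptic_ulcer", "hf": "heart_failure", "asthma": "asthma"}

# co-hazard coin -> (eligible profiles, emitted medication codelist, NSAID?)
_HAZARD_COINS = {
    "a_age65_nsaid": (("none", "acei"), "oral_nsaid", True),
    "b_pu_nsaid": (("pu",), "oral_nsaid", True),
    "c_pu_antiplatelet": (("pu",), "antiplatelet_other", False),
    "d_anticoag_nsaid": (("anticoag",), "oral_nsaid", True),
    "e_anticoag_antiplatelet": (("anticoag",), "antiplatelet_other", False),
    "f_aspirin_antiplatelet": (("aspirin",), "antiplatelet_other", False),
    "g_hf_nsaid": (("hf",), "oral_nsaid", True),
    "h_asthma_betablocker": (("asthma",), "beta_blocker_nonselective", False),
    "i_crf_nsaid": (("crf",), "oral_nsaid", True),
}


@dataclass
class DisruptionConfig:
    """COVID-style disruption to blood-test monitoring.

    ``multiplier`` scales the monthly miss rates (capped at 1) between
    ``onset_month`` and ``end_month`` inclusive, then decays linearly back to
    1 over ``recovery_ramp_months``.
    """

    onset_month: date = date(2020, 3, 1)
    end_month: date = date(2020, 5, 1)
    multiplier: float = 1.2
    recovery_ramp_months: int = 4
    # optional transient dip in NSAID prescribing over the same window
    nsaid_dip_multiplier: float = 1.0


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_practices_a: int = 10
    n_practices_b: int = 15
    patients_per_practice: int = 50
    study_start: date = date(2019, 9, 1)
    study_end: date = date(2021, 9, 1)
    lookback_days: int = 90
    age_distribution: dict = field(default_factory=lambda: dict(DEFAULT_AGE_DISTRIBUTION))
    prevalence: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    medication_rates: dict = field(default_factory=lambda: dict(DEFAULT_MEDICATION_RATES))
    cohazard_rates: dict = field(default_factory=lambda: dict(DEFAULT_COHAZARD_RATES))
    monitoring_miss_rates: dict = field(default_factory=lambda: dict(DEFAULT_MONITORING_MISS_RATES))
    disruption: DisruptionConfig | None = field(default_factory=DisruptionConfig)
    # fraction of patients violating base-population rules (minors, deaths,
    # deregistrations), to exercise the exclusion logic downstream
    invalid_patient_rate: float = 0.02

    @classmethod
    def from_dict(cls, raw: dict) -> "GeneratorConfig":
        raw = dict(raw)
        for key in ("study_start", "study_end"):
            if key in raw and isinstance(raw[key], str):
                raw[key] = parse_month(raw[key])
        if raw.get("disruption") is not None and isinstance(raw["disruption"], dict):
            d = dict(raw["disruption"])
            for key in ("onset_month", "end_month"):
                if key in d and isinstance(d[key], str):
                    d[key] = parse_month(d[key])
            raw["disruption"] = DisruptionConfig(**d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown generator config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["study_start"] = str(self.study_start)
        out["study_end"] = str(self.study_end)
        if self.disruption is not None:
            out["disruption"]["onset_month"] = str(self.disruption.onset_month)
            out["disruption"]["end_month"] = str(self.disruption.end_month)
        return out


def _validate_config(cfg: GeneratorConfig) -> None:
    if cfg.n_practices_a + cfg.n_practices_b <= 0 or min(cfg.n_practices_a, cfg.n_practices_b) < 0:
        raise ValueError("need a positive number of practices")
    if cfg.patients_per_practice <= 0:
        raise ValueError("need a positive number of patients per practice")
    if cfg.study_start >= cfg.study_end:
        raise ValueError("study_start must precede study_end")
    probs = (
        list(cfg.prevalence.values())
        + list(cfg.medication_rates.values())
        + list(cfg.cohazard_rates.values())
        + list(cfg.monitoring_miss_rates.values())
        + [cfg.invalid_patient_rate]
    )
    if any(p < 0 or p > 1 for p in probs):
        raise ValueError("all probabilities must lie in [0, 1]")
    if sum(cfg.prevalence.values()) + sum(cfg.medication_rates.values()) > 1:
        raise ValueError("profile probabilities sum above 1")
    if cfg.disruption is not None and cfg.disruption.multiplier < 1:
        raise ValueError("disruption multiplier must be >= 1")


def lookback_slot_count(lookback_days: int) -> int:
    """Number of calendar-month slots a day-based lookback window spans."""
    return max(1, int(round(lookback_days / 30.4375)))


def marginal_to_slot_rate(p: float, lookback_days: int) -> float:
    """Per-slot coin probability giving marginal ``p`` over the lookback."""
    k = lookback_slot_count(lookback_days)
    return 1.0 - (1.0 - p) ** (1.0 / k)


def expected_steady_state(cfg: GeneratorConfig, monitoring_windows: dict | None = None) -> dict[str, float]:
    """Configured ground-truth steady-state percentage per measure key."""
    if monitoring_windows is None:
        monitoring_windows = {
            "j_acei_loop_no_renal": ("renal_function", 15),
            "k_mtx_no_fbc": ("full_blood_count", 3),
            "l_mtx_no_lft": ("liver_function", 3),
            "m_lithium_no_level": ("lithium_level", 3),
            "n_amiodarone_no_tft": ("thyroid_function", 6),
        }
    out = {key: 100.0 * p for key, p in cfg.cohazard_rates.items()}
    for key, (test, window) in monitoring_windows.items():
        out[key] = 100.0 * cfg.monitoring_miss_rates[test] ** window
    return out


def _codes_for(codelists: dict, name: str) -> list[str]:
    return sorted(codelists[name].codes)


def _age_matrix(dob: pd.Series, slots: list[date]) -> np.ndarray:
    """ages[i, s] = completed years of patient i at slot s."""
    dob_y = dob.dt.year.to_numpy()
    dob_m = dob.dt.month.to_numpy()
    dob_d = dob.dt.day.to_numpy()
    out = np.empty((len(dob), len(slots)), dtype=np.int64)
    for s, slot in enumerate(slots):
        not_yet = (dob_m > slot.month) | ((dob_m == slot.month) & (dob_d > slot.day))
        out[:, s] = (slot.year - dob_y) - not_yet
    return out


def generate(config: GeneratorConfig) -> SyntheticEhr:
    """Generate a two-backend event-level dataset; deterministic per seed."""
    _validate_config(config)
    codelists = _codes.default_codelists()
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_pat, rng_clin, rng_med, rng_test, rng_haz = (np.random.default_rng(s) for s in streams)

    start = first_of_month(config.study_start)
    end = first_of_month(config.study_end)

    # ---------------- patients ----------------
    practices = [("backend_a", i + 1) for i in range(config.n_practices_a)] + [
        ("backend_b", config.n_practices_a + i + 1) for i in range(config.n_practices_b)
    ]
    counts = rng_pat.poisson(config.patients_per_practice, size=len(practices))
    counts = np.maximum(counts, 1)
    n = int(counts.sum())
    backend = np.repeat([b for b, _ in practices], counts)
    practice_id = np.repeat([p for _, p in practices], counts)
    patient_id = np.arange(1, n + 1)

    profile_names = ["pu", "hf", "asthma", "crf", "anticoag", "aspirin", "acei", "mtx", "lithium", "amiodarone"]
    profile_probs = [
        config.prevalence["peptic_ulcer"],
        config.prevalence["heart_failure"],
        config.prevalence["asthma"],
        config.prevalence["egfr_lt45"],
        config.medication_rates["anticoagulant"],
        config.medication_rates["aspirin"],
        config.medication_rates["acei_or_loop"],
        config.medication_rates["methotrexate"],
        config.medication_rates["lithium_medication"],
        config.medication_rates["amiodarone"],
    ]
    probs = np.array(profile_probs + [1.0 - sum(profile_probs)])
    profile = rng_pat.choice(profile_names + ["none"], size=n, p=probs)

    bands = list(config.age_distribution)
    weights = np.array([config.age_distribution[b] for b in bands], dtype=float)
    weights = weights / weights.sum()
    band_idx = rng_pat.choice(len(bands), size=n, p=weights)
    lo = np.array([int(b.split("-")[0]) for b in bands])
    hi = np.array([int(b.split("-")[1]) for b in bands])
    years = rng_pat.integers(lo[band_idx], hi[band_idx] + 1)
    # profile age strata: condition/chronic-med profiles stay below 65 so each
    # patient contributes to one indicator family; the ACEI/loop profile is
    # 75+ (it also carries the age>=65 NSAID co-hazard coin).
    stratified = np.isin(profile, ["pu", "hf", "asthma", "crf", "anticoag", "aspirin", "mtx", "lithium", "amiodarone"])
    years = np.where(stratified, rng_pat.integers(30, 61, size=n), years)
    years = np.where(profile == "acei", rng_pat.integers(75, 89, size=n), years)

    # invalid patients: minors / mid-study deaths / mid-study deregistrations
    invalid_u = rng_pat.random(n)
    invalid_kind = rng_pat.integers(0, 3, size=n)  # 0 minor, 1 dies, 2 deregisters
    is_invalid = invalid_u < config.invalid_patient_rate
    years = np.where(is_invalid & (invalid_kind == 0), rng_pat.integers(14, 18, size=n), years)

    dob_day = rng_pat.integers(0, 365, size=n)
    dob = [add_months(start, -12 * int(y)) - timedelta(days=int(d)) for y, d in zip(years, dob_day)]

    horizon_days = (end - start).days
    death_off = rng_pat.integers(0, horizon_days, size=n)
    date_of_death = [
        start + timedelta(days=int(o)) if (bad and kind == 1) else None
        for bad, kind, o in zip(is_invalid, invalid_kind, death_off)
    ]
    rereg_off = rng_pat.integers(0, horizon_days, size=n)
    registration_end = [
        start + timedelta(days=int(o)) if (bad and kind == 2) else None
        for bad, kind, o in zip(is_invalid, invalid_kind, rereg_off)
    ]
    reg_back = rng_pat.integers(400, 3650, size=n)
    registration_start = [start - timedelta(days=int(d)) for d in reg_back]

    sex = rng_pat.choice(["female", "male"], size=n, p=[0.52, 0.48])
    ethnicity = rng_pat.choice(ETHNICITIES, size=n, p=[0.62, 0.05, 0.03, 0.02, 0.04, 0.24])
    imd = rng_pat.choice(IMD_QUINTILES, size=n, p=[0.19, 0.20, 0.20, 0.20, 0.20, 0.01])
    region = rng_pat.choice(REGIONS, size=n, p=[0.12, 0.12, 0.19, 0.16, 0.13, 0.17, 0.11])

    patients = pd.DataFrame(
        {
            "patient_id": patient_id,
            "backend": backend,
            "practice_id": practice_id,
            "date_of_birth": pd.to_datetime(dob),
            "sex": sex,
            "ethnicity": ethnicity,
            "imd_quintile": imd,
            "region": region,
            "registration_start": pd.to_datetime(registration_start),
            "registration_end": pd.to_datetime(pd.Series(registration_end, dtype=object)),
            "date_of_death": pd.to_datetime(pd.Series(date_of_death, dtype=object)),
        }
    )

    # ---------------- condition histories ----------------
    clin_rows = []
    back_days = rng_clin.integers(365, 8 * 365, size=n)
    for prof, cl_name in _CONDITION_EVENT.items():
        idx = np.flatnonzero(profile == prof)
        code_pool = _codes_for(codelists, cl_name)
        code_pick = rng_clin.integers(0, len(code_pool), size=n)
        for i in idx:
            clin_rows.append(
                (int(patient_id[i]), start - timedelta(days=int(back_days[i])), code_pool[code_pick[i]])
            )
    clinical_events = pd.DataFrame(clin_rows, columns=["patient_id", "date", "code"])
    clinical_events["date"] = pd.to_datetime(clinical_events["date"])

    # ---------------- chronic medication streams ----------------
    med_slots = month_range(add_months(start, -12), add_months(end, -1))
    med_frames = []
    for prof in sorted(_CHRONIC_MED):
        cl_name = _CHRONIC_MED[prof]
        idx = np.flatnonzero(profile == prof)
        code_pool = _codes_for(codelists, cl_name)
        code_pick = rng_med.integers(0, len(code_pool), size=n)
        day_off = rng_med.integers(0, 28, size=(n, len(med_slots)))
        if len(idx) == 0:
            continue
        pids = np.repeat(patient_id[idx], len(med_slots))
        dates = [
            slot + timedelta(days=int(day_off[i, s]))
            for i in idx
            for s, slot in enumerate(med_slots)
        ]
        codes_col = np.repeat([code_pool[code_pick[i]] for i in idx], len(med_slots))
        med_frames.append(pd.DataFrame({"patient_id": pids, "date": pd.to_datetime(dates), "code": codes_col}))

    # ---------------- eGFR results for the renal-impairment profile ----------
    test_rows = []
    egfr_code = _codes_for(codelists, "egfr")[0]
    egfr_cat = rng_test.random(n)
    egfr_low = rng_test.uniform(15, 44, size=n)
    egfr_high = rng_test.uniform(46, 90, size=n)
    egfr_day = rng_test.integers(0, 180, size=n)
    crf_satisfied = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(profile == "crf"):
        when = add_months(start, -6) + timedelta(days=int(egfr_day[i]) % 28)
        if egfr_cat[i] < 0.8:  # unambiguously below threshold
            test_rows.append((int(patient_id[i]), when, egfr_code, float(np.round(egfr_low[i], 1)), "eq"))
            crf_satisfied[i] = True
        elif egfr_cat[i] < 0.9:  # ambiguous: coded as "> 30"
            test_rows.append((int(patient_id[i]), when, egfr_code, 30.0, "gt"))
        else:  # unambiguously not below threshold
            test_rows.append((int(patient_id[i]), when, egfr_code, float(np.round(egfr_high[i], 1)), "eq"))

    # ---------------- monitoring blood tests ----------------
    test_slots = month_range(add_months(start, -15), add_months(end, -1))
    for prof in sorted(_MONITORING_PLAN):
        _, tests = _MONITORING_PLAN[prof]
        idx = np.flatnonzero(profile == prof)
        for cl_name in tests:
            miss = config.monitoring_miss_rates[cl_name]
            code = _codes_for(codelists, cl_name)[0]
            u = rng_test.random((n, len(test_slots)))
            day_off = rng_test.integers(0, 28, size=(n, len(test_slots)))
            for i in idx:
                for s, slot in enumerate(test_slots):
                    if u[i, s] >= miss:  # test performed this month
                        test_rows.append((int(patient_id[i]), slot + timedelta(days=int(day_off[i, s])), code, None, None))
    test_results = pd.DataFrame(test_rows, columns=["patient_id", "date", "code", "value", "comparator"])
    test_results["date"] = pd.to_datetime(test_results["date"])
    test_results["value"] = test_results["value"].astype(float)

    # ---------------- co-hazard coin flips ----------------
    k_slots = lookback_slot_count(config.lookback_days)
    haz_slots = month_range(add_months(start, -k_slots), add_months(end, -1))
    age_mat = None
    dip = config.disruption
    for key in sorted(_HAZARD_COINS):
        profiles, cl_name, is_nsaid = _HAZARD_COINS[key]
        p = config.cohazard_rates.get(key, 0.0)
        q = marginal_to_slot_rate(p, config.lookback_days)
        u = rng_haz.random((n, len(haz_slots)))
        day_off = rng_haz.integers(0, 28, size=(n, len(haz_slots)))
        code_pool = _codes_for(codelists, cl_name)
        code_pick = rng_haz.integers(0, len(code_pool), size=(n, len(haz_slots)))

        eligible = np.isin(profile, profiles)
        if key == "i_crf_nsaid":
            eligible = eligible & crf_satisfied
        elig_mat = np.repeat(eligible[:, None], len(haz_slots), axis=1)
        if key == "a_age65_nsaid":
            if age_mat is None:
                age_mat = _age_matrix(patients["date_of_birth"], haz_slots)
            elig_mat = elig_mat & (age_mat >= 65)

        q_slot = np.full(len(haz_slots), q)
        if is_nsaid and dip is not None and dip.nsaid_dip_multiplier != 1.0:
            for s, slot in enumerate(haz_slots):
                if dip.onset_month <= slot <= dip.end_month:
                    q_slot[s] = q * dip.nsaid_dip_multiplier
        hit = elig_mat & (u < q_slot[None, :])
        ii, ss = np.nonzero(hit)
        if len(ii) == 0:
            continue
        dates = [haz_slots[s] + timedelta(days=int(day_off[i, s])) for i, s in zip(ii, ss)]
        med_frames.append(
            pd.DataFrame(
                {
                    "patient_id": patient_id[ii],
                    "date": pd.to_datetime(dates),
                    "code": [code_pool[code_pick[i, s]] for i, s in zip(ii, ss)],
                }
            )
        )

    if med_frames:
        medications = pd.concat(med_frames, ignore_index=True)
        medications = medications.sort_values(["patient_id", "date", "code"], kind="mergesort").reset_index(drop=True)
    else:
        medications = pd.DataFrame(columns=["patient_id", "date", "code"])

    ds = SyntheticEhr(
        patients=patients,
        medications=medications,
        clinical_events=clinical_events,
        test_results=test_results.sort_values(["patient_id", "date", "code"], kind="mergesort").reset_index(drop=True),
        provenance={"generator": "pincer_indicators.synthetic_ehr", "seed": config.seed, "config": config.to_dict()},
    )
    ds.validate()
    if config.disruption is not None and config.disruption.multiplier > 1.0:
        ds = inject_disruption(ds, config.disruption, config.monitoring_miss_rates, seed=config.seed + 777)
    return ds


def _effective_multiplier(month: date, d: DisruptionConfig) -> float:
    """Full multiplier inside the window, linear decay to 1 over the ramp."""
    if month < d.onset_month or d.multiplier <= 1.0:
        return 1.0
    if month <= d.end_month:
        return d.multiplier
    ramp = max(0, d.recovery_ramp_months)
    j = 1
    cur = add_months(d.end_month, 1)
    while cur < month:
        cur = add_months(cur, 1)
        j += 1
    if j > ramp:
        return 1.0
    return 1.0 + (d.multiplier - 1.0) * (ramp + 1 - j) / (ramp + 1)


def inject_disruption(
    dataset: SyntheticEhr,
    disruption: DisruptionConfig,
    miss_rates: dict | None = None,
    seed: int = 0,
    test_codelists: tuple[str, ...] = _codes.MONITORING_TEST_CODELISTS,
) -> SyntheticEhr:
    """Remove monitoring-test events in the disruption window.

    An event due in month ``m`` survives generation with probability
    ``1 - baseline``; removal with probability
    ``(min(1, mult*baseline) - baseline) / (1 - baseline)`` makes the
    post-removal miss rate ``min(1, multiplier x baseline)``.  A multiplier
    of 1 removes nothing, so the dataset is returned byte-identical.
    Only ``test_results`` is touched.
    """
    cfg = dataset.provenance.get("config", {})
    horizon_start = parse_month(cfg["study_start"]) if "study_start" in cfg else None
    horizon_end = parse_month(cfg["study_end"]) if "study_end" in cfg else None
    if horizon_start is None and len(dataset.test_results):
        horizon_start = first_of_month(dataset.test_results["date"].min().date())
        horizon_end = first_of_month(dataset.test_results["date"].max().date())
    if disruption.onset_month > disruption.end_month:
        raise ValueError("disruption onset after end")
    if horizon_end is not None and not (
        horizon_start <= disruption.onset_month and disruption.end_month <= horizon_end
    ):
        raise ValueError("disruption window lies outside the study horizon")

    if miss_rates is None:
        miss_rates = cfg.get("monitoring_miss_rates", DEFAULT_MONITORING_MISS_RATES)
    codelists = _codes.default_codelists()
    code_to_baseline = {}
    for name in test_codelists:
        for code in codelists[name].codes:
            code_to_baseline[code] = miss_rates.get(name, 0.0)

    tests = dataset.test_results
    rng = np.random.default_rng(np.random.SeedSequence([seed, 20200301]))
    u = rng.random(len(tests))
    keep = np.ones(len(tests), dtype=bool)
    months = tests["date"].dt.to_period("M").dt.to_timestamp()
    for pos, (code, month_ts, uu) in enumerate(zip(tests["code"], months, u)):
        b = code_to_baseline.get(code)
        if b is None or b >= 1.0:
            continue
        mult = _effective_multiplier(month_ts.date(), disruption)
        if mult <= 1.0:
            continue
        eff = min(1.0, b * mult)
        p_rm = (eff - b) / (1.0 - b)
        if uu < p_rm:
            keep[pos] = False

    out = SyntheticEhr(
        patients=dataset.patients,
        medications=dataset.medications,
        clinical_events=dataset.clinical_events,
        test_results=tests[keep].reset_index(drop=True),
        provenance={
            **dataset.provenance,
            "disruption": {
                "onset_month": str(disruption.onset_month),
                "end_month": str(disruption.end_month),
                "multiplier": disruption.multiplier,
                "recovery_ramp_months": disruption.recovery_ramp_months,
            },
        },
    )
    return out
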
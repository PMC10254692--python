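from datetime import date

import numpy as np
import pandas as pd
import pytest

import pincer_indicators as pi
from pincer_indicators.codes import default_codelists

STUDY_MONTHS = pi.month_range(date(2019, 9, 1), date(2021, 9, 1))


@pytest.fixture(scope="session")
def definitions():
    return pi.default_definitions()

@pytest.fixture(scope="session")
def months():
    return STUDY_MONTHS


@pytest.fixture(scope="session")
def small_dataset():
    cfg = pi.GeneratorConfig(seed=42, n_practices_a=3, n_practices_b=4, patients_per_practice=40)
    return pi.generate(cfg)


@pytest.fixture(scope="session")
def small_flags(small_dataset, definitions):
    sampled = STUDY_MONTHS[::6] + [STUDY_MONTHS[-1]]
    flags, _ = pi.evaluate_all(small_dataset, definitions, sampled)
    return flags


def make_dataset(patients, medications=(), clinical_events=(), test_results=()):
    """Hand-build a dataset from terse tuples (for rule-level fixtures).

    patients: (patient_id, dob, backend, practice_id[, extras dict]);
    medications/clinical_events: (patient_id, date, code);
    test_results: (patient_id, date, code[, value[, comparator]]).
    """
    prows = []
    for spec in patients:
        pid, dob, backend, practice = spec[:4]
        extras = spec[4] if len(spec) > 4 else {}
        prows.append(
            {
                "patient_id": pid,
                "backend": backend,
                "practice_id": practice,
                "date_of_birth": pd.Timestamp(dob),
                "sex": extras.get("sex", "female"),
                "ethnicity": extras.get("ethnicity", "white"),
                "imd_quintile": extras.get("imd_quintile", "3"),
                "region": extras.get("region", "London"),
                "registration_start": pd.Timestamp(extras.get("registration_start", date(2000, 1, 1))),
                "registration_end": pd.Timestamp(extras["registration_end"]) if "registration_end" in extras else pd.NaT,
                "date_of_death": pd.Timestamp(extras["date_of_death"]) if "date_of_death" in extras else pd.NaT,
            }
        )
    trows = []
    for spec in test_results:
        pid, when, code = spec[:3]
        value = spec[3] if len(spec) > 3 else np.nan
        comparator = spec[4] if len(spec) > 4 else ("eq" if value is not None and not pd.isna(value) else np.nan)
        trows.append({"patient_id": pid, "date": pd.Timestamp(when), "code": code, "value": value, "comparator": comparator})
    ds = pi.SyntheticEhr(
        patients=pd.DataFrame(prows),
        medications=pd.DataFrame(
            [{"patient_id": p, "date": pd.Timestamp(d), "code": c} for p, d, c in medications],
            columns=["patient_id", "date", "code"],
        ),
        clinical_events=pd.DataFrame(
            [{"patient_id": p, "date": pd.Timestamp(d), "code": c} for p, d, c in clinical_events],
            columns=["patient_id", "date", "code"],
        ),
        test_results=pd.DataFrame(trows, columns=["patient_id", "date", "code", "value", "comparator"]),
        provenance={"source": "test fixture"},
    )
    for df in (ds.medications, ds.clinical_events, ds.test_results):
        if len(df) == 0:
            df["date"] = pd.to_datetime(df["date"])
        df["patient_id"] = df["patient_id"].astype("int64") if len(df) else df["patient_id"]
    ds.test_results["value"] = ds.test_results["value"].astype(float)
    return ds


def add_noise_events(dataset, seed, n_medications=80, n_clinical=30, n_tests=40):
    """Sprinkle uniformly random coded events (all codelists, incl. the
    gastroprotective drugs the generator never emits) over a dataset."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    cls = default_codelists()
    med_codes = sorted(set().union(*(cl.codes for cl in cls.values() if cl.system == "medication")))
    clin_codes = sorted(set().union(*(cl.codes for cl in cls.values() if cl.system == "clinical")))
    test_codes = sorted(set().union(*(cl.codes for cl in cls.values() if cl.system == "test")))
    pids = dataset.patients["patient_id"].to_numpy()
    span_start, span_days = pd.Timestamp(date(2018, 1, 1)), 1400

    def draw(codes, n):
        return pd.DataFrame(
            {
                "patient_id": rng.choice(pids, size=n),
                "date": span_start + pd.to_timedelta(rng.integers(0, span_days, size=n), unit="D"),
                "code": rng.choice(codes, size=n),
            }
        )

    meds = draw(med_codes, n_medications)
    clin = draw(clin_codes, n_clinical)
    tests = draw(test_codes, n_tests)
    has_value = rng.random(n_tests) < 0.6
    values = np.round(rng.uniform(5, 120, size=n_tests), 1)
    comparators = rng.choice(["eq", "lt", "le", "gt", "ge"], size=n_tests)
    tests["value"] = np.where(has_value, values, np.nan)
    tests["comparator"] = np.where(has_value, comparators, None)
    out = pi.SyntheticEhr(
        patients=dataset.patients,
        medications=pd.concat([dataset.medications, meds], ignore_index=True),
        clinical_events=pd.concat([dataset.clinical_events, clin], ignore_index=True),
        test_results=pd.concat([dataset.test_results, tests], ignore_index=True),
        provenance={**dataset.provenance, "noise_seed": seed},
    )
    out.validate()
    return out
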
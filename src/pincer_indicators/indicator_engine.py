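"""Monthly evaluation of the 13 PINCER hazardous-prescribing indicators.

The 13 clinical indicators yield 14 measure keys: the methotrexate indicator
carries two monitoring sub-measures (full blood count and liver function).
Each indicator is a pair of cohort rules evaluated for every patient on the
first of each month:

* a **denominator** — the patients for whom the safety check is clinically
  meaningful (e.g. everyone aged >=65, or everyone established on lithium);
* a **numerator** — the denominator subset currently exposed to the hazard
  (e.g. on an oral NSAID without gastroprotection, or overdue a blood test).

Window conventions (applied uniformly):

* "current prescription" — at least one medication event in the half-open
  window ``[as_of - lookback_days, as_of)``; the default lookback is 90 days.
* "history of" a condition — any clinical event strictly before ``as_of``.
* monitoring windows — calendar-month arithmetic, ``[as_of - w months, as_of)``.
* "established treatment" — a current prescription *and* an earliest-ever
  prescription at least ``min_treatment_months`` calendar months before
  ``as_of``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import pandas as pd
import yaml
from dateutil.relativedelta import relativedelta

from . import codes as _codes
from .ehr_model import Codelist, DatasetError, SyntheticEhr, add_months

INDICATOR_KEYS = (
    "a_age65_nsaid",
    "b_pu_nsaid",
    "c_pu_antiplatelet",
    "d_anticoag_nsaid",
    "e_anticoag_antiplatelet",
    "f_aspirin_antiplatelet",
    "g_hf_nsaid",
    "h_asthma_betablocker",
    "i_crf_nsaid",
    "j_acei_loop_no_renal",
    "k_mtx_no_fbc",
    "l_mtx_no_lft",
    "m_lithium_no_level",
    "n_amiodarone_no_tft",
)

INDICATOR_GROUPS = {
    "gi_bleed": (
        "a_age65_nsaid",
        "b_pu_nsaid",
        "c_pu_antiplatelet",
        "d_anticoag_nsaid",
        "e_anticoag_antiplatelet",
        "f_aspirin_antiplatelet",
    ),
    "cautioned": ("g_hf_nsaid", "h_asthma_betablocker", "i_crf_nsaid"),
    "monitoring": (
        "j_acei_loop_no_renal",
        "k_mtx_no_fbc",
        "l_mtx_no_lft",
        "m_lithium_no_level",
        "n_amiodarone_no_tft",
    ),
}

MONITORING_KEYS = INDICATOR_GROUPS["monitoring"]

FLAG_COLUMNS = ["patient_id", "indicator", "month", "in_denominator", "in_numerator"]


@dataclass(frozen=True)
class IndicatorDefinition:
    key: str
    group: str
    codelists: dict[str, Codelist] = field(default_factory=dict)
    lookback_days: int = 90
    monitoring_window_months: int | None = None
    min_treatment_months: int | None = None
    min_age: int | None = None
    max_age: int | None = None
    requires_numeric_values: bool = False
    egfr_threshold: float = 45.0

    def __post_init__(self):
        if self.key not in INDICATOR_KEYS:
            raise DatasetError(f"unknown indicator key {self.key!r}")
        is_monitoring = self.key in MONITORING_KEYS
        if is_monitoring and not self.monitoring_window_months:
            raise DatasetError(f"{self.key}: monitoring indicator needs a monitoring window")
        if not is_monitoring and self.monitoring_window_months:
            raise DatasetError(f"{self.key}: only monitoring indicators take a monitoring window")
        if self.lookback_days <= 0:
            raise DatasetError(f"{self.key}: lookback_days must be positive")


def load_definitions(path: str | Path, codelist_dir: str | Path | None = None) -> dict[str, IndicatorDefinition]:
    """Load indicator definitions from a YAML file.

    Each entry binds codelist names (CSV file stems in ``codelist_dir``,
    defaulting to the shipped synthetic codelists) to the roles the
    indicator's rule uses.
    """
    path = Path(path)
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    lookback = int(spec.get("lookback_days", 90))
    if codelist_dir is not None:
        codelist_dir = Path(codelist_dir)
        pool: dict[str, Codelist] = {}
    else:
        pool = _codes.default_codelists()

    defs = {}
    for key, entry in spec["indicators"].items():
        bound = {}
        for role, name in entry["codelists"].items():
            system = _codes.ROLE_SYSTEMS[role]
            if name in pool:
                cl = pool[name]
            else:
                from .ehr_model import load_codelist

                cl = load_codelist(Path(codelist_dir) / f"{name}.csv", system)
                pool[name] = cl
            if cl.system != system:
                raise DatasetError(f"{key}: role {role!r} expects a {system} codelist, got {cl.system}")
            bound[role] = cl
        defs[key] = IndicatorDefinition(
            key=key,
            group=entry["group"],
            codelists=bound,
            lookback_days=int(entry.get("lookback_days", lookback)),
            monitoring_window_months=entry.get("monitoring_window_months"),
            min_treatment_months=entry.get("min_treatment_months"),
            min_age=entry.get("min_age"),
            max_age=entry.get("max_age"),
            requires_numeric_values=bool(entry.get("requires_numeric_values", False)),
            egfr_threshold=float(entry.get("egfr_threshold", 45.0)),
        )
    missing = set(INDICATOR_KEYS) - set(defs)
    if missing:
        raise DatasetError(f"definitions file lacks indicators: {sorted(missing)}")
    return defs


def default_definitions() -> dict[str, IndicatorDefinition]:
    from importlib import resources

    with resources.as_file(_codes.data_path().joinpath("definitions.yaml")) as path:
        return load_definitions(path)


# ---------------------------------------------------------------------------
# scalar operations (per-patient semantics; the vectorised evaluator below
# follows exactly the same window conventions)


def age_on(date_of_birth: date, as_of: date) -> int:
    """Completed years of age on ``as_of``."""
    if date_of_birth > as_of:
        raise ValueError("date_of_birth after as_of")
    return relativedelta(as_of, date_of_birth).years


def on_medication(medications: pd.DataFrame, patient_id, codelist: Codelist, as_of: date, lookback_days: int = 90) -> bool:
    """True iff the patient has a codelist prescription in ``[as_of - lookback, as_of)``."""
    if lookback_days <= 0:
        raise ValueError("lookback_days must be positive")
    start = pd.Timestamp(as_of - timedelta(days=lookback_days))
    end = pd.Timestamp(as_of)
    sub = medications[medications["patient_id"] == patient_id]
    mask = sub["code"].isin(codelist.codes) & (sub["date"] >= start) & (sub["date"] < end)
    return bool(mask.any())


def has_history(clinical_events: pd.DataFrame, patient_id, codelist: Codelist, as_of: date) -> bool:
    """True iff any codelist clinical event strictly before ``as_of``."""
    sub = clinical_events[clinical_events["patient_id"] == patient_id]
    mask = sub["code"].isin(codelist.codes) & (sub["date"] < pd.Timestamp(as_of))
    return bool(mask.any())


def established_treatment(
    medications: pd.DataFrame,
    patient_id,
    codelist: Codelist,
    as_of: date,
    min_months: int,
    lookback_days: int = 90,
) -> bool:
    """Current prescription plus earliest-ever prescription >= ``min_months`` before ``as_of``."""
    if min_months <= 0:
        raise ValueError("min_months must be positive")
    sub = medications[medications["patient_id"] == patient_id]
    sub = sub[sub["code"].isin(codelist.codes) & (sub["date"] < pd.Timestamp(as_of))]
    if sub.empty:
        return False
    current = (sub["date"] >= pd.Timestamp(as_of - timedelta(days=lookback_days))).any()
    established = sub["date"].min() <= pd.Timestamp(add_months(as_of, -min_months))
    return bool(current and established)


def has_recent_test(test_results: pd.DataFrame, patient_id, codelist: Codelist, as_of: date, window_months: int) -> bool:
    """True iff any codelist test result in ``[as_of - window_months, as_of)`` (calendar months)."""
    if window_months <= 0:
        raise ValueError("window_months must be positive")
    start = pd.Timestamp(add_months(as_of, -window_months))
    sub = test_results[test_results["patient_id"] == patient_id]
    mask = sub["code"].isin(codelist.codes) & (sub["date"] >= start) & (sub["date"] < pd.Timestamp(as_of))
    return bool(mask.any())


def resolve_threshold(value: float, comparator: str | None, threshold: float, direction: str = "below") -> str:
    """Classify a comparator-coded numeric result against ``true value < threshold``.

    Returns ``"satisfied"`` when the coded result unambiguously implies the
    true value is below the threshold, ``"not_satisfied"`` when it
    unambiguously contradicts it, and ``"ambiguous"`` otherwise (e.g. a
    result coded ``>30`` tells us nothing about being below 45).
    A missing comparator is read as equality.
    """
    if direction != "below":
        raise ValueError("only direction='below' thresholds are supported")
    cmp = comparator if comparator and not pd.isna(comparator) else "eq"
    if cmp == "eq":
        return "satisfied" if value < threshold else "not_satisfied"
    if cmp == "lt":  # true value < recorded value
        return "satisfied" if value <= threshold else "ambiguous"
    if cmp == "le":  # true value <= recorded value
        return "satisfied" if value < threshold else "ambiguous"
    if cmp in ("gt", "ge"):  # true value > / >= recorded value
        return "not_satisfied" if value >= threshold else "ambiguous"
    raise ValueError(f"unknown comparator {cmp!r}")


# ---------------------------------------------------------------------------
# vectorised evaluation


def base_population(dataset: SyntheticEhr, as_of: date) -> set:
    """Patients alive, aged 18-120, and registered on ``as_of``."""
    pats = dataset.patients
    ts = pd.Timestamp(as_of)
    dob = pats["date_of_birth"]
    years = as_of.year - dob.dt.year
    not_yet = (dob.dt.month > as_of.month) | ((dob.dt.month == as_of.month) & (dob.dt.day > as_of.day))
    age = years - not_yet.astype(int)
    alive = pats["date_of_death"].isna() | (pats["date_of_death"] >= ts)
    registered = (pats["registration_start"] <= ts) & (
        pats["registration_end"].isna() | (pats["registration_end"] >= ts)
    )
    ok = alive & registered & (age >= 18) & (age <= 120)
    return set(pats.loc[ok, "patient_id"])


def _ages(dataset: SyntheticEhr, as_of: date) -> pd.Series:
    pats = dataset.patients
    dob = pats["date_of_birth"]
    years = as_of.year - dob.dt.year
    not_yet = (dob.dt.month > as_of.month) | ((dob.dt.month == as_of.month) & (dob.dt.day > as_of.day))
    return pd.Series((years - not_yet.astype(int)).values, index=pats["patient_id"].values)


def _ids_in_window(events: pd.DataFrame, codelist: Codelist, start: date, end: date) -> set:
    mask = events["code"].isin(codelist.codes) & (events["date"] >= pd.Timestamp(start)) & (
        events["date"] < pd.Timestamp(end)
    )
    return set(events.loc[mask, "patient_id"])


def _ids_with_history(events: pd.DataFrame, codelist: Codelist, as_of: date) -> set:
    mask = events["code"].isin(codelist.codes) & (events["date"] < pd.Timestamp(as_of))
    return set(events.loc[mask, "patient_id"])


def _ids_established(meds: pd.DataFrame, codelist: Codelist, as_of: date, min_months: int, lookback_days: int) -> set:
    sub = meds[meds["code"].isin(codelist.codes) & (meds["date"] < pd.Timestamp(as_of))]
    if sub.empty:
        return set()
    current = set(sub.loc[sub["date"] >= pd.Timestamp(as_of - timedelta(days=lookback_days)), "patient_id"])
    earliest = sub.groupby("patient_id")["date"].min()
    est = set(earliest[earliest <= pd.Timestamp(add_months(as_of, -min_months))].index)
    return current & est


def _ids_egfr_satisfied(tests: pd.DataFrame, codelist: Codelist, as_of: date, threshold: float) -> set:
    """Patients whose latest numeric eGFR before ``as_of`` is unambiguously below threshold.

    Only value-bearing results are considered; ties on date are broken by
    record order (the last recorded result wins).
    """
    sub = tests[tests["code"].isin(codelist.codes) & (tests["date"] < pd.Timestamp(as_of)) & tests["value"].notna()]
    if sub.empty:
        return set()
    sub = sub.sort_values(["patient_id", "date"], kind="mergesort")
    last = sub.groupby("patient_id", sort=False).tail(1)
    keep = [
        pid
        for pid, val, cmp in zip(last["patient_id"], last["value"], last["comparator"])
        if resolve_threshold(val, cmp, threshold) == "satisfied"
    ]
    return set(keep)


def evaluate_indicator(
    dataset: SyntheticEhr,
    definition: IndicatorDefinition,
    as_of: date,
    capabilities=None,
) -> pd.DataFrame | None:
    """One flag row per denominator patient for one indicator and month.

    Returns ``None`` (a skip signal, not an error) when the indicator needs
    numeric comparator support the backend does not declare.
    """
    if definition.requires_numeric_values and capabilities is not None:
        if not getattr(capabilities, "supports_numeric_comparators", True):
            return None

    key = definition.key
    cl = definition.codelists
    lookback = definition.lookback_days
    win_start = as_of - timedelta(days=lookback)
    base = base_population(dataset, as_of)
    meds = dataset.medications
    ages = None

    def hazard_ids() -> set:
        return _ids_in_window(meds, cl["hazard"], win_start, as_of)

    def protected_ids() -> set:
        if "protective" not in cl:
            return set()
        return _ids_in_window(meds, cl["protective"], win_start, as_of)

    if key == "a_age65_nsaid":
        ages = _ages(dataset, as_of)
        den = {p for p in base if ages[p] >= (definition.min_age or 65)}
        num = (hazard_ids() - protected_ids()) & den
    elif key in ("b_pu_nsaid", "c_pu_antiplatelet", "g_hf_nsaid", "h_asthma_betablocker"):
        den = base & _ids_with_history(dataset.clinical_events, cl["condition"], as_of)
        num = (hazard_ids() - protected_ids()) & den
    elif key in ("d_anticoag_nsaid", "e_anticoag_antiplatelet", "f_aspirin_antiplatelet"):
        den = base & _ids_in_window(meds, cl["base_med"], win_start, as_of)
        num = (hazard_ids() - protected_ids()) & den
    elif key == "i_crf_nsaid":
        den = base & _ids_egfr_satisfied(dataset.test_results, cl["threshold_test"], as_of, definition.egfr_threshold)
        num = hazard_ids() & den
    elif key in MONITORING_KEYS:
        den = base & _ids_established(meds, cl["base_med"], as_of, definition.min_treatment_months, lookback)
        if definition.min_age is not None:
            ages = _ages(dataset, as_of)
            den = {p for p in den if ages[p] >= definition.min_age}
        tested = _ids_in_window(
            dataset.test_results,
            cl["monitoring_test"],
            add_months(as_of, -definition.monitoring_window_months),
            as_of,
        )
        num = den - tested
    else:  # pragma: no cover - key set is closed
        raise DatasetError(f"no rule for indicator {key!r}")

    den_sorted = sorted(den)
    return pd.DataFrame(
        {
            "patient_id": pd.array(den_sorted, dtype="int64"),
            "indicator": key,
            "month": pd.Timestamp(as_of),
            "in_denominator": pd.array([True] * len(den_sorted), dtype=bool),
            "in_numerator": pd.array([p in num for p in den_sorted], dtype=bool),
        },
        columns=FLAG_COLUMNS,
    )


def evaluate_all(
    dataset: SyntheticEhr,
    definitions: dict[str, IndicatorDefinition],
    months: list[date],
    capabilities=None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Evaluate every definition at every month; returns (flags, run log)."""
    frames = []
    log: list[dict] = []
    for key in sorted(definitions):
        definition = definitions[key]
        skipped = False
        for as_of in months:
            flags = evaluate_indicator(dataset, definition, as_of, capabilities)
            if flags is None:
                skipped = True
                break
            frames.append(flags)
        if skipped:
            log.append(
                {
                    "indicator": key,
                    "skipped": True,
                    "reason": "backend does not support numeric comparator queries",
                }
            )
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=FLAG_COLUMNS)
    return out, log
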
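"""Domain model for event-level pseudo-EHR data.

The in-memory container is a :class:`SyntheticEhr` holding five event-level
tables as pandas DataFrames (registrations are folded into the patient
table).  All dates are ISO-8601 calendar dates without times, because every
downstream evaluation happens "as of" the first of a month.

Code systems are synthetic: opaque tokens such as ``M0101`` with a shipped
registry mapping each token to its clinical role.  No real SNOMED-CT or dm+d
content is bundled.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd
from dateutil.relativedelta import relativedelta

BACKENDS = ("backend_a", "backend_b")
CODE_SYSTEMS = ("clinical", "medication", "test")
COMPARATORS = ("eq", "lt", "le", "gt", "ge")
SEXES = ("female", "male")
ETHNICITIES = ("white", "south_asian", "black", "mixed", "other", "missing")
IMD_QUINTILES = ("1", "2", "3", "4", "5", "missing")
REGIONS = (
    "East",
    "London",
    "Midlands",
    "North East and Yorkshire",
    "North West",
    "South East",
    "South West",
)

PATIENT_COLUMNS = [
    "patient_id",
    "backend",
    "practice_id",
    "date_of_birth",
    "sex",
    "ethnicity",
    "imd_quintile",
    "region",
    "registration_start",
    "registration_end",
    "date_of_death",
]
MEDICATION_COLUMNS = ["patient_id", "date", "code"]
CLINICAL_COLUMNS = ["patient_id", "date", "code"]
TEST_COLUMNS = ["patient_id", "date", "code", "value", "comparator"]

_DATE_COLUMNS = {
    "patients": ["date_of_birth", "registration_start", "registration_end", "date_of_death"],
    "medications": ["date"],
    "clinical_events": ["date"],
    "test_results": ["date"],
}


class DatasetError(ValueError):
    """Raised when a dataset or codelist violates a structural invariant."""


# ---------------------------------------------------------------------------
# calendar helpers


def parse_month(text: str) -> date:
    """Parse ``YYYY-MM`` (or ``YYYY-MM-DD``) into a first-of-month date."""
    parts = str(text).split("-")
    return date(int(parts[0]), int(parts[1]), 1)


def first_of_month(d: date) -> date:
    return date(d.year, d.month, 1)


def add_months(d: date, months: int) -> date:
    """Calendar-month shift, same day-of-month clamped to the month end."""
    return d + relativedelta(months=months)


def month_range(start: date, end: date) -> list[date]:
    """First-of-month dates from ``start`` to ``end`` inclusive."""
    start, end = first_of_month(start), first_of_month(end)
    if start > end:
        raise ValueError("start month after end month")
    out = []
    cur = start
    while cur <= end:
        out.append(cur)
        cur = add_months(cur, 1)
    return out


# ---------------------------------------------------------------------------
# codelists


@dataclass(frozen=True)
class Codelist:
    """A named set of codes in one code system.

    Membership is case-sensitive exact string match.
    """

    name: str
    system: str
    codes: frozenset[str]

    def __post_init__(self):
        if self.system not in CODE_SYSTEMS:
            raise DatasetError(f"unknown code system {self.system!r}")
        if not self.codes:
            raise DatasetError(f"codelist {self.name!r} is empty")
        if any(not c for c in self.codes):
            raise DatasetError(f"codelist {self.name!r} contains an empty code")

    def __contains__(self, code: str) -> bool:
        return code in self.codes


def load_codelist(path: str | Path, system: str) -> Codelist:
    """Load a ``code,term`` CSV into a :class:`Codelist`.

    Duplicate codes and empty bodies are hard errors: a codelist with a
    repeated code is almost always a curation mistake.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "code" not in reader.fieldnames:
            raise DatasetError(f"{path}: expected a header row containing 'code'")
        codes: list[str] = []
        for row in reader:
            code = (row["code"] or "").strip()
            if not code:
                raise DatasetError(f"{path}: blank code in body")
            if code in codes:
                raise DatasetError(f"{path}: duplicate code {code!r}")
            codes.append(code)
    if not codes:
        raise DatasetError(f"{path}: codelist body is empty")
    return Codelist(name=path.stem, system=system, codes=frozenset(codes))


# ---------------------------------------------------------------------------
# dataset container


@dataclass
class SyntheticEhr:
    """Five event-level tables tagged by backend and practice.

    ``provenance`` records the generator configuration and seed (or the load
    path) so any dataset can be traced back to the code that produced it.
    """

    patients: pd.DataFrame
    medications: pd.DataFrame
    clinical_events: pd.DataFrame
    test_results: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def validate(self) -> "SyntheticEhr":
        validate_dataset(self)
        return self

    def restrict_to_backend(self, backend: str) -> "SyntheticEhr":
        """Event-level view of a single backend's practices."""
        if backend not in BACKENDS:
            raise DatasetError(f"unknown backend {backend!r}")
        pats = self.patients[self.patients["backend"] == backend].copy()
        keep = set(pats["patient_id"])
        return SyntheticEhr(
            patients=pats.reset_index(drop=True),
            medications=self.medications[self.medications["patient_id"].isin(keep)].reset_index(drop=True),
            clinical_events=self.clinical_events[self.clinical_events["patient_id"].isin(keep)].reset_index(drop=True),
            test_results=self.test_results[self.test_results["patient_id"].isin(keep)].reset_index(drop=True),
            provenance={**self.provenance, "backend": backend},
        )

    def truncate_before(self, cutoff: date) -> "SyntheticEhr":
        """Drop all events dated on/after ``cutoff`` (used by no-lookahead checks)."""
        ts = pd.Timestamp(cutoff)
        return SyntheticEhr(
            patients=self.patients.copy(),
            medications=self.medications[self.medications["date"] < ts].reset_index(drop=True),
            clinical_events=self.clinical_events[self.clinical_events["date"] < ts].reset_index(drop=True),
            test_results=self.test_results[self.test_results["date"] < ts].reset_index(drop=True),
            provenance={**self.provenance, "truncated_before": str(cutoff)},
        )


def _require_columns(df: pd.DataFrame, cols: list[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DatasetError(f"table {table!r} is missing columns {missing}")


def validate_dataset(ds: SyntheticEhr) -> None:
    """Enforce referential closure and the patient-table invariants."""
    _require_columns(ds.patients, PATIENT_COLUMNS, "patients")
    _require_columns(ds.medications, MEDICATION_COLUMNS, "medications")
    _require_columns(ds.clinical_events, CLINICAL_COLUMNS, "clinical_events")
    _require_columns(ds.test_results, TEST_COLUMNS, "test_results")

    pats = ds.patients
    if pats["patient_id"].duplicated().any():
        dup = pats.loc[pats["patient_id"].duplicated(), "patient_id"].tolist()[:5]
        raise DatasetError(f"duplicate patient_id values: {dup}")
    bad_backend = set(pats["backend"]) - set(BACKENDS)
    if bad_backend:
        raise DatasetError(f"unknown backend values: {sorted(bad_backend)}")

    # practice ids must be disjoint across backends: federation combination
    # relies on practice identity being globally unique.
    per_backend = pats.groupby("backend")["practice_id"].agg(set)
    if len(per_backend) == 2:
        overlap = per_backend.iloc[0] & per_backend.iloc[1]
        if overlap:
            raise DatasetError(f"practice_id values shared across backends: {sorted(overlap)[:5]}")

    reg_bad = pats["registration_end"].notna() & (pats["registration_end"] < pats["registration_start"])
    if reg_bad.any():
        raise DatasetError(f"registration_end before registration_start for patients {pats.loc[reg_bad, 'patient_id'].tolist()[:5]}")
    death_bad = pats["date_of_death"].notna() & (pats["date_of_death"] < pats["date_of_birth"])
    if death_bad.any():
        raise DatasetError(f"date_of_death before date_of_birth for patients {pats.loc[death_bad, 'patient_id'].tolist()[:5]}")

    known = set(pats["patient_id"])
    for name, table in (
        ("medications", ds.medications),
        ("clinical_events", ds.clinical_events),
        ("test_results", ds.test_results),
    ):
        orphan = set(table["patient_id"]) - known
        if orphan:
            raise DatasetError(f"table {name!r} has events for unknown patients: {sorted(orphan)[:5]}")

    bad_cmp = set(ds.test_results["comparator"].dropna()) - set(COMPARATORS)
    if bad_cmp:
        raise DatasetError(f"unknown comparators: {sorted(bad_cmp)}")
    vals = ds.test_results["value"].dropna()
    if (vals < 0).any():
        raise DatasetError("negative test-result values")


# ---------------------------------------------------------------------------
# serialisation

_TABLE_FILES = {
    "patients": "patients.csv",
    "medications": "medications.csv",
    "clinical_events": "clinical_events.csv",
    "test_results": "test_results.csv",
}


def save_dataset(ds: SyntheticEhr, directory: str | Path) -> Path:
    """Write the five-file CSV layout (plus ``metadata.json``)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for attr, fname in _TABLE_FILES.items():
        df = getattr(ds, attr).copy()
        for col in _DATE_COLUMNS[attr]:
            df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        df.to_csv(directory / fname, index=False)
    with open(directory / "metadata.json", "w") as fh:
        json.dump(ds.provenance, fh, indent=2, default=str)
    return directory


def load_dataset(directory: str | Path) -> SyntheticEhr:
    """Load and validate a dataset directory written by :func:`save_dataset`."""
    directory = Path(directory)
    tables = {}
    for attr, fname in _TABLE_FILES.items():
        path = directory / fname
        if not path.exists():
            raise DatasetError(f"missing table file: {path}")
        df = pd.read_csv(path, dtype={"code": str, "comparator": str})
        for col in _DATE_COLUMNS[attr]:
            if col in df.columns:
                df[col] = pd.to_datetime(df[col], format="%Y-%m-%d")
        tables[attr] = df
    for col, kind in (("sex", str), ("ethnicity", str), ("imd_quintile", str), ("region", str), ("backend", str)):
        tables["patients"][col] = tables["patients"][col].astype(str)
    if "value" not in tables["test_results"].columns:
        tables["test_results"]["value"] = pd.Series(dtype=float)
    meta_path = directory / "metadata.json"
    provenance = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            provenance = json.load(fh)
    ds = SyntheticEhr(provenance=provenance, **tables)
    validate_dataset(ds)
    return ds
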
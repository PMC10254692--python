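"""Aggregation of patient flags into practice-level and cumulative measures.

Conventions (matching how national prescribing-safety summaries are
reported):

* practice-month percentage = 100 x numerator / denominator, undefined
  (row absent) when the denominator is zero;
* deciles use linear interpolation between order statistics;
* the Q1 mean pools practice-months over January-March (each practice-month
  is one unit);
* cumulative counts are patient-months: an event repeated in two months is
  two events; group rows deduplicate patients across the group's indicators
  within each month;
* reported percentages are rounded half-up to 2 decimal places;
* released aggregates pass through small-cell disclosure control
  (suppression then rounding), never the in-memory analysis tables.
"""

from __future__ import annotations

from datetime import date
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .indicator_engine import INDICATOR_GROUPS
from .ehr_model import add_months

MEASURE_COLUMNS = ["backend", "practice_id", "indicator", "month", "numerator", "denominator", "pct"]

DECILES = tuple(range(10, 100, 10))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (so 2.675 -> 2.68, unlike bankers' rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def report_pct(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """Percentage as printed in summary tables: 100*n/d rounded half-up."""
    if denominator == 0:
        raise ZeroDivisionError("percentage undefined for zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)


def practice_month_measures(flags: pd.DataFrame, patients: pd.DataFrame) -> pd.DataFrame:
    """Exact numerator/denominator tallies per practice x indicator x month."""
    if len(flags) and (flags["in_numerator"] & ~flags["in_denominator"]).any():
        raise ValueError("flags violate numerator subset-of denominator")
    joined = flags.merge(patients[["patient_id", "backend", "practice_id"]], on="patient_id", how="left")
    if joined["practice_id"].isna().any():
        raise ValueError("flags reference patients missing from the patient table")
    grouped = (
        joined.groupby(["backend", "practice_id", "indicator", "month"], as_index=False)
        .agg(numerator=("in_numerator", "sum"), denominator=("in_denominator", "sum"))
    )
    grouped["numerator"] = grouped["numerator"].astype(int)
    grouped["denominator"] = grouped["denominator"].astype(int)
    grouped["pct"] = 100.0 * grouped["numerator"] / grouped["denominator"]
    return grouped.sort_values(["indicator", "month", "backend", "practice_id"], kind="mergesort").reset_index(
        drop=True
    )


def decile_table(measures: pd.DataFrame, indicator: str) -> pd.DataFrame:
    """Monthly d10..d90 of practice percentages (linear interpolation)."""
    sub = measures[(measures["indicator"] == indicator) & measures["denominator"].gt(0)]
    rows = []
    for month, grp in sub.groupby("month"):
        pcts = grp["pct"].to_numpy(dtype=float)
        if len(pcts) == 0:
            continue
        values = np.percentile(pcts, DECILES, method="linear")
        rows.append({"indicator": indicator, "month": month, **{f"d{d}": v for d, v in zip(DECILES, values)}})
    columns = ["indicator", "month"] + [f"d{d}" for d in DECILES]
    return pd.DataFrame(rows, columns=columns)


def q1_mean(measures: pd.DataFrame, indicator: str, year: int, per_practice: bool = False) -> float:
    """Mean practice rate over January-March of ``year``.

    Default treats each practice-month as one unit; ``per_practice=True``
    averages within practice first, then across practices.
    """
    sub = measures[
        (measures["indicator"] == indicator)
        & (measures["month"].dt.year == year)
        & (measures["month"].dt.month.isin([1, 2, 3]))
        & measures["denominator"].gt(0)
    ]
    if sub.empty:
        raise ValueError(f"no Q1 {year} rows for indicator {indicator!r}")
    if per_practice:
        return float(sub.groupby("practice_id")["pct"].mean().mean())
    return float(sub["pct"].mean())


def max_impact_month(onset_month: date, window_months: int) -> date:
    """Disruption onset advanced by the indicator's monitoring window.

    Pure calendar addition: the month by which every patient's monitoring
    could have lapsed if nothing had been done since the onset.
    """
    if window_months < 0:
        raise ValueError("window_months must be >= 0")
    return add_months(onset_month, window_months)


def _group_month_counts(flags: pd.DataFrame, keys: tuple[str, ...]) -> pd.DataFrame:
    """Per-month distinct-patient denominator/numerator counts for a group."""
    sub = flags[flags["indicator"].isin(keys)]
    den = sub.groupby("month")["patient_id"].nunique()
    num = sub[sub["in_numerator"]].groupby("month")["patient_id"].nunique()
    out = pd.DataFrame({"denominator": den, "numerator": num}).fillna(0).astype(int)
    return out


def cumulative_summary(
    flags: pd.DataFrame,
    measures: pd.DataFrame,
    n_total_practices: int | None = None,
    total_practices_by_indicator: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Cumulative per-indicator and per-group summary over the study window.

    Counts are patient-months ("repeated events counted for each month"),
    plus the events-per-unique-patient ratio and the number and percentage
    of practices with at least one hazardous prescribing event.
    ``total_practices_by_indicator`` overrides the practice base per
    indicator (needed when an indicator runs on a subset of backends).
    """
    rows = []
    items = [(key, (key,)) for key in sorted(flags["indicator"].unique())]
    items += [(grp, keys) for grp, keys in INDICATOR_GROUPS.items() if any(k in set(flags["indicator"]) for k in keys)]
    for label, keys in items:
        is_group = len(keys) > 1
        if is_group:
            month_counts = _group_month_counts(flags, keys)
            cum_num = int(month_counts["numerator"].sum())
            cum_den = int(month_counts["denominator"].sum())
            sub = flags[flags["indicator"].isin(keys)]
        else:
            sub = flags[flags["indicator"] == keys[0]]
            cum_num = int(sub["in_numerator"].sum())
            cum_den = int(len(sub))
        unique_patients = int(sub.loc[sub["in_numerator"], "patient_id"].nunique())
        msub = measures[measures["indicator"].isin(keys)]
        practices_with_event = int(msub.loc[msub["numerator"] > 0, "practice_id"].nunique())
        if total_practices_by_indicator and not is_group and keys[0] in total_practices_by_indicator:
            base = total_practices_by_indicator[keys[0]]
        elif n_total_practices is not None:
            base = n_total_practices
        else:
            base = int(measures["practice_id"].nunique())
        rows.append(
            {
                "indicator": label,
                "is_group": is_group,
                "cum_numerator": cum_num,
                "cum_denominator": cum_den,
                "pct": report_pct(cum_num, cum_den) if cum_den else np.nan,
                "n_unique_patients": unique_patients,
                "events_per_patient_ratio": (cum_num / unique_patients) if unique_patients else np.nan,
                "n_practices_with_event": practices_with_event,
                "n_total_practices": base,
                "pct_practices": report_pct(practices_with_event, base) if base else np.nan,
            }
        )
    return pd.DataFrame(rows)


def apply_disclosure_control(
    table: pd.DataFrame,
    count_columns: tuple[str, ...] = ("numerator", "denominator"),
    suppress_below: int = 5,
    round_base: int = 5,
    pct_column: str | None = "pct",
) -> pd.DataFrame:
    """Small-cell suppression then rounding for released aggregates.

    Counts in ``(0, suppress_below]`` become missing (with a ``suppressed``
    marker); surviving counts are rounded to the nearest ``round_base``,
    bumped up to the next multiple above the suppression threshold if
    rounding would land them back inside the band (this is what makes the
    operation idempotent).  Percentages are recomputed from disclosed counts
    only.  Zero is non-disclosive and passes through.
    """
    if suppress_below < 0 or round_base < 1:
        raise ValueError("suppress_below must be >= 0 and round_base >= 1")
    out = table.copy()
    suppressed = pd.Series(False, index=out.index)
    for col in count_columns:
        vals = out[col].astype(float)
        hit = (vals > 0) & (vals <= suppress_below)
        rounded = np.floor(vals / round_base + 0.5) * round_base
        in_band = (rounded > 0) & (rounded <= suppress_below)
        rounded = np.where(in_band, np.ceil((suppress_below + 1) / round_base) * round_base, rounded)
        out[col] = np.where(hit, np.nan, rounded)
        suppressed |= hit
    out["suppressed"] = suppressed.to_numpy()
    if pct_column is not None and pct_column in out.columns:
        num, den = count_columns[0], count_columns[1]
        with np.errstate(invalid="ignore", divide="ignore"):
            out[pct_column] = 100.0 * out[num] / out[den]
        out.loc[out[den].isna() | out[num].isna() | (out[den] == 0), pct_column] = np.nan
    return out
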
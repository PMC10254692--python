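"""Federated execution: run the measures pipeline per backend, combine aggregates.

Mirrors the review-then-release workflow of federated analytics over two
EHR-vendor environments: identical analysis code executes against each
backend's event-level data in isolation, disclosure control is applied to
each backend's aggregate bundle, and only aggregates are combined.  No
patient-level record crosses the combination boundary (checked
structurally).  "Federation" here is a same-machine execution contract, not
remote execution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .ehr_model import BACKENDS, DatasetError, SyntheticEhr
from .indicator_engine import IndicatorDefinition, evaluate_all
from .measures import (
    apply_disclosure_control,
    cumulative_summary,
    decile_table,
    practice_month_measures,
    q1_mean,
    report_pct,
)


@dataclass(frozen=True)
class BackendCapabilities:
    backend: str
    supports_numeric_comparators: bool = True


@dataclass
class DisclosureSettings:
    suppress_below: int = 5
    round_base: int = 5


@dataclass
class AggregateBundle:
    """One backend's released aggregates: no event-level rows."""

    backend: str
    n_practices: int
    measures: pd.DataFrame
    cumulative: pd.DataFrame
    run_log: list = field(default_factory=list)
    disclosure: DisclosureSettings | None = None


@dataclass
class CombinedBundle:
    measures: pd.DataFrame
    cumulative: pd.DataFrame
    deciles: dict[str, pd.DataFrame]
    q1_means: pd.DataFrame
    run_log: list
    n_practices: int


def assert_aggregate_only(bundle) -> None:
    """Privacy gate: bundles must not carry a patient_id column anywhere."""
    frames = [bundle.measures, bundle.cumulative]
    if isinstance(bundle, CombinedBundle):
        frames += list(bundle.deciles.values()) + [bundle.q1_means]
    for df in frames:
        if "patient_id" in df.columns:
            raise DatasetError("aggregate bundle contains patient-level identifiers")


def _disclose_cumulative(cum: pd.DataFrame, disclosure: DisclosureSettings) -> pd.DataFrame:
    out = apply_disclosure_control(
        cum,
        count_columns=("cum_numerator", "cum_denominator"),
        suppress_below=disclosure.suppress_below,
        round_base=disclosure.round_base,
        pct_column=None,
    )
    for col in ("n_unique_patients", "n_practices_with_event"):
        vals = out[col].astype(float)
        hit = (vals > 0) & (vals <= disclosure.suppress_below)
        rounded = np.floor(vals / disclosure.round_base + 0.5) * disclosure.round_base
        out[col] = np.where(hit, np.nan, rounded)
    return _recompute_cumulative_stats(out)


def _recompute_cumulative_stats(cum: pd.DataFrame) -> pd.DataFrame:
    out = cum.copy()
    out["pct"] = [
        report_pct(n, d) if (pd.notna(n) and pd.notna(d) and d) else np.nan
        for n, d in zip(out["cum_numerator"], out["cum_denominator"])
    ]
    out["events_per_patient_ratio"] = [
        (n / u) if (pd.notna(n) and pd.notna(u) and u) else np.nan
        for n, u in zip(out["cum_numerator"], out["n_unique_patients"])
    ]
    out["pct_practices"] = [
        report_pct(p, t) if (pd.notna(p) and t) else np.nan
        for p, t in zip(out["n_practices_with_event"], out["n_total_practices"])
    ]
    return out


def run_backend(
    dataset: SyntheticEhr,
    definitions: dict[str, IndicatorDefinition],
    months: list[date],
    capabilities: BackendCapabilities,
    disclosure: DisclosureSettings | None = None,
) -> AggregateBundle:
    """Execute the full measures pipeline against one backend's data only."""
    backends_present = set(dataset.patients["backend"])
    if backends_present - {capabilities.backend}:
        raise DatasetError(
            f"dataset contains practices from foreign backends: {sorted(backends_present - {capabilities.backend})}"
        )
    n_practices = int(dataset.patients["practice_id"].nunique())
    if n_practices == 0:
        raise DatasetError("backend has no practices")

    flags, log = evaluate_all(dataset, definitions, months, capabilities)
    measures = practice_month_measures(flags, dataset.patients)
    cum = cumulative_summary(flags, measures, n_total_practices=n_practices)
    cum.insert(0, "backend", capabilities.backend)

    if disclosure is not None:
        measures = apply_disclosure_control(
            measures,
            suppress_below=disclosure.suppress_below,
            round_base=disclosure.round_base,
        )
        cum = _disclose_cumulative(cum, disclosure)

    bundle = AggregateBundle(
        backend=capabilities.backend,
        n_practices=n_practices,
        measures=measures,
        cumulative=cum,
        run_log=log,
        disclosure=disclosure,
    )
    assert_aggregate_only(bundle)
    return bundle


def combine(bundles: list[AggregateBundle]) -> CombinedBundle:
    """Pool disclosed aggregate bundles from backends with disjoint practices."""
    if not bundles:
        raise DatasetError("no bundles to combine")
    seen: set = set()
    for b in bundles:
        ids = set(b.measures["practice_id"].unique())
        overlap = seen & ids
        if overlap:
            raise DatasetError(f"practice_id {sorted(overlap)[:5]} appears in more than one bundle")
        seen |= ids

    measures = pd.concat([b.measures for b in bundles], ignore_index=True)
    measures = measures.sort_values(["indicator", "month", "backend", "practice_id"], kind="mergesort").reset_index(
        drop=True
    )

    # cumulative: sum count components across backends (patients are disjoint
    # across backends, so distinct-patient counts add), then recompute the
    # derived statistics from the summed counts.
    cum_all = pd.concat([b.cumulative for b in bundles], ignore_index=True)
    summed = (
        cum_all.groupby(["indicator", "is_group"], as_index=False)[
            ["cum_numerator", "cum_denominator", "n_unique_patients", "n_practices_with_event", "n_total_practices"]
        ]
        .sum(min_count=1)
    )
    combined_cum = _recompute_cumulative_stats(summed)

    deciles = {}
    q1_rows = []
    for indicator in sorted(measures["indicator"].unique()):
        ok = measures[measures["indicator"] == indicator].dropna(subset=["pct"])
        deciles[indicator] = decile_table(ok, indicator)
        for year in sorted(measures["month"].dt.year.unique()):
            has_q1 = (
                (ok["month"].dt.year == year) & ok["month"].dt.month.isin([1, 2, 3]) & ok["denominator"].gt(0)
            ).any()
            if has_q1:
                q1_rows.append({"indicator": indicator, "year": int(year), "q1_mean_pct": q1_mean(ok, indicator, year)})
    q1_means = pd.DataFrame(q1_rows)

    run_log = [entry for b in bundles for entry in ([{"backend": b.backend, **e} for e in b.run_log])]
    combined = CombinedBundle(
        measures=measures,
        cumulative=combined_cum,
        deciles=deciles,
        q1_means=q1_means,
        run_log=run_log,
        n_practices=sum(b.n_practices for b in bundles),
    )
    assert_aggregate_only(combined)
    return combined


def pooled_run(
    dataset: SyntheticEhr,
    definitions: dict[str, IndicatorDefinition],
    months: list[date],
) -> pd.DataFrame:
    """Non-federated reference execution: one pass over the pooled dataset.

    Returns the practice-month measure table; used to verify that federated
    execution plus combination is equivalent to pooling the event data.
    """
    flags, _ = evaluate_all(dataset, definitions, months, capabilities=None)
    return practice_month_measures(flags, dataset.patients)


# ---------------------------------------------------------------------------
# bundle (de)serialisation for the CLI


def save_bundle(bundle: AggregateBundle, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    m = bundle.measures.copy()
    m["month"] = pd.to_datetime(m["month"]).dt.strftime("%Y-%m-%d")
    m.to_csv(directory / "measures.csv", index=False)
    bundle.cumulative.to_csv(directory / "cumulative.csv", index=False)
    meta = {
        "backend": bundle.backend,
        "n_practices": bundle.n_practices,
        "run_log": bundle.run_log,
        "disclosure": None
        if bundle.disclosure is None
        else {"suppress_below": bundle.disclosure.suppress_below, "round_base": bundle.disclosure.round_base},
    }
    with open(directory / "bundle.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return directory


def load_bundle(directory: str | Path) -> AggregateBundle:
    directory = Path(directory)
    with open(directory / "bundle.json") as fh:
        meta = json.load(fh)
    measures = pd.read_csv(directory / "measures.csv")
    measures["month"] = pd.to_datetime(measures["month"])
    cumulative = pd.read_csv(directory / "cumulative.csv")
    disclosure = meta["disclosure"]
    return AggregateBundle(
        backend=meta["backend"],
        n_practices=meta["n_practices"],
        measures=measures,
        cumulative=cumulative,
        run_log=meta["run_log"],
        disclosure=None if disclosure is None else DisclosureSettings(**disclosure),
    )
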
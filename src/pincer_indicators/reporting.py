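"""Reports: cohort demographics, decile charts, and the end-to-end pipeline.

Charts follow the conventions of practice-level decile monitoring: the
median as a thick solid line, the other deciles dashed, a vertical line at
the national lockdown month and (for monitoring indicators) a second
vertical line at the projected month of maximum impact — the onset of
disruption advanced by the indicator's monitoring window, i.e. the month by
which every patient's monitoring could have lapsed absent mitigation.
"""

from __future__ import annotations

import json
from datetime import date
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
import yaml

from . import __version__
from .ehr_model import DatasetError, SyntheticEhr, load_dataset, month_range, parse_month
from .federation import (
    BackendCapabilities,
    CombinedBundle,
    DisclosureSettings,
    combine,
    run_backend,
    save_bundle,
)
from .indicator_engine import MONITORING_KEYS, default_definitions, evaluate_all, load_definitions
from .measures import max_impact_month, round_half_up
from .synthetic_ehr import GeneratorConfig, generate

AGE_BANDS = ((18, 19), (20, 29), (30, 39), (40, 49), (50, 59), (60, 69), (70, 79), (80, 120))

LOCKDOWN_MONTH = date(2020, 3, 1)


def _age_band_label(lo: int, hi: int) -> str:
    return f">={lo}" if hi >= 120 else f"{lo}-{hi}"


def demographics_table(
    datasets: dict[str, SyntheticEhr],
    flags_by_backend: dict[str, pd.DataFrame],
    month: date,
) -> pd.DataFrame:
    """Cohort description of patients in >=1 indicator denominator at ``month``.

    Each patient is counted once regardless of how many denominators they
    fall in; the combined column is the sum of backend counts and every
    percentage is count / block total x 100, rounded last.
    """
    ts = pd.Timestamp(month)
    cohorts = {}
    for backend, flags in flags_by_backend.items():
        sub = flags[flags["month"] == ts]
        if sub.empty:
            raise DatasetError(f"no flags for month {month} in backend {backend}")
        ids = set(sub["patient_id"].unique())
        pats = datasets[backend].patients
        cohorts[backend] = pats[pats["patient_id"].isin(ids)].copy()

    backends = sorted(cohorts)
    rows = []

    def block(name: str, categorise) -> None:
        per_backend = {b: categorise(cohorts[b]).value_counts() for b in backends}
        categories = []
        for b in backends:
            for cat in per_backend[b].index:
                if cat not in categories:
                    categories.append(cat)
        totals = {b: int(len(cohorts[b])) for b in backends}
        for cat in categories:
            row = {"block": name, "category": str(cat)}
            combined_count = 0
            for b in backends:
                c = int(per_backend[b].get(cat, 0))
                row[f"{b}_count"] = c
                row[f"{b}_pct"] = round_half_up(100.0 * c / totals[b]) if totals[b] else float("nan")
                combined_count += c
            total_all = sum(totals.values())
            row["combined_count"] = combined_count
            row["combined_pct"] = round_half_up(100.0 * combined_count / total_all) if total_all else float("nan")
            rows.append(row)

    def overall(pats: pd.DataFrame) -> pd.Series:
        return pd.Series(["total"] * len(pats), index=pats.index)

    def age_bands(pats: pd.DataFrame) -> pd.Series:
        dob = pats["date_of_birth"]
        years = month.year - dob.dt.year
        not_yet = (dob.dt.month > month.month) | ((dob.dt.month == month.month) & (dob.dt.day > month.day))
        age = years - not_yet.astype(int)
        labels = pd.Series("<18", index=pats.index)
        for lo, hi in AGE_BANDS:
            labels[(age >= lo) & (age <= hi)] = _age_band_label(lo, hi)
        return labels

    block("overall", overall)
    block("age", age_bands)
    block("sex", lambda p: p["sex"])
    block("ethnicity", lambda p: p["ethnicity"])
    block("imd_quintile", lambda p: p["imd_quintile"])
    block("region", lambda p: p["region"])
    return pd.DataFrame(rows)


def decile_chart(
    series: pd.DataFrame,
    lockdown_month: date | None,
    max_impact: date | None,
    out_path: str | Path,
    title: str | None = None,
) -> Path:
    """Render one indicator's decile series to an image file."""
    if series.empty:
        raise ValueError("empty decile series")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    months = pd.to_datetime(series["month"])
    fig, ax = plt.subplots(figsize=(7, 4))
    for col in [c for c in series.columns if c.startswith("d")]:
        if col == "d50":
            ax.plot(months, series[col], color="rebeccapurple", linewidth=2.2, label="median")
        else:
            ax.plot(months, series[col], color="rebeccapurple", linewidth=0.8, linestyle="--")
    if lockdown_month is not None:
        ax.axvline(pd.Timestamp(lockdown_month), color="goldenrod", linestyle="--", label="lockdown")
    if max_impact is not None:
        ax.axvline(pd.Timestamp(max_impact), color="crimson", linestyle="--", label="projected max impact")
    ax.set_ylabel("% of denominator at risk")
    ax.set_xlabel("month")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper left", fontsize=8)
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(out_path, dpi=100, metadata={"Software": "pincer-indicators"})
    plt.close(fig)
    return out_path


DEFAULT_CAPABILITIES = {"backend_a": True, "backend_b": False}


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> Path:
    """Generate (or load) a dataset, run each backend, combine, write outputs.

    ``config`` is a mapping (or YAML file path) with optional keys:
    ``generator`` (GeneratorConfig fields), ``dataset_dir``, ``definitions``
    (YAML path), ``months`` ({start, end}), ``capabilities``
    (backend -> supports numeric comparators), ``disclosure``
    ({suppress_below, round_base} or null), ``charts`` (bool),
    ``lockdown_month``, ``output_dir``.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out = Path(out_dir or config.get("output_dir", "pincer_outputs"))
    out.mkdir(parents=True, exist_ok=True)

    # --- stage: data ---
    try:
        if config.get("dataset_dir"):
            dataset = load_dataset(config["dataset_dir"])
            gen_cfg = None
        else:
            gen_cfg = GeneratorConfig.from_dict(config.get("generator", {}))
            dataset = generate(gen_cfg)
    except Exception as exc:
        raise RuntimeError(f"stage 'data': {exc}") from exc

    if config.get("definitions"):
        definitions = load_definitions(config["definitions"])
    else:
        definitions = default_definitions()

    months_cfg = config.get("months", {})
    if months_cfg:
        months = month_range(parse_month(months_cfg["start"]), parse_month(months_cfg["end"]))
    elif gen_cfg is not None:
        months = month_range(gen_cfg.study_start, gen_cfg.study_end)
    else:
        cfg = dataset.provenance.get("config", {})
        months = month_range(parse_month(cfg["study_start"]), parse_month(cfg["study_end"]))

    caps_cfg = {**DEFAULT_CAPABILITIES, **config.get("capabilities", {})}
    disclosure_cfg = config.get("disclosure", {"suppress_below": 5, "round_base": 5})
    disclosure = DisclosureSettings(**disclosure_cfg) if disclosure_cfg else None

    # --- stage: per-backend federated runs ---
    bundles = []
    flags_by_backend = {}
    datasets = {}
    try:
        for backend in sorted(set(dataset.patients["backend"])):
            local = dataset.restrict_to_backend(backend)
            datasets[backend] = local
            caps = BackendCapabilities(backend, supports_numeric_comparators=caps_cfg.get(backend, True))
            bundles.append(run_backend(local, definitions, months, caps, disclosure))
            # flags are recomputed for the demographics report inside the
            # backend boundary; they never enter a bundle
            flags, _ = evaluate_all(local, definitions, months, caps)
            flags_by_backend[backend] = flags
    except Exception as exc:
        raise RuntimeError(f"stage 'run_backend': {exc}") from exc

    # --- stage: combine ---
    try:
        combined = combine(bundles)
    except Exception as exc:
        raise RuntimeError(f"stage 'combine': {exc}") from exc

    # --- stage: report ---
    try:
        write_outputs(combined, out)
        demo = demographics_table(datasets, flags_by_backend, months[-1])
        demo.to_csv(out / "demographics.csv", index=False)
        if config.get("charts", True):
            windows = {
                key: definitions[key].monitoring_window_months for key in MONITORING_KEYS if key in definitions
            }
            lockdown = parse_month(str(config.get("lockdown_month", LOCKDOWN_MONTH)))
            for indicator, series in combined.deciles.items():
                if series.empty:  # every practice-month suppressed
                    continue
                impact = (
                    max_impact_month(lockdown, windows[indicator]) if indicator in windows else None
                )
                decile_chart(series, lockdown, impact, out / "figures" / f"deciles_{indicator}.png", title=indicator)
        log = {
            "package_version": __version__,
            "seed": None if gen_cfg is None else gen_cfg.seed,
            "months": [str(m) for m in months],
            "n_practices": combined.n_practices,
            "capabilities": caps_cfg,
            "disclosure": disclosure_cfg or None,
            "skipped": combined.run_log,
        }
        with open(out / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2)
    except RuntimeError:
        raise
    except Exception as exc:
        raise RuntimeError(f"stage 'report': {exc}") from exc
    return out


def write_outputs(combined: CombinedBundle, out: str | Path) -> None:
    """Write the combined bundle as tidy CSVs (aggregate-only by construction)."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    for indicator, grp in combined.measures.groupby("indicator"):
        g = grp.copy()
        g["month"] = pd.to_datetime(g["month"]).dt.strftime("%Y-%m-%d")
        g.to_csv(out / f"measures_{indicator}.csv", index=False)
    for indicator, series in combined.deciles.items():
        s = series.copy()
        if not s.empty:
            s["month"] = pd.to_datetime(s["month"]).dt.strftime("%Y-%m-%d")
        s.to_csv(out / f"deciles_{indicator}.csv", index=False)
    combined.cumulative.to_csv(out / "cumulative_summary.csv", index=False)
    combined.q1_means.to_csv(out / "q1_means.csv", index=False)
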
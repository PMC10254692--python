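#!/usr/bin/env python
"""Render the practice-level decile charts.

One chart per measure key: median emphasised, other deciles dashed, a
vertical line at the March 2020 lockdown, and — for the monitoring
indicators — a second vertical line at the projected month of maximum
impact (lockdown advanced by the monitoring window: June 2020 for the
3-month windows, September 2020 for amiodarone, June 2021 for the
ACE-inhibitor/loop-diuretic indicator).
"""

from datetime import date
from pathlib import Path

import pandas as pd

import pincer_indicators as pi

COMBINED = Path("results/combined")
FIGURES = Path("results/figures")

LOCKDOWN = date(2020, 3, 1)


def main() -> None:
    definitions = pi.default_definitions()
    made = 0
    for path in sorted(COMBINED.glob("deciles_*.csv")):
        key = path.stem.removeprefix("deciles_")
        series = pd.read_csv(path)
        if series.empty:
            print(f"{key}: no disclosable practice-months, skipped")
            continue
        series["month"] = pd.to_datetime(series["month"])
        window = definitions[key].monitoring_window_months
        impact = pi.max_impact_month(LOCKDOWN, window) if window else None
        out = pi.decile_chart(series, LOCKDOWN, impact, FIGURES / f"{key}.png", title=key)
        made += 1
        annotation = f" (max impact {impact})" if impact else ""
        print(f"{key}: {len(series)} months -> {out}{annotation}")
    print(f"{made} charts in {FIGURES}")


if __name__ == "__main__":
    main()
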
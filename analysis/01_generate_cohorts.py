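#!/usr/bin/env python
"""Generate the synthetic two-backend study cohort.

Emulates the study conditions: two EHR backends, monthly evaluation horizon
September 2019 - September 2021, co-hazard and monitoring-miss rates at
pre-pandemic national levels, and a monitoring disruption from March 2020
with a staged recovery.  The event-level dataset goes to scratch/ (it is an
intermediate, regenerated on demand); a small summary table goes to
results/.
"""

from pathlib import Path

import pandas as pd

import pincer_indicators as pi

DATASET_DIR = Path("scratch/study_dataset")
RESULTS = Path("results")

CONFIG = pi.GeneratorConfig(
    seed=20190901,
    n_practices_a=12,
    n_practices_b=18,
    patients_per_practice=80,
)


def main() -> None:
    ds = pi.generate(CONFIG)
    pi.save_dataset(ds, DATASET_DIR)

    RESULTS.mkdir(exist_ok=True)
    summary = (
        ds.patients.groupby("backend")
        .agg(n_practices=("practice_id", "nunique"), n_patients=("patient_id", "size"))
        .reset_index()
    )
    events = pd.DataFrame(
        {
            "backend": summary["backend"],
            "n_prescriptions": [
                ds.medications["patient_id"].isin(ds.patients.loc[ds.patients["backend"] == b, "patient_id"]).sum()
                for b in summary["backend"]
            ],
            "n_test_results": [
                ds.test_results["patient_id"].isin(ds.patients.loc[ds.patients["backend"] == b, "patient_id"]).sum()
                for b in summary["backend"]
            ],
        }
    )
    summary = summary.merge(events, on="backend")
    summary.to_csv(RESULTS / "dataset_summary.csv", index=False)

    print(f"dataset -> {DATASET_DIR}")
    print(summary.to_string(index=False))
    print(
        f"horizon {CONFIG.study_start}..{CONFIG.study_end}; "
        f"monitoring disruption x{CONFIG.disruption.multiplier} over "
        f"{CONFIG.disruption.onset_month}..{CONFIG.disruption.end_month}"
    )


if __name__ == "__main__":
    main()
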
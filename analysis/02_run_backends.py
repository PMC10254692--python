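#!/usr/bin/env python
"""Run the indicator pipeline separately inside each backend (federated stage).

Backend A supports numeric comparator queries; backend B does not, so the
renal-impairment NSAID indicator is evaluated on backend A only — the skip
is recorded in the run log, not raised.  Each backend releases a
disclosure-controlled aggregate bundle (small cells suppressed, counts
rounded to 5); nothing patient-level leaves this stage.
"""

from pathlib import Path

import pincer_indicators as pi
from pincer_indicators.federation import save_bundle

DATASET_DIR = Path("scratch/study_dataset")
BUNDLES_DIR = Path("scratch/bundles")

CAPABILITIES = {
    "backend_a": pi.BackendCapabilities("backend_a", supports_numeric_comparators=True),
    "backend_b": pi.BackendCapabilities("backend_b", supports_numeric_comparators=False),
}


def main() -> None:
    ds = pi.load_dataset(DATASET_DIR)
    cfg = ds.provenance["config"]
    months = pi.month_range(pi.parse_month(cfg["study_start"]), pi.parse_month(cfg["study_end"]))
    disclosure = pi.DisclosureSettings(suppress_below=5, round_base=5)

    for backend, caps in CAPABILITIES.items():
        local = ds.restrict_to_backend(backend)
        bundle = pi.run_backend(local, pi.default_definitions(), months, caps, disclosure)
        save_bundle(bundle, BUNDLES_DIR / backend)
        keys = bundle.measures["indicator"].nunique()
        print(f"{backend}: {bundle.n_practices} practices, {keys} measure keys -> {BUNDLES_DIR / backend}")
        for entry in bundle.run_log:
            print(f"  skipped {entry['indicator']}: {entry['reason']}")


if __name__ == "__main__":
    main()
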
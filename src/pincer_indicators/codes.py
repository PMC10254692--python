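"""Shipped synthetic code registry.

Each codelist is a small ``code,term`` CSV under ``data/codelists/``; the
tokens (``M0101`` ...) are opaque stand-ins whose clinical role is given by
the ``term`` column and by the registry below.  Real terminology content
(SNOMED-CT, dm+d) is a configuration input, never package data.
"""

from __future__ import annotations

from importlib import resources

from .ehr_model import Codelist, load_codelist

# codelist file stem -> code system
CODELIST_SYSTEMS: dict[str, str] = {
    "oral_nsaid": "medication",
    "ulcer_healing_drug": "medication",
    "aspirin": "medication",
    "antiplatelet_other": "medication",
    "antiplatelet_any": "medication",
    "anticoagulant": "medication",
    "beta_blocker_nonselective": "medication",
    "acei_or_loop": "medication",
    "methotrexate": "medication",
    "lithium_medication": "medication",
    "amiodarone": "medication",
    "peptic_ulcer": "clinical",
    "heart_failure": "clinical",
    "asthma": "clinical",
    "egfr": "test",
    "renal_function": "test",
    "full_blood_count": "test",
    "liver_function": "test",
    "lithium_level": "test",
    "thyroid_function": "test",
}

# indicator-definition role -> code system expected for that role
ROLE_SYSTEMS: dict[str, str] = {
    "hazard": "medication",
    "base_med": "medication",
    "protective": "medication",
    "condition": "clinical",
    "monitoring_test": "test",
    "threshold_test": "test",
}

MONITORING_TEST_CODELISTS = (
    "renal_function",
    "full_blood_count",
    "liver_function",
    "lithium_level",
    "thyroid_function",
)


def data_path():
    return resources.files("pincer_indicators").joinpath("data")


def default_codelists() -> dict[str, Codelist]:
    """Load every shipped codelist, keyed by file stem."""
    base = data_path().joinpath("codelists")
    out = {}
    for name, system in CODELIST_SYSTEMS.items():
        with resources.as_file(base.joinpath(f"{name}.csv")) as path:
            out[name] = load_codelist(path, system)
    return out
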
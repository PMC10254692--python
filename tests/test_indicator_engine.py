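from datetime import date

import pandas as pd
import pytest

import pincer_indicators as pi
from pincer_indicators.indicator_engine import (
    age_on,
    established_treatment,
    has_history,
    has_recent_test,
    on_medication,
)

from conftest import add_noise_events, make_dataset
import oracle

AS_OF = date(2020, 3, 1)


@pytest.fixture(scope="module")
def codelists():
    from pincer_indicators.codes import default_codelists

    return default_codelists()


class TestScalarOps:
    @pytest.mark.parametrize(
        "dob,as_of,expected",
        [
            (date(1955, 3, 1), date(2020, 3, 1), 65),  # exact anniversary
            (date(1955, 3, 2), date(2020, 3, 1), 64),  # day before anniversary
            (date(2000, 1, 1), date(2020, 6, 1), 20),
        ],
    )
    def test_age_in_completed_years(self, dob, as_of, expected):
        assert age_on(dob, as_of) == expected

    def test_age_requires_birth_before_as_of(self):
        with pytest.raises(ValueError):
            age_on(date(2021, 1, 1), date(2020, 1, 1))

    @pytest.mark.parametrize(
        "event_day,lookback,expected",
        [
            (date(2020, 2, 29), 90, True),  # day before as_of
            (date(2020, 3, 1), 90, False),  # the as_of day itself is excluded
            (date(2019, 12, 2), 90, True),  # exactly lookback days before: closed bound
            (date(2019, 12, 1), 90, False),  # one day beyond the window
        ],
    )
    def test_prescription_window_is_half_open(self, codelists, event_day, lookback, expected):
        meds = pd.DataFrame({"patient_id": [1], "date": [pd.Timestamp(event_day)], "code": ["M0101"]})
        assert on_medication(meds, 1, codelists["oral_nsaid"], AS_OF, lookback) is expected

    def test_history_is_strictly_before_as_of(self, codelists):
        clin = pd.DataFrame({"patient_id": [1], "date": [pd.Timestamp(AS_OF)], "code": ["C0101"]})
        assert has_history(clin, 1, codelists["peptic_ulcer"], AS_OF) is False
        clin_old = pd.DataFrame({"patient_id": [1], "date": [pd.Timestamp(date(2015, 3, 1))], "code": ["C0101"]})
        assert has_history(clin_old, 1, codelists["peptic_ulcer"], AS_OF) is True

    @pytest.mark.parametrize(
        "event_days,min_months,expected",
        [
            ([date(2019, 10, 1), date(2020, 2, 1)], 3, True),  # current and long-standing
            ([date(2020, 2, 1)], 3, False),  # recent starter, not established
            ([date(2019, 11, 1)], 3, False),  # established but no current script
            ([date(2019, 12, 1), date(2020, 2, 1)], 3, True),  # earliest exactly 3 months before
        ],
    )
    def test_established_treatment_needs_current_and_earliest(self, codelists, event_days, min_months, expected):
        meds = pd.DataFrame(
            {"patient_id": 1, "date": pd.to_datetime(event_days), "code": "M0701"}
        )
        got = established_treatment(meds, 1, codelists["methotrexate"], AS_OF, min_months)
        assert got is expected

    @pytest.mark.parametrize(
        "test_day,window,expected",
        [
            (date(2020, 2, 20), 3, True),
            (date(2019, 11, 22), 3, False),  # 100 days ago, outside 3 calendar months
            (date(2019, 12, 1), 3, True),  # exactly window months before: closed bound
            (date(2020, 3, 1), 3, False),  # as_of excluded
        ],
    )
    def test_monitoring_window_uses_calendar_months(self, codelists, test_day, window, expected):
        tests = pd.DataFrame(
            {"patient_id": [1], "date": [pd.Timestamp(test_day)], "code": ["T0501"], "value": [None], "comparator": [None]}
        )
        assert has_recent_test(tests, 1, codelists["lithium_level"], AS_OF, window) is expected


class TestThresholdResolution:
    @pytest.mark.parametrize(
        "value,comparator,expected",
        [
            (30, "gt", "ambiguous"),  # ">30" says nothing about <45
            (30, "lt", "satisfied"),
            (50, "eq", "not_satisfied"),
            (50, "gt", "not_satisfied"),
            (44.9, "eq", "satisfied"),
            (45, "eq", "not_satisfied"),
            (45, "lt", "satisfied"),
            (45, "le", "ambiguous"),
            (44, "ge", "ambiguous"),
            (45, "ge", "not_satisfied"),
            (50, "le", "ambiguous"),
            (30, None, "satisfied"),  # missing comparator read as equality
        ],
    )
    def test_comparator_coded_results(self, value, comparator, expected):
        assert pi.resolve_threshold(value, comparator, 45.0) == expected


class TestIndicatorRules:
    def test_nsaid_without_gastroprotection_flags_elderly(self, definitions):
        ds = make_dataset(
            patients=[(1, date(1950, 1, 1), "backend_a", 1)],
            medications=[(1, date(2020, 2, 20), "M0101")],
        )
        flags = pi.evaluate_indicator(ds, definitions["a_age65_nsaid"], AS_OF)
        assert flags.iloc[0]["in_denominator"] and flags.iloc[0]["in_numerator"]

    def test_gastroprotection_clears_the_numerator(self, definitions):
        ds = make_dataset(
            patients=[(1, date(1950, 1, 1), "backend_a", 1)],
            medications=[(1, date(2020, 2, 20), "M0101"), (1, date(2020, 1, 15), "M0201")],
        )
        flags = pi.evaluate_indicator(ds, definitions["a_age65_nsaid"], AS_OF)
        assert flags.iloc[0]["in_denominator"] and not flags.iloc[0]["in_numerator"]

    def test_methotrexate_monitoring_submeasures_are_independent(self, definitions):
        # established methotrexate, recent FBC but no LFT: safe on one
        # sub-measure, flagged on the other
        ds = make_dataset(
            patients=[(1, date(1960, 1, 1), "backend_a", 1)],
            medications=[(1, date(2019, 10, 5), "M0701"), (1, date(2020, 2, 10), "M0701")],
            test_results=[(1, date(2020, 1, 20), "T0301")],
        )
        k = pi.evaluate_indicator(ds, definitions["k_mtx_no_fbc"], AS_OF)
        l = pi.evaluate_indicator(ds, definitions["l_mtx_no_lft"], AS_OF)
        assert not k.iloc[0]["in_numerator"]
        assert l.iloc[0]["in_numerator"]

    def test_ambiguous_egfr_excluded_from_renal_denominator(self, definitions):
        ds = make_dataset(
            patients=[(1, date(1960, 1, 1), "backend_a", 1), (2, date(1960, 1, 1), "backend_a", 1)],
            medications=[(1, date(2020, 2, 20), "M0101"), (2, date(2020, 2, 20), "M0101")],
            test_results=[(1, date(2019, 6, 1), "T0101", 30.0, "gt"), (2, date(2019, 6, 1), "T0101", 30.0, "eq")],
        )
        flags = pi.evaluate_indicator(ds, definitions["i_crf_nsaid"], AS_OF)
        assert flags["patient_id"].tolist() == [2]
        assert flags.iloc[0]["in_numerator"]

    def test_latest_egfr_wins_over_older_results(self, definitions):
        ds = make_dataset(
            patients=[(1, date(1960, 1, 1), "backend_a", 1)],
            test_results=[
                (1, date(2019, 1, 1), "T0101", 30.0, "eq"),
                (1, date(2019, 12, 1), "T0101", 60.0, "eq"),
            ],
        )
        flags = pi.evaluate_indicator(ds, definitions["i_crf_nsaid"], AS_OF)
        assert len(flags) == 0  # latest value is 60: unambiguously not below 45

    def test_numeric_indicator_skipped_without_capability(self, definitions):
        ds = make_dataset(patients=[(1, date(1960, 1, 1), "backend_b", 9)])
        caps = pi.BackendCapabilities("backend_b", supports_numeric_comparators=False)
        assert pi.evaluate_indicator(ds, definitions["i_crf_nsaid"], AS_OF, caps) is None

    def test_open_ended_registration_includes_patient(self, definitions):
        ds = make_dataset(
            patients=[(1, date(1950, 1, 1), "backend_a", 1, {"registration_start": date(2019, 3, 1)})]
        )
        assert pi.base_population(ds, AS_OF) == {1}

    def test_base_population_exclusions(self, definitions):
        ds = make_dataset(
            patients=[
                (1, date(2002, 4, 1), "backend_a", 1),  # 17y11m: too young
                (2, date(1950, 1, 1), "backend_a", 1, {"date_of_death": date(2020, 2, 29)}),
                (3, date(1950, 1, 1), "backend_a", 1, {"registration_end": date(2020, 1, 1)}),
                (4, date(1950, 1, 1), "backend_a", 1),
            ]
        )
        assert pi.base_population(ds, AS_OF) == {4}


class TestEngineProperties:
    def test_numerator_is_subset_of_denominator(self, small_flags):
        assert (small_flags["in_numerator"] <= small_flags["in_denominator"]).all()

    def test_no_lookahead_under_truncation(self, definitions):
        """Evaluating at as_of must ignore events dated on/after as_of."""
        cfg = pi.GeneratorConfig(seed=7, n_practices_a=2, n_practices_b=2, patients_per_practice=25)
        ds = add_noise_events(pi.generate(cfg), seed=7)
        as_of = date(2020, 7, 1)
        truncated = ds.truncate_before(as_of)
        for key in pi.INDICATOR_KEYS:
            full = pi.evaluate_indicator(ds, definitions[key], as_of)
            cut = pi.evaluate_indicator(truncated, definitions[key], as_of)
            pd.testing.assert_frame_equal(full, cut)

    def test_removing_a_test_never_shrinks_monitoring_numerator(self, definitions):
        cfg = pi.GeneratorConfig(seed=11, n_practices_a=2, n_practices_b=2, patients_per_practice=30)
        ds = pi.generate(cfg)
        as_of = date(2021, 1, 1)
        thinned = pi.SyntheticEhr(
            patients=ds.patients,
            medications=ds.medications,
            clinical_events=ds.clinical_events,
            test_results=ds.test_results.iloc[::2].reset_index(drop=True),
            provenance=ds.provenance,
        )
        for key in pi.MONITORING_KEYS:
            before = pi.evaluate_indicator(ds, definitions[key], as_of)
            after = pi.evaluate_indicator(thinned, definitions[key], as_of)
            num_before = set(before.loc[before["in_numerator"], "patient_id"])
            num_after = set(after.loc[after["in_numerator"], "patient_id"])
            assert num_before <= num_after

    def test_matches_straight_line_oracle_on_one_fuzzed_dataset(self, definitions):
        cfg = pi.GeneratorConfig(seed=5, n_practices_a=1, n_practices_b=1, patients_per_practice=10)
        ds = add_noise_events(pi.generate(cfg), seed=5)
        for as_of in (date(2019, 9, 1), date(2020, 6, 1), date(2021, 9, 1)):
            for key in pi.INDICATOR_KEYS:
                got = pi.evaluate_indicator(ds, definitions[key], as_of)
                engine = dict(zip(got["patient_id"], got["in_numerator"]))
                expected = oracle.oracle_indicator(ds, key, as_of)
                assert engine == expected, (key, as_of)
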
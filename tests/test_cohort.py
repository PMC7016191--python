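"""Cohort construction: code mapping, chronicity, coexistence selection,
analysis age and censoring."""

from datetime import date

import pandas as pd
import pytest

from comorbnet.cohort import (
    compute_patient_age,
    filter_chronic,
    flag_complete_records,
    map_codes,
    select_multimorbid,
)
from comorbnet.errors import InputError

from .conftest import PERIOD, make_diagnoses, make_patients


class TestMapCodes:
    def test_maps_source_to_target(self, toy_catalog):
        events = make_diagnoses([("p1", "E11", "2010-01-01")])
        result = map_codes(events, toy_catalog)
        assert result.events["code"].tolist() == ["T90"]
        assert result.n_dropped == 0

    def test_native_codes_pass_through(self, toy_catalog):
        events = make_diagnoses([("p1", "T90", "2010-01-01"), ("p1", "K86", "2011-01-01")])
        result = map_codes(events, toy_catalog)
        assert result.events["code"].tolist() == ["T90", "K86"]

    def test_unmapped_codes_dropped_and_counted(self, toy_catalog):
        events = make_diagnoses(
            [("p1", "E11", "2010-01-01"), ("p1", "Z99", "2010-01-01"), ("p2", "Z99", "2012-05-05")]
        )
        result = map_codes(events, toy_catalog)
        assert result.n_dropped == 2
        assert result.dropped_codes == {"Z99": 2}
        assert len(result.events) == 1

    def test_ambiguous_mapping_without_priority_errors(self, toy_catalog):
        toy_catalog.mapping = pd.concat(
            [
                toy_catalog.mapping,
                pd.DataFrame([{"source_system": "ICD-10", "source_code": "E11",
                               "target_system": "ICPC-2", "target_code": "K86"}]),
            ],
            ignore_index=True,
        )
        events = make_diagnoses([("p1", "E11", "2010-01-01")])
        with pytest.raises(InputError, match="ambiguous"):
            map_codes(events, toy_catalog)

    def test_ambiguous_mapping_resolved_by_priority(self, toy_catalog):
        toy_catalog.mapping = pd.DataFrame(
            [
                {"source_system": "ICD-10", "source_code": "E11", "target_system": "ICPC-2",
                 "target_code": "K86", "priority": 2},
                {"source_system": "ICD-10", "source_code": "E11", "target_system": "ICPC-2",
                 "target_code": "T90", "priority": 1},
            ]
        )
        events = make_diagnoses([("p1", "E11", "2010-01-01")])
        assert map_codes(events, toy_catalog).events["code"].tolist() == ["T90"]


class TestFilterChronic:
    def test_only_chronic_codes_retained(self, toy_catalog):
        events = make_diagnoses(
            [("p1", "T90", "2010-01-01"), ("p1", "R74", "2010-02-01"), ("p2", "K86", "2011-01-01")]
        )
        out = filter_chronic(events, toy_catalog)
        assert sorted(out["code"]) == ["K86", "T90"]

    def test_empty_input(self, toy_catalog):
        out = filter_chronic(make_diagnoses([]).reindex(columns=["patient_id", "code", "diagnosis_date", "resolution_date"]), toy_catalog)
        assert out.empty


class TestSelectMultimorbid:
    def test_two_open_intervals_overlap_included(self):
        patients = make_patients([("p1", "F", "1950-06-01")])
        events = make_diagnoses([("p1", "T90", "2007-01-01"), ("p1", "K86", "2010-01-01")])
        cohort = select_multimorbid(patients, events, PERIOD)
        assert cohort.size == 1

    def test_single_condition_excluded(self):
        patients = make_patients([("p1", "F", "1950-06-01")])
        events = make_diagnoses([("p1", "T90", "2007-01-01")])
        assert select_multimorbid(patients, events, PERIOD).size == 0

    def test_non_overlapping_intervals_strict_vs_lenient(self):
        # A resolved in 2008, B diagnosed 2012: never simultaneously active
        patients = make_patients([("p1", "F", "1950-06-01")])
        events = make_diagnoses(
            [("p1", "T90", "2007-01-01", "2008-01-01"), ("p1", "K86", "2012-01-01")]
        )
        assert select_multimorbid(patients, events, PERIOD, coexistence="strict").size == 0
        assert select_multimorbid(patients, events, PERIOD, coexistence="lenient").size == 1

    def test_events_truncated_at_death(self):
        patients = make_patients([("p1", "F", "1950-06-01", "2010-01-01")])
        events = make_diagnoses(
            [
                ("p1", "T90", "2007-01-01"),
                ("p1", "K86", "2008-01-01"),
                ("p1", "F83", "2011-01-01"),  # recorded after death: dropped
            ]
        )
        cohort = select_multimorbid(patients, events, PERIOD)
        assert cohort.size == 1
        assert sorted(cohort.events["code"]) == ["K86", "T90"]
        end = cohort.patients.set_index("patient_id")["end_date"]
        joined = cohort.events.join(end, on="patient_id")
        assert (joined["diagnosis_date"] <= joined["end_date"]).all()

    def test_duplicate_code_does_not_count_as_two_conditions(self):
        patients = make_patients([("p1", "F", "1950-06-01")])
        events = make_diagnoses([("p1", "T90", "2007-01-01"), ("p1", "T90", "2012-01-01")])
        assert select_multimorbid(patients, events, PERIOD).size == 0

    def test_period_outside_all_data_gives_empty_cohort(self):
        patients = make_patients([("p1", "F", "1950-06-01")])
        events = make_diagnoses([("p1", "T90", "2007-01-01", "2008-01-01")])
        cohort = select_multimorbid(patients, events, (date(2020, 1, 1), date(2021, 1, 1)))
        assert cohort.size == 0

    def test_idempotent_on_own_output(self, small_default_cohort):
        config, patients, diagnoses, _ = small_default_cohort
        cohort = select_multimorbid(patients, diagnoses, config.study_period)
        again = select_multimorbid(cohort.patients, cohort.events, config.study_period)
        assert sorted(again.patients["patient_id"]) == sorted(cohort.patients["patient_id"])
        assert len(again.events) == len(cohort.events)

    def test_matches_brute_force_on_default_generator_output(self, small_default_cohort):
        """Without resolution dates, strict coexistence reduces to >=2
        distinct chronic codes diagnosed before death, so the cohort size
        equals a direct enumeration."""
        config, patients, diagnoses, _ = small_default_cohort
        cohort = select_multimorbid(patients, diagnoses, config.study_period)
        end = patients.set_index("patient_id")["end_date"]
        ev = diagnoses.join(end, on="patient_id")
        ev = ev[ev["end_date"].isna() | (ev["diagnosis_date"] <= ev["end_date"])]
        counts = ev.groupby("patient_id")["code"].nunique()
        eligible = set(counts[counts >= 2].index)
        ages = compute_patient_age(
            patients[patients["patient_id"].isin(eligible)],
            ev[ev["patient_id"].isin(eligible)],
            config.study_period,
        )
        expected = int((ages >= 18).sum())
        assert cohort.size == expected


class TestPatientAge:
    def test_mean_of_first_and_last_diagnosis_ages(self):
        patients = make_patients([("p1", "F", "1960-01-01")])
        events = make_diagnoses([("p1", "T90", "2006-01-01"), ("p1", "K86", "2016-01-01")])
        age = compute_patient_age(patients, events, PERIOD)
        assert age["p1"] == pytest.approx(51.0, abs=0.02)

    def test_single_diagnosis_is_its_own_mean(self):
        patients = make_patients([("p1", "F", "1960-01-01")])
        events = make_diagnoses([("p1", "T90", "2010-01-01")])
        age = compute_patient_age(patients, events, PERIOD)
        assert age["p1"] == pytest.approx(50.0, abs=0.02)

    def test_no_in_period_diagnosis_uses_period_midpoint(self):
        patients = make_patients([("p1", "F", "1960-01-01")])
        events = make_diagnoses([("p1", "T90", "2000-01-01")])
        age = compute_patient_age(patients, events, PERIOD)
        midpoint = pd.Timestamp("2006-01-01") + (pd.Timestamp("2017-12-31") - pd.Timestamp("2006-01-01")) / 2
        expected = (midpoint - pd.Timestamp("1960-01-01")).days / 365.25
        assert age["p1"] == pytest.approx(expected, abs=1e-9)

    def test_birth_after_period_end_errors(self):
        patients = make_patients([("p1", "F", "2030-01-01")])
        with pytest.raises(InputError):
            compute_patient_age(patients, make_diagnoses([]), PERIOD)


class TestCompleteRecords:
    def test_all_four_covariates_present_flags_true(self):
        pats = make_patients([("p1", "F", "1960-01-01"), ("p2", "M", "1955-01-01")])
        pats["tobacco"] = ["never", None]
        pats["alcohol"] = ["no", "yes"]
        pats["weight"] = [70.0, 80.0]
        pats["height"] = [165.0, 180.0]
        flagged = flag_complete_records(pats)
        assert flagged["covariates_complete"].tolist() == [True, False]

    def test_synthetic_missing_fraction(self, small_default_cohort):
        _, patients, _, _ = small_default_cohort  # missing fraction 0.30
        flagged = flag_complete_records(patients)
        assert flagged["covariates_complete"].mean() == pytest.approx(0.7, abs=0.03)
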
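"""The case definition: rule clauses, gates, and batch/oracle agreement."""

import numpy as np
import pandas as pd
import pytest

from adhd_emr.case_finder import (
    CaseDefinitionConfig,
    MissingBirthYearError,
    classify_patient,
    find_cases,
    qualifying_visit_days,
)
from conftest import build_dataset, oracle_is_case, random_small_dataset

CFG = CaseDefinitionConfig()


def _one_patient(birth_year=2000, coded_days=(), med_dates=(), extra_dx=(), in_person=True):
    """Patient p1 with in-person encounters on coded_days carrying a 314 code."""
    encounters, diagnoses, prescriptions = [], [], []
    for j, (day, code) in enumerate(coded_days):
        encounters.append(
            {"encounter_id": f"e{j}", "patient_id": "p1", "date": day, "in_person": in_person}
        )
        diagnoses.append(
            {"patient_id": "p1", "encounter_id": f"e{j}", "date": day, "code": code}
        )
    for code, day in extra_dx:
        diagnoses.append({"patient_id": "p1", "date": day, "code": code,
                          "source": "health_condition"})
    for day in med_dates:
        prescriptions.append({"patient_id": "p1", "date": day, "drug_identifier": "METHYLPHENIDATE"})
    return build_dataset(
        [{"patient_id": "p1", "birth_year": birth_year}], encounters, diagnoses, prescriptions
    )


class TestQualifyingVisitDays:
    def test_same_day_codes_collapse_to_one(self):
        ds = _one_patient(coded_days=[("2010-01-05", "314"), ("2010-01-05", "314.01")])
        assert len(qualifying_visit_days("p1", ds, CFG)) == 1

    def test_distinct_days_count_separately(self):
        ds = _one_patient(coded_days=[("2010-01-05", "314.0"), ("2010-03-02", "314")])
        assert len(qualifying_visit_days("p1", ds, CFG)) == 2

    def test_prefix_mismatch_gives_empty_set(self):
        ds = _one_patient(coded_days=[("2010-01-05", "315.1")])
        assert qualifying_visit_days("p1", ds, CFG) == set()

    def test_virtual_visits_do_not_qualify(self):
        ds = _one_patient(coded_days=[("2010-01-05", "314"), ("2010-02-05", "314")],
                          in_person=False)
        assert qualifying_visit_days("p1", ds, CFG) == set()


class TestClassifyPatient:
    def test_one_visit_plus_medication_qualifies(self):
        ds = _one_patient(birth_year=2000, coded_days=[("2010-06-01", "314")],
                          med_dates=["2010-06-15"])
        call = classify_patient("p1", ds, CFG, as_of_year=2010)
        assert call.is_case and call.qualifying_rule == "code_plus_medication"

    def test_two_visits_without_medication_qualifies(self):
        ds = _one_patient(birth_year=1980,
                          coded_days=[("2010-06-01", "314"), ("2011-02-01", "314.01")])
        call = classify_patient("p1", ds, CFG, as_of_year=2011)
        assert call.is_case and call.qualifying_rule == "code_twice"

    def test_age_gate_blocks_three_year_old(self):
        ds = _one_patient(birth_year=2008, coded_days=[("2011-06-01", "314"), ("2011-07-01", "314")],
                          med_dates=["2011-06-15"])
        assert not classify_patient("p1", ds, CFG, as_of_year=2011).is_case

    def test_single_ruleout_visit_does_not_qualify(self):
        ds = _one_patient(coded_days=[("2010-06-01", "314")])
        call = classify_patient("p1", ds, CFG, as_of_year=2010)
        assert not call.is_case and call.qualifying_rule == "none"

    def test_exclusion_code_blocks_and_is_reported(self):
        ds = _one_patient(coded_days=[("2010-06-01", "314"), ("2010-08-01", "314")],
                          extra_dx=[("299.0", "2009-01-01")])
        call = classify_patient("p1", ds, CFG, as_of_year=2010)
        assert not call.is_case and call.excluded_by == "299.0"

    def test_events_after_study_year_ignored(self):
        ds = _one_patient(coded_days=[("2010-06-01", "314"), ("2012-02-01", "314")])
        assert not classify_patient("p1", ds, CFG, as_of_year=2011).is_case
        assert classify_patient("p1", ds, CFG, as_of_year=2012).is_case

    def test_atc_prefix_matches_medication_clause(self):
        ds = _one_patient(coded_days=[("2010-06-01", "314")])
        ds.prescriptions = build_dataset(
            [{"patient_id": "p1"}],
            prescriptions=[{"patient_id": "p1", "date": "2010-07-01", "drug_identifier": "N06BA04"}],
        ).prescriptions
        assert classify_patient("p1", ds, CFG, as_of_year=2010).is_case

    def test_missing_birth_year_is_an_error(self):
        ds = _one_patient(birth_year=None, coded_days=[("2010-06-01", "314")])
        with pytest.raises(MissingBirthYearError):
            classify_patient("p1", ds, CFG, as_of_year=2010)


class TestFindCases:
    def test_empty_dataset_gives_empty_result(self):
        assert len(find_cases(build_dataset(), CFG, 2010)) == 0

    def test_missing_birth_year_flagged_not_fatal(self):
        ds = build_dataset([{"patient_id": "p1", "birth_year": None}, {"patient_id": "p2"}])
        out = find_cases(ds, CFG, 2010)
        assert out.set_index("patient_id").loc["p1", "error"] == "missing_birth_year"
        assert out.set_index("patient_id").loc["p2", "error"] is None

    @pytest.mark.parametrize("seed", range(12))
    def test_batch_equals_per_patient_reference(self, seed):
        ds = random_small_dataset(np.random.default_rng(seed), n_patients=12)
        batch = find_cases(ds, CFG, as_of_year=2015).set_index("patient_id")
        for pid in ds.patients["patient_id"]:
            if batch.loc[pid, "error"] is not None:
                with pytest.raises(MissingBirthYearError):
                    classify_patient(pid, ds, CFG, 2015)
                continue
            call = classify_patient(pid, ds, CFG, 2015)
            assert call.is_case == batch.loc[pid, "is_case"]
            assert call.qualifying_rule == batch.loc[pid, "qualifying_rule"]

    @pytest.mark.parametrize("seed", range(12))
    def test_batch_equals_independent_bruteforce_oracle(self, seed):
        ds = random_small_dataset(np.random.default_rng(1000 + seed), n_patients=12)
        batch = find_cases(ds, CFG, as_of_year=2015).set_index("patient_id")
        for pid in ds.patients["patient_id"]:
            expected = oracle_is_case(pid, ds, 2015)
            if expected is None:
                assert batch.loc[pid, "error"] == "missing_birth_year"
            else:
                assert bool(batch.loc[pid, "is_case"]) == expected, pid


class TestInvariants:
    def test_monotone_in_added_evidence(self):
        """Extra coded visits or prescriptions never un-flag a case."""
        rng = np.random.default_rng(7)
        for trial in range(25):
            ds = random_small_dataset(rng, n_patients=6)
            before = find_cases(ds, CFG, 2015).set_index("patient_id")
            pid = str(rng.choice(ds.patients["patient_id"]))
            day = pd.Timestamp("2015-06-01") + pd.Timedelta(days=int(rng.integers(0, 60)))
            if rng.random() < 0.5:
                new_enc = pd.DataFrame(
                    [{"encounter_id": "extra_e", "patient_id": pid, "date": day, "in_person": True}]
                )
                new_dx = pd.DataFrame(
                    [{"patient_id": pid, "encounter_id": "extra_e", "date": day,
                      "code": "314", "code_system": "ICD9", "source": "billing"}]
                )
                ds.encounters = pd.concat([ds.encounters, new_enc], ignore_index=True)
                ds.diagnoses = pd.concat([ds.diagnoses, new_dx], ignore_index=True)
            else:
                new_rx = pd.DataFrame(
                    [{"patient_id": pid, "date": day,
                      "drug_identifier": "METHYLPHENIDATE", "drug_class": ""}]
                )
                ds.prescriptions = pd.concat([ds.prescriptions, new_rx], ignore_index=True)
            after = find_cases(ds, CFG, 2015).set_index("patient_id")
            was = before[before["error"].isna() & before["excluded_by"].isna()]
            for q in was.index:
                if before.loc[q, "is_case"] and after.loc[q, "excluded_by"] is None:
                    assert after.loc[q, "is_case"]

    def test_temporal_consistency_absent_exclusions(self):
        """Once a case, always a case in later years (records only accrue)."""
        rng = np.random.default_rng(11)
        for trial in range(10):
            ds = random_small_dataset(rng, n_patients=8)
            ds.diagnoses = ds.diagnoses[~ds.diagnoses["code"].str.startswith("299")].reset_index(drop=True)
            flagged_2014 = find_cases(ds, CFG, 2014)
            flagged_2015 = find_cases(ds, CFG, 2015).set_index("patient_id")
            for _, row in flagged_2014.iterrows():
                if row["is_case"]:
                    assert flagged_2015.loc[row["patient_id"], "is_case"]
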
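"""Shared fixtures and builders for the test suite.

``build_dataset`` constructs a canonical in-memory Dataset from terse row
dicts so unit tests can state clinical scenarios in a few lines. The
engineered validation clinic is session-scoped because several test modules
reuse it and it takes a couple of seconds to build.
"""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import settings

from adhd_emr.store import Dataset, empty_dataset

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def build_dataset(patients=(), encounters=(), diagnoses=(), prescriptions=()) -> Dataset:
    """Dataset from lists of partial row dicts; missing fields get defaults."""
    base = empty_dataset()

    def rows(items, defaults, date_cols):
        if not items:
            return None
        out = pd.DataFrame([{**defaults, **item} for item in items])
        for c in date_cols:
            out[c] = pd.to_datetime(out[c])
        return out

    pat = rows(patients, {"birth_year": 2000, "gender": "M", "site_id": "S1"}, [])
    if pat is not None:
        pat["birth_year"] = pat["birth_year"].astype("Int64")
        base.patients = pat[base.patients.columns]
    enc = rows(encounters, {"in_person": True}, ["date"])
    if enc is not None:
        base.encounters = enc[base.encounters.columns]
    dx = rows(
        diagnoses,
        {"encounter_id": "", "code_system": "ICD9", "source": "encounter_diagnosis"},
        ["date"],
    )
    if dx is not None:
        base.diagnoses = dx[base.diagnoses.columns]
    rx = rows(prescriptions, {"drug_class": ""}, ["date"])
    if rx is not None:
        base.prescriptions = rx[base.prescriptions.columns]
    return base


@pytest.fixture(scope="session")
def validation_fixture():
    from adhd_emr.synth import make_validation_fixture

    return make_validation_fixture()


# ---------------------------------------------------------------------------
# independent brute-force oracle for the case definition, written from the
# clinical rules alone (no package helpers): used to check both code paths


def oracle_is_case(patient_id, ds, as_of_year, *,
                   min_age=4, prefix="314",
                   exclusions=("290", "295", "299", "317", "318", "319"),
                   med_names=("METHYLPHENIDATE", "DEXMETHYLPHENIDATE", "AMPHETAMINE",
                              "DEXTROAMPHETAMINE", "MIXED AMPHETAMINE SALTS",
                              "LISDEXAMFETAMINE", "ATOMOXETINE", "GUANFACINE XR"),
                   atc_prefix="N06BA"):
    """True/False/None (None = not classifiable: no year of birth)."""
    cutoff = pd.Timestamp(as_of_year, 12, 31)
    prow = ds.patients[ds.patients.patient_id == patient_id].iloc[0]
    if pd.isna(prow.birth_year):
        return None
    if as_of_year - int(prow.birth_year) < min_age:
        return False

    dx = [r for _, r in ds.diagnoses.iterrows()
          if r.patient_id == patient_id and r.date <= cutoff]
    if any(r.code.startswith(e) for r in dx for e in exclusions):
        return False

    in_person_enc = {r.encounter_id: r for _, r in ds.encounters.iterrows()
                     if r.patient_id == patient_id and r.in_person}
    in_person_dates = {r.date for r in in_person_enc.values()}
    days = set()
    for r in dx:
        if not r.code.startswith(prefix):
            continue
        if (r.encounter_id and r.encounter_id in in_person_enc) or r.date in in_person_dates:
            days.add(r.date)

    has_med = any(
        r.patient_id == patient_id and r.date <= cutoff
        and (r.drug_identifier.strip().upper().startswith(atc_prefix)
             or r.drug_identifier.strip().upper() in med_names)
        for _, r in ds.prescriptions.iterrows()
    )
    return (len(days) >= 1 and has_med) or len(days) >= 2


def random_small_dataset(rng, n_patients=10):
    """Adversarial small dataset: mixed codes, linkage styles, missing data."""
    codes = ["314", "314.0", "314.01", "315.1", "299.0", "296.2", "31"]
    drugs = ["METHYLPHENIDATE", "N06BA04", "IBUPROFEN", "atomoxetine", "GUANFACINE XR"]
    dates = pd.date_range("2013-01-01", "2015-12-31", freq="D")

    patients, encounters, diagnoses, prescriptions = [], [], [], []
    eid = 0
    for i in range(n_patients):
        pid = f"p{i}"
        patients.append(
            {
                "patient_id": pid,
                "birth_year": None if rng.random() < 0.1 else int(rng.integers(1950, 2014)),
                "gender": rng.choice(["M", "F", ""]),
            }
        )
        my_encs = []
        for _ in range(int(rng.integers(0, 5))):
            e = {"encounter_id": f"e{eid}", "patient_id": pid,
                 "date": dates[rng.integers(len(dates))],
                 "in_person": bool(rng.random() < 0.7)}
            encounters.append(e)
            my_encs.append(e)
            eid += 1
        for _ in range(int(rng.integers(0, 4))):
            linked = my_encs and rng.random() < 0.5
            enc = my_encs[rng.integers(len(my_encs))] if linked else None
            diagnoses.append(
                {
                    "patient_id": pid,
                    "encounter_id": enc["encounter_id"] if linked else "",
                    "date": enc["date"] if linked else dates[rng.integers(len(dates))],
                    "code": codes[rng.integers(len(codes))],
                    "source": rng.choice(["encounter_diagnosis", "billing"]),
                }
            )
        for _ in range(int(rng.integers(0, 3))):
            prescriptions.append(
                {
                    "patient_id": pid,
                    "date": dates[rng.integers(len(dates))],
                    "drug_identifier": drugs[rng.integers(len(drugs))],
                }
            )
    ds = build_dataset(patients, encounters, diagnoses, prescriptions)
    # normalise codes/identifiers the way the reader would
    ds.diagnoses["code"] = ds.diagnoses["code"].str.strip().str.upper()
    return ds
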
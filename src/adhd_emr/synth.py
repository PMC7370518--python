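"""Seeded generator of synthetic primary-care EMR datasets with known truth.

Real CPCSSN-style extracts are access-restricted, so every downstream stage
is exercised on synthetic data that emulates the structural features the
case-finding problem depends on:

* patients with year of birth and gender, a small fraction carrying
  invalid/missing demographics;
* a yearly encounter stream (Poisson per active patient-year) over a random
  roster period, so two-year contact denominators are non-trivial;
* ICD-9 314-family diagnosis codes attached to in-person encounters through
  either the encounter-diagnosis or the billing source;
* ADHD-related prescriptions;
* exclusionary-condition codes;
* and the two misclassification mechanisms chart reviews of such algorithms
  document: true cases managed by a specialist with no structured ADHD
  footprint in the primary-care record (missed cases), and rule-out
  evaluations coded 314 once without a subsequent diagnosis or treatment
  plan.

Ground truth (who truly has ADHD, and through which mechanism their record
arose) is returned alongside the dataset, which is what makes parameter
recovery and confusion-matrix closure testable.

The generator does not model comorbidity structure, free-text notes, or
realistic dosing; see the methods note for what that implies about test
conclusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .case_finder import CaseDefinitionConfig, find_cases
from .store import Dataset
from .validity import ConfusionCounts

ADHD_CODES = ("314", "314.0", "314.00", "314.01", "314.1", "314.2", "314.8", "314.9")

ADHD_MEDS = (
    "METHYLPHENIDATE",
    "LISDEXAMFETAMINE",
    "MIXED AMPHETAMINE SALTS",
    "ATOMOXETINE",
    "GUANFACINE XR",
)

EXCLUSION_CODES = ("290.0", "295.1", "299.0", "317", "318.0", "319")

#: age-structure weights at the reference year (primary-care roster style:
#: adult-heavy, with a small under-4 and senior tail)
AGE_BANDS = (((0, 3), 0.04), ((4, 17), 0.17), ((18, 34), 0.24), ((35, 64), 0.47), ((65, 80), 0.08))

#: default true ADHD prevalence by (age group, gender); levels and the
#: male:female gradient (≈1.4:1 in children shrinking with age) are
#: illustrative of primary-care ADHD epidemiology
DEFAULT_PREVALENCE: Mapping[tuple[str, str], float] = {
    ("4-17", "M"): 0.095,
    ("4-17", "F"): 0.070,
    ("18-34", "M"): 0.075,
    ("18-34", "F"): 0.062,
    ("35-64", "M"): 0.055,
    ("35-64", "F"): 0.051,
}

MECHANISMS = (
    "typical_case",
    "specialist_managed_case",
    "non_case",
    "ruleout_non_case",
    "excluded_condition",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic population; defaults are the study conditions.

    ``p_specialist_managed`` defaults to 9/245, the missed-case fraction a
    246+246 chart review of this algorithm family exhibits; the other base
    rates have no published population-level counterpart and are set to
    plausible primary-care magnitudes (documented in the methods note).
    """

    n_patients: int = 20_000
    year_range: tuple[int, int] = (2008, 2015)
    true_prevalence_by_stratum: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    encounter_rate: float = 3.0
    p_specialist_managed: float = 9 / 245
    p_ruleout_coded: float = 0.01
    p_invalid_demographics: float = 0.01
    p_exclusion_condition: float = 0.005
    p_male: float = 0.43
    p_in_person: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be well-ordered")
        for name in (
            "p_specialist_managed", "p_ruleout_coded", "p_invalid_demographics",
            "p_exclusion_condition", "p_male", "p_in_person",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if any(not 0 <= v <= 1 for v in self.true_prevalence_by_stratum.values()):
            raise ValueError("prevalences must lie in [0, 1]")


def _dates_from_year_day(years: np.ndarray, days: np.ndarray) -> np.ndarray:
    """Vectorised (year, day-of-year offset 0..364) -> datetime64[D]."""
    return (years - 1970).astype("datetime64[Y]").astype("datetime64[D]") + days


def _age_group(age: int) -> str | None:
    for lo, hi in ((4, 17), (18, 34), (35, 64)):
        if lo <= age <= hi:
            return f"{lo}-{hi}"
    return None


def generate(config: GeneratorConfig) -> tuple[Dataset, pd.DataFrame]:
    """Generate a synthetic Dataset plus its ground-truth table.

    Deterministic given ``config.seed``. The ground truth has one row per
    patient with ``patient_id``, ``is_true_case``, ``mechanism`` and the
    stratum assignment used at generation time.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    first_year, last_year = cfg.year_range
    ref_year = last_year

    pid = np.array([f"P{i:07d}" for i in range(n)])

    # demographics
    bands = np.array([b for b, _ in AGE_BANDS], dtype=object)
    weights = np.array([w for _, w in AGE_BANDS])
    band_idx = rng.choice(len(bands), size=n, p=weights / weights.sum())
    lo = np.array([AGE_BANDS[i][0][0] for i in band_idx])
    hi = np.array([AGE_BANDS[i][0][1] for i in band_idx])
    age = rng.integers(lo, hi + 1)
    birth_year = ref_year - age
    gender = np.where(rng.random(n) < cfg.p_male, "M", "F")

    # ground-truth case status by stratum at the reference year
    group = np.array([_age_group(a) or "" for a in age], dtype=object)
    prev = np.zeros(n)
    for (g, sex), p in cfg.true_prevalence_by_stratum.items():
        prev[(group == g) & (gender == sex)] = p
    is_case = rng.random(n) < prev

    mech = np.full(n, "non_case", dtype=object)
    specialist = is_case & (rng.random(n) < cfg.p_specialist_managed)
    mech[is_case] = "typical_case"
    mech[specialist] = "specialist_managed_case"
    ruleout = ~is_case & (rng.random(n) < cfg.p_ruleout_coded)
    mech[ruleout] = "ruleout_non_case"
    has_exclusion = rng.random(n) < cfg.p_exclusion_condition
    mech[~is_case & ~ruleout & has_exclusion] = "excluded_condition"

    # roster period: active from a uniform start year through the last year
    start_year = rng.integers(first_year, last_year + 1, size=n)
    n_active = last_year - start_year + 1

    # base encounter stream: Poisson(encounter_rate) per active patient-year
    py_patient = np.repeat(np.arange(n), n_active)
    py_year = np.concatenate([np.arange(s, last_year + 1) for s in start_year]) if n else np.array([], dtype=int)
    counts = rng.poisson(cfg.encounter_rate, size=py_patient.size)
    enc_patient = np.repeat(py_patient, counts)
    enc_year = np.repeat(py_year, counts)
    enc_day = rng.integers(0, 365, size=enc_patient.size)
    enc_dates = _dates_from_year_day(enc_year, enc_day)
    enc_in_person = rng.random(enc_patient.size) < cfg.p_in_person

    encounters = {
        "patient_id": list(pid[enc_patient]),
        "date": list(enc_dates),
        "in_person": list(enc_in_person),
    }
    dx_rows: list[tuple] = []  # (patient, encounter_idx or -1, date, code, source)
    rx_rows: list[tuple] = []  # (patient, date, drug)

    def _add_encounter(patient_i: int, date: np.datetime64, in_person: bool) -> int:
        encounters["patient_id"].append(pid[patient_i])
        encounters["date"].append(date)
        encounters["in_person"].append(in_person)
        return len(encounters["patient_id"]) - 1

    def _coded_days(i: int, k: int) -> np.ndarray:
        """k distinct calendar dates within patient i's active period."""
        span = int(n_active[i]) * 365
        offs = rng.choice(span, size=min(k, span), replace=False)
        years = start_year[i] + offs // 365
        return _dates_from_year_day(years, offs % 365)

    def _plant_adhd_visits(i: int, k_days: int, with_med: bool) -> None:
        dates = np.sort(_coded_days(i, k_days))
        for d in dates:
            idx = _add_encounter(i, d, True)
            code = ADHD_CODES[rng.integers(len(ADHD_CODES))]
            source = "billing" if rng.random() < 0.5 else "encounter_diagnosis"
            dx_rows.append((pid[i], idx, d, code, source))
        if with_med:
            # prescription must fall inside the study window to count in the
            # last study year
            horizon = np.datetime64(f"{last_year}-12-31")
            for _ in range(int(rng.integers(1, 3))):
                gap = int(rng.integers(0, 60))
                rx_rows.append((pid[i], min(dates[0] + gap, horizon), ADHD_MEDS[rng.integers(len(ADHD_MEDS))]))

    # typical cases leave a structured footprint; half qualify through the
    # medication clause, half through repeat coded visits
    for i in np.flatnonzero(is_case & ~specialist):
        if rng.random() < 0.5:
            _plant_adhd_visits(i, 1, with_med=True)
        else:
            _plant_adhd_visits(i, int(rng.integers(2, 5)), with_med=rng.random() < 0.3)

    # rule-out evaluations: exactly one coded visit, never a prescription
    for i in np.flatnonzero(ruleout):
        _plant_adhd_visits(i, 1, with_med=False)

    # exclusionary-condition codes ride on the health-condition table
    for i in np.flatnonzero(has_exclusion):
        d = _coded_days(i, 1)[0]
        dx_rows.append((pid[i], -1, d, EXCLUSION_CODES[rng.integers(len(EXCLUSION_CODES))], "health_condition"))

    # invalid demographics: missing year of birth or missing gender
    invalid = rng.random(n) < cfg.p_invalid_demographics
    drop_birth = invalid & (rng.random(n) < 0.5)
    drop_gender = invalid & ~drop_birth

    birth_year_col = pd.array(birth_year, dtype="Int64")
    birth_year_col[drop_birth] = pd.NA
    gender_col = gender.copy()
    gender_col[drop_gender] = ""

    n_enc = len(encounters["patient_id"])
    eid = np.array([f"E{i:08d}" for i in range(n_enc)])

    patients = pd.DataFrame(
        {"patient_id": pid, "birth_year": birth_year_col, "gender": gender_col, "site_id": "S01"}
    )
    enc_df = pd.DataFrame(
        {
            "encounter_id": eid,
            "patient_id": encounters["patient_id"],
            "date": pd.to_datetime(np.array(encounters["date"], dtype="datetime64[D]")),
            "in_person": np.array(encounters["in_person"], dtype=bool),
        }
    )
    from .store import empty_dataset

    if dx_rows:
        dx_df = pd.DataFrame(dx_rows, columns=["patient_id", "enc_idx", "date", "code", "source"])
        dx_df["encounter_id"] = np.where(dx_df["enc_idx"] >= 0, eid[dx_df["enc_idx"].clip(lower=0)], "")
        dx_df["date"] = pd.to_datetime(np.array(dx_df["date"], dtype="datetime64[D]"))
        dx_df["code_system"] = "ICD9"
        diagnoses = dx_df[["patient_id", "encounter_id", "date", "code", "code_system", "source"]]
    else:
        diagnoses = empty_dataset().diagnoses

    if rx_rows:
        rx_df = pd.DataFrame(rx_rows, columns=["patient_id", "date", "drug_identifier"])
        rx_df["date"] = pd.to_datetime(np.array(rx_df["date"], dtype="datetime64[D]"))
        rx_df["drug_class"] = "adhd_medication"
    else:
        rx_df = empty_dataset().prescriptions

    ds = Dataset(
        patients=patients,
        encounters=enc_df,
        diagnoses=diagnoses.reset_index(drop=True),
        prescriptions=rx_df.reset_index(drop=True),
        provenance={"generator": "synth.generate", "seed": cfg.seed, "n_patients": n},
    )
    truth = pd.DataFrame(
        {
            "patient_id": pid,
            "is_true_case": is_case,
            "mechanism": mech,
            "age_group": group,
            "gender": gender,
        }
    )
    return ds, truth


# ---------------------------------------------------------------------------
# engineered validation fixture


def make_validation_fixture(
    seed: int = 2468, case_cfg: CaseDefinitionConfig | None = None
) -> tuple[Dataset, pd.DataFrame, ConfusionCounts]:
    """A single synthetic clinic engineered to reproduce a canonical
    246-flagged / 246-sampled chart-review validation exactly.

    The clinic holds 19,683 patients. 236 true cases carry qualifying
    structured records (flagged true positives); 10 non-cases carry two
    314-coded billing visit days from rule-out evaluations (flagged false
    positives); 9 true cases are specialist-managed with no structured ADHD
    footprint (missed); decoys that satisfy the visit rules but fail the age
    gate or carry exclusion codes are planted to exercise every clause. The
    246-patient unflagged review sample is engineered to contain the 9 missed
    cases plus 237 sampled true non-cases, so the 2×2 is TP=236, FP=10,
    TN=237, FN=9.

    Returns (dataset, ground_truth, confusion) where the confusion counts are
    recomputed here by running the case finder, not hard-coded.
    """
    rng = np.random.default_rng(seed)
    cfg = case_cfg or CaseDefinitionConfig()
    as_of_year = 2015
    n_total = 19_683

    n_tp, n_fn, n_fp = 236, 9, 10
    n_underage, n_excl_decoy, n_single_ruleout = 6, 6, 150

    patients: list[dict] = []
    encounters: list[dict] = []
    diagnoses: list[dict] = []
    prescriptions: list[dict] = []
    truth_rows: list[dict] = []
    counter = {"e": 0}

    def _new_patient(age: int, gender: str) -> str:
        p = f"V{len(patients):06d}"
        patients.append(
            {"patient_id": p, "birth_year": as_of_year - age, "gender": gender, "site_id": "CLINIC1"}
        )
        return p

    def _enc(p: str, date, in_person: bool = True) -> str:
        e = f"VE{counter['e']:07d}"
        counter["e"] += 1
        encounters.append({"encounter_id": e, "patient_id": p, "date": date, "in_person": in_person})
        return e

    def _rand_date(year: int):
        return pd.Timestamp(year=year, month=1, day=1) + pd.Timedelta(days=int(rng.integers(0, 365)))

    def _base_visits(p: str) -> None:
        for _ in range(int(rng.integers(1, 3))):
            _enc(p, _rand_date(int(rng.integers(2014, 2016))))

    def _coded_visit(p: str, date, source: str) -> None:
        e = _enc(p, date)
        diagnoses.append(
            {
                "patient_id": p, "encounter_id": e, "date": date,
                "code": ADHD_CODES[int(rng.integers(len(ADHD_CODES)))],
                "code_system": "ICD9", "source": source,
            }
        )

    def _distinct_dates(k: int):
        offs = rng.choice(720, size=k, replace=False)
        return [pd.Timestamp("2014-01-01") + pd.Timedelta(days=int(o)) for o in offs]

    def _rand_age() -> int:
        return int(rng.integers(6, 60))

    def _rand_gender() -> str:
        return "M" if rng.random() < 0.6 else "F"

    # flagged true positives: half medication clause, half repeat visits
    for j in range(n_tp):
        p = _new_patient(_rand_age(), _rand_gender())
        _base_visits(p)
        if j % 2 == 0:
            (d,) = _distinct_dates(1)
            _coded_visit(p, d, "encounter_diagnosis")
            # the prescription must precede the study-year cutoff to count
            rx_date = min(d + pd.Timedelta(days=int(rng.integers(0, 30))),
                          pd.Timestamp(as_of_year, 12, 31))
            prescriptions.append(
                {
                    "patient_id": p, "date": rx_date,
                    "drug_identifier": ADHD_MEDS[int(rng.integers(len(ADHD_MEDS)))],
                    "drug_class": "adhd_medication",
                }
            )
        else:
            for d in _distinct_dates(int(rng.integers(2, 4))):
                _coded_visit(p, d, "billing" if rng.random() < 0.5 else "encounter_diagnosis")
        truth_rows.append({"patient_id": p, "is_true_case": True, "mechanism": "typical_case"})

    # missed true cases: specialist-managed, structured record is silent
    for _ in range(n_fn):
        p = _new_patient(_rand_age(), _rand_gender())
        _base_visits(p)
        truth_rows.append(
            {"patient_id": p, "is_true_case": True, "mechanism": "specialist_managed_case"}
        )

    # flagged false positives: intensive rule-out work-ups, billing-coded on
    # two days, no diagnosis or treatment plan followed
    for _ in range(n_fp):
        p = _new_patient(_rand_age(), _rand_gender())
        _base_visits(p)
        for d in _distinct_dates(2):
            _coded_visit(p, d, "billing")
        truth_rows.append({"patient_id": p, "is_true_case": False, "mechanism": "ruleout_non_case"})

    # decoys: would qualify on visits but the age gate blocks them
    for _ in range(n_underage):
        p = _new_patient(3, _rand_gender())
        for d in _distinct_dates(2):
            _coded_visit(p, d, "encounter_diagnosis")
        truth_rows.append({"patient_id": p, "is_true_case": False, "mechanism": "non_case"})

    # decoys: qualify on visits but carry an exclusionary-condition code
    for _ in range(n_excl_decoy):
        p = _new_patient(_rand_age(), _rand_gender())
        for d in _distinct_dates(2):
            _coded_visit(p, d, "encounter_diagnosis")
        diagnoses.append(
            {
                "patient_id": p, "encounter_id": "", "date": _rand_date(2014),
                "code": EXCLUSION_CODES[int(rng.integers(len(EXCLUSION_CODES)))],
                "code_system": "ICD9", "source": "health_condition",
            }
        )
        truth_rows.append({"patient_id": p, "is_true_case": False, "mechanism": "excluded_condition"})

    # single-visit rule-outs: one coded day never qualifies
    for _ in range(n_single_ruleout):
        p = _new_patient(_rand_age(), _rand_gender())
        _base_visits(p)
        (d,) = _distinct_dates(1)
        _coded_visit(p, d, "billing")
        truth_rows.append({"patient_id": p, "is_true_case": False, "mechanism": "ruleout_non_case"})

    # plain non-cases fill the clinic; vectorised for speed
    n_plain = n_total - len(patients)
    plain_ids = np.array([f"V{len(patients) + i:06d}" for i in range(n_plain)])
    plain_age = rng.integers(1, 81, size=n_plain)
    plain_gender = np.where(rng.random(n_plain) < 0.43, "M", "F")
    plain_year = rng.integers(2014, 2016, size=n_plain)
    plain_dates = _dates_from_year_day(plain_year, rng.integers(0, 365, size=n_plain))

    pat_df = pd.concat(
        [
            pd.DataFrame(patients),
            pd.DataFrame(
                {
                    "patient_id": plain_ids,
                    "birth_year": as_of_year - plain_age,
                    "gender": plain_gender,
                    "site_id": "CLINIC1",
                }
            ),
        ],
        ignore_index=True,
    )
    pat_df["birth_year"] = pat_df["birth_year"].astype("Int64")
    enc_df = pd.concat(
        [
            pd.DataFrame(encounters),
            pd.DataFrame(
                {
                    "encounter_id": [f"VP{i:07d}" for i in range(n_plain)],
                    "patient_id": plain_ids,
                    "date": pd.to_datetime(plain_dates),
                    "in_person": rng.random(n_plain) < 0.9,
                }
            ),
        ],
        ignore_index=True,
    )
    dx_df = pd.DataFrame(diagnoses)
    dx_df["date"] = pd.to_datetime(dx_df["date"])
    rx_df = pd.DataFrame(prescriptions)
    rx_df["date"] = pd.to_datetime(rx_df["date"])
    enc_df["date"] = pd.to_datetime(enc_df["date"])
    enc_df["in_person"] = enc_df["in_person"].astype(bool)

    truth = pd.concat(
        [
            pd.DataFrame(truth_rows),
            pd.DataFrame(
                {"patient_id": plain_ids, "is_true_case": False, "mechanism": "non_case"}
            ),
        ],
        ignore_index=True,
    )

    ds = Dataset(
        patients=pat_df,
        encounters=enc_df,
        diagnoses=dx_df.reset_index(drop=True),
        prescriptions=rx_df.reset_index(drop=True),
        provenance={"generator": "synth.make_validation_fixture", "seed": seed},
    )

    # recompute the 2x2 by actually running the case finder
    calls = find_cases(ds, cfg, as_of_year=as_of_year)
    flagged = set(calls.loc[calls["is_case"], "patient_id"])
    true_ids = set(truth.loc[truth["is_true_case"], "patient_id"])

    fn_ids = [r["patient_id"] for r in truth_rows if r["mechanism"] == "specialist_managed_case"]
    pool = np.sort(plain_ids)
    sampled_tn = rng.choice(pool, size=246 - len(fn_ids), replace=False)
    review_unflagged = set(fn_ids) | set(sampled_tn)
    review_ids = flagged | review_unflagged
    truth["in_review_sample"] = truth["patient_id"].isin(review_ids)

    tp = len(flagged & true_ids)
    fp = len(flagged - true_ids)
    tn = len(review_unflagged - true_ids)
    fn = len(review_unflagged & true_ids)
    counts = ConfusionCounts(
        tp=tp, fp=fp, tn=tn, fn=fn,
        clinic_total=n_total, clinic_flagged=len(flagged),
    )
    return ds, truth, counts


def no_misclassification(config: GeneratorConfig) -> GeneratorConfig:
    """Copy of ``config`` with both misclassification mechanisms switched off
    (and no exclusion codes), under which the case finder should be perfect."""
    return replace(
        config, p_specialist_managed=0.0, p_ruleout_coded=0.0, p_exclusion_condition=0.0
    )
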
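"""Yearly practice populations and age/gender strata.

The denominator for surveillance prevalence is the "two-year contact group":
for study year Y, every patient with at least one encounter dated in Y or
Y−1, restricted to patients with a valid year of birth and gender. Age is
year arithmetic (study year minus birth year) because the extract carries
year of birth only; boundary patients can shift by up to one year relative
to exact-birthdate ages.

Strata cover ages 4–17, 18–34 and 35–64. Children under four and seniors
(65+) appear in no stratum — ADHD is neither diagnosable by these rules
under age four nor prevalent enough in seniors to estimate usefully.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import pandas as pd

from .store import Dataset

AGE_GROUPS: dict[str, tuple[int, int]] = {
    "4-17": (4, 17),
    "18-34": (18, 34),
    "35-64": (35, 64),
}

GENDERS = ("M", "F", "all")


class StratumKey(NamedTuple):
    year: int
    age_group: str  # key of AGE_GROUPS
    gender: str  # "M", "F", or "all"


@dataclass(frozen=True)
class PracticePopulation:
    year: int
    member_ids: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.member_ids)


def practice_population(ds: Dataset, year: int) -> PracticePopulation:
    """Two-year contact group for ``year``: patients with an encounter in
    ``year`` or ``year - 1`` and valid demographics."""
    enc = ds.encounters
    years = enc["date"].dt.year
    contact_ids = set(enc.loc[(years == year) | (years == year - 1), "patient_id"])

    pat = ds.patients
    valid = pat["birth_year"].notna() & pat["gender"].isin(["M", "F"])
    members = set(pat.loc[valid, "patient_id"]) & contact_ids
    return PracticePopulation(year=year, member_ids=frozenset(members))


def age_in_year(birth_year: int, year: int) -> int:
    """Age from year arithmetic; raises for births after ``year``."""
    if birth_year > year:
        raise ValueError(f"birth_year {birth_year} is after study year {year}")
    return year - birth_year


def age_group_of(age: int) -> str | None:
    for name, (lo, hi) in AGE_GROUPS.items():
        if lo <= age <= hi:
            return name
    return None


def stratify(pop: PracticePopulation, ds: Dataset) -> dict[StratumKey, frozenset[str]]:
    """Partition a practice population into age-group × gender strata.

    Patients outside 4–64 in the study year appear in no stratum. Each
    "all"-gender stratum is the union of its gendered strata (membership
    requires valid gender, enforced upstream).
    """
    pat = ds.patients[ds.patients["patient_id"].isin(pop.member_ids)]
    age = pop.year - pat["birth_year"].astype(int)

    strata: dict[StratumKey, frozenset[str]] = {}
    for group, (lo, hi) in AGE_GROUPS.items():
        in_group = pat[(age >= lo) & (age <= hi)]
        for g in ("M", "F"):
            ids = frozenset(in_group.loc[in_group["gender"] == g, "patient_id"])
            strata[StratumKey(pop.year, group, g)] = ids
        strata[StratumKey(pop.year, group, "all")] = frozenset(in_group["patient_id"])
    return strata


def population_table(ds: Dataset, years: list[int]) -> pd.DataFrame:
    """Per-year denominator summary: population size, age-group and gender
    percentages (restricted to ages 4–64, mirroring surveillance reports)."""
    rows = []
    for year in years:
        pop = practice_population(ds, year)
        strata = stratify(pop, ds)
        eligible = sum(
            len(strata[StratumKey(year, g, "all")]) for g in AGE_GROUPS
        )
        row: dict = {"year": year, "n": eligible}
        for g in AGE_GROUPS:
            size = len(strata[StratumKey(year, g, "all")])
            row[f"pct_{g}"] = 100 * size / eligible if eligible else float("nan")
        n_male = sum(len(strata[StratumKey(year, g, "M")]) for g in AGE_GROUPS)
        row["pct_male"] = 100 * n_male / eligible if eligible else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
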
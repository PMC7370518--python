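"""Typed in-memory EMR tables with delimited-file I/O and schema validation.

The data model is a minimal abstraction of a primary-care EMR extract in the
style of the CPCSSN repository: four flat tables (patients, encounters,
diagnoses, prescriptions) linked by opaque string identifiers. Patients carry
a year of birth only; event tables carry full ISO dates. The on-disk format
is one UTF-8 CSV per table with a header row and empty string for missing.

The column dictionary ships with the package as ``schema.yaml``; readers
coerce and validate against it, rejecting rows that violate type constraints
(with counts reported in the dataset provenance) and refusing datasets that
break referential integrity.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

log = logging.getLogger(__name__)

TABLES = ("patients", "encounters", "diagnoses", "prescriptions")

#: plausible year-of-birth window used by default when reading
DEFAULT_BIRTH_YEAR_RANGE = (1900, _dt.date.today().year)


class SchemaError(ValueError):
    """A table file is missing, or lacks a required column."""


class ReferentialIntegrityError(ValueError):
    """An event row references a patient or encounter that does not exist."""


def load_schema() -> dict:
    """Return the packaged column dictionary as nested dicts."""
    text = resources.files("adhd_emr").joinpath("schema.yaml").read_text("utf-8")
    return yaml.safe_load(text)


@dataclass
class Dataset:
    """The four EMR tables plus free-form provenance metadata.

    Canonical in-memory dtypes: identifiers and codes are ``str`` (empty
    string = missing where nullable), ``birth_year`` is nullable ``Int64``,
    dates are ``datetime64[ns]``, ``in_person`` is ``bool``.
    """

    patients: pd.DataFrame
    encounters: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        if name not in TABLES:
            raise KeyError(name)
        return getattr(self, name)

    @property
    def sizes(self) -> dict[str, int]:
        return {name: len(self.table(name)) for name in TABLES}


def empty_dataset() -> Dataset:
    """A valid Dataset with zero rows and canonical dtypes."""
    return Dataset(
        patients=pd.DataFrame(
            {
                "patient_id": pd.Series(dtype="str"),
                "birth_year": pd.Series(dtype="Int64"),
                "gender": pd.Series(dtype="str"),
                "site_id": pd.Series(dtype="str"),
            }
        ),
        encounters=pd.DataFrame(
            {
                "encounter_id": pd.Series(dtype="str"),
                "patient_id": pd.Series(dtype="str"),
                "date": pd.Series(dtype="datetime64[ns]"),
                "in_person": pd.Series(dtype="bool"),
            }
        ),
        diagnoses=pd.DataFrame(
            {
                "patient_id": pd.Series(dtype="str"),
                "encounter_id": pd.Series(dtype="str"),
                "date": pd.Series(dtype="datetime64[ns]"),
                "code": pd.Series(dtype="str"),
                "code_system": pd.Series(dtype="str"),
                "source": pd.Series(dtype="str"),
            }
        ),
        prescriptions=pd.DataFrame(
            {
                "patient_id": pd.Series(dtype="str"),
                "date": pd.Series(dtype="datetime64[ns]"),
                "drug_identifier": pd.Series(dtype="str"),
                "drug_class": pd.Series(dtype="str"),
            }
        ),
    )


# ---------------------------------------------------------------------------
# validation

def validate_dataset(ds: Dataset) -> None:
    """Raise if ``ds`` violates uniqueness or referential integrity."""
    pat = ds.patients
    if pat["patient_id"].duplicated().any():
        dupes = pat.loc[pat["patient_id"].duplicated(), "patient_id"].tolist()
        raise ReferentialIntegrityError(f"duplicate patient_id values: {dupes[:5]}")
    if ds.encounters["encounter_id"].duplicated().any():
        raise ReferentialIntegrityError("duplicate encounter_id values")

    known_patients = set(pat["patient_id"])
    for name in ("encounters", "diagnoses", "prescriptions"):
        refs = ds.table(name)["patient_id"]
        missing = ~refs.isin(known_patients)
        if missing.any():
            raise ReferentialIntegrityError(
                f"{name}: {int(missing.sum())} rows reference unknown patient_id "
                f"(e.g. {refs[missing].iloc[0]!r})"
            )
    linked = ds.diagnoses["encounter_id"]
    linked = linked[linked != ""]
    unknown = ~linked.isin(set(ds.encounters["encounter_id"]))
    if unknown.any():
        raise ReferentialIntegrityError(
            f"diagnoses: {int(unknown.sum())} rows reference unknown encounter_id"
        )


def _normalize_code(s: pd.Series) -> pd.Series:
    return s.str.strip().str.upper()


def _normalize_gender(s: pd.Series) -> pd.Series:
    up = s.str.strip().str.upper()
    out = pd.Series("", index=s.index, dtype="str")
    out[up.isin(["M", "MALE"])] = "M"
    out[up.isin(["F", "FEMALE"])] = "F"
    return out


# ---------------------------------------------------------------------------
# reading

def _coerce_patients(raw: pd.DataFrame, birth_year_range) -> tuple[pd.DataFrame, int]:
    ok = raw["patient_id"].str.len() > 0
    by = pd.to_numeric(raw["birth_year"].replace("", pd.NA), errors="coerce").astype("Int64")
    lo, hi = birth_year_range
    bad_year = by.notna() & ((by < lo) | (by > hi))
    # a non-empty birth_year that failed to parse is a type violation
    unparsed = (raw["birth_year"] != "") & by.isna()
    ok &= ~(bad_year | unparsed)
    out = pd.DataFrame(
        {
            "patient_id": raw["patient_id"],
            "birth_year": by,
            "gender": _normalize_gender(raw["gender"]),
            "site_id": raw["site_id"].str.strip(),
        }
    )[ok]
    return out.reset_index(drop=True), int((~ok).sum())


def _coerce_dates(s: pd.Series) -> pd.Series:
    return pd.to_datetime(s, format="%Y-%m-%d", errors="coerce")


def _coerce_bool(s: pd.Series) -> pd.Series:
    up = s.str.strip().str.lower()
    out = pd.Series(pd.NA, index=s.index, dtype="boolean")
    out[up.isin(["true", "t", "1", "yes"])] = True
    out[up.isin(["false", "f", "0", "no"])] = False
    return out


def _coerce_encounters(raw: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    date = _coerce_dates(raw["date"])
    inp = _coerce_bool(raw["in_person"])
    ok = (raw["encounter_id"].str.len() > 0) & (raw["patient_id"].str.len() > 0)
    ok &= date.notna() & inp.notna()
    out = pd.DataFrame(
        {
            "encounter_id": raw["encounter_id"],
            "patient_id": raw["patient_id"],
            "date": date,
            "in_person": inp,
        }
    )[ok]
    out["in_person"] = out["in_person"].astype(bool)
    return out.reset_index(drop=True), int((~ok).sum())


def _coerce_diagnoses(raw: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    date = _coerce_dates(raw["date"])
    code = _normalize_code(raw["code"])
    ok = (raw["patient_id"].str.len() > 0) & date.notna() & (code.str.len() > 0)
    ok &= raw["code_system"].isin(["ICD9"])
    ok &= raw["source"].isin(["encounter_diagnosis", "billing", "health_condition"])
    out = pd.DataFrame(
        {
            "patient_id": raw["patient_id"],
            "encounter_id": raw["encounter_id"].str.strip(),
            "date": date,
            "code": code,
            "code_system": raw["code_system"],
            "source": raw["source"],
        }
    )[ok]
    return out.reset_index(drop=True), int((~ok).sum())


def _coerce_prescriptions(raw: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    date = _coerce_dates(raw["date"])
    ok = (raw["patient_id"].str.len() > 0) & date.notna()
    ok &= raw["drug_identifier"].str.strip().str.len() > 0
    out = pd.DataFrame(
        {
            "patient_id": raw["patient_id"],
            "date": date,
            "drug_identifier": raw["drug_identifier"].str.strip(),
            "drug_class": raw["drug_class"].str.strip(),
        }
    )[ok]
    return out.reset_index(drop=True), int((~ok).sum())


def read_dataset(
    paths: Mapping[str, Path] | Path | str,
    birth_year_range: tuple[int, int] = DEFAULT_BIRTH_YEAR_RANGE,
) -> Dataset:
    """Read the four CSV tables, coerce, validate, and return a Dataset.

    ``paths`` is either a directory containing ``<table>.csv`` for each table
    or an explicit mapping table-name → file path. Rows violating type
    constraints are dropped; per-table rejection counts are logged and stored
    under ``provenance["rejected_rows"]``. Missing files or columns raise
    :class:`SchemaError`; broken references raise
    :class:`ReferentialIntegrityError`.
    """
    if not isinstance(paths, Mapping):
        root = Path(paths)
        paths = {name: root / f"{name}.csv" for name in TABLES}

    schema = load_schema()
    raw: dict[str, pd.DataFrame] = {}
    for name in TABLES:
        path = Path(paths[name])
        if not path.exists():
            raise SchemaError(f"missing table file: {path}")
        df = pd.read_csv(path, dtype="str", keep_default_na=False, encoding="utf-8")
        required = [c for c, meta in schema[name].items() if meta.get("required")]
        absent = [c for c in required if c not in df.columns]
        if absent:
            raise SchemaError(f"{path}: missing required columns {absent}")
        raw[name] = df

    coercers = {
        "patients": lambda df: _coerce_patients(df, birth_year_range),
        "encounters": _coerce_encounters,
        "diagnoses": _coerce_diagnoses,
        "prescriptions": _coerce_prescriptions,
    }
    frames, rejected = {}, {}
    for name in TABLES:
        frames[name], rejected[name] = coercers[name](raw[name])
        if rejected[name]:
            log.warning("%s: rejected %d unparseable rows", name, rejected[name])

    ds = Dataset(
        **frames,
        provenance={
            "paths": {k: str(v) for k, v in paths.items()},
            "rejected_rows": rejected,
        },
    )
    validate_dataset(ds)
    return ds


# ---------------------------------------------------------------------------
# writing

def write_dataset(ds: Dataset, out_dir: Path | str) -> dict[str, Path]:
    """Write one CSV per table under ``out_dir``; returns the paths.

    ``read_dataset(write_dataset(ds))`` reproduces ``ds`` field-for-field.
    """
    validate_dataset(ds)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name in TABLES:
        df = ds.table(name).copy()
        for col in df.columns:
            if pd.api.types.is_datetime64_any_dtype(df[col]):
                df[col] = df[col].dt.strftime("%Y-%m-%d")
            elif pd.api.types.is_bool_dtype(df[col]):
                df[col] = df[col].map({True: "true", False: "false"})
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, na_rep="", encoding="utf-8")
        paths[name] = path
    return paths


def datasets_equal(a: Dataset, b: Dataset) -> bool:
    """Field-for-field equality of the four tables (provenance ignored)."""
    try:
        for name in TABLES:
            pd.testing.assert_frame_equal(
                a.table(name).reset_index(drop=True),
                b.table(name).reset_index(drop=True),
                check_dtype=False,
            )
    except AssertionError:
        return False
    return True
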
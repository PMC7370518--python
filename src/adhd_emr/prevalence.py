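"""Observed and misclassification-adjusted prevalence over practice populations.

Observed prevalence is the fraction of a stratum's practice population the
case-finding algorithm flags, with an exact (Clopper-Pearson) binomial 95%
interval. Because the algorithm misclassifies, observed prevalence is biased;
two adjustments to the true prevalence pi are supported:

``rogan_gladen``
    pi = (p + Sp - 1) / (Se + Sp - 1), truncated to [0, 1]. Requires an
    informative algorithm (Se + Sp > 1). This is the default: Se and Sp are
    properties of the algorithm and transport across populations whose
    prevalence differs from the validation clinic's.

``ppv_npv_direct``
    pi = p * PPV + (1 - p) * (1 - NPV). Exact at the validation clinic, but
    PPV/NPV are prevalence-dependent, so this is strictly valid only where
    the target population's prevalence matches the clinic's.

Adjusted intervals transform both endpoints of the exact binomial interval of
the observed proportion through the same map (an approximation: it ignores
uncertainty in the validity indices themselves).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd

from .case_finder import CaseDefinitionConfig, find_cases
from .cohort import AGE_GROUPS, StratumKey, population_table, practice_population, stratify
from .store import Dataset
from .validity import ValidityIndices, clopper_pearson

log = logging.getLogger(__name__)

METHODS = ("rogan_gladen", "ppv_npv_direct")


def observed_prevalence(
    case_ids: set[str] | frozenset[str],
    strata: Mapping[StratumKey, frozenset[str]],
) -> pd.DataFrame:
    """Per-stratum observed prevalence with exact binomial 95% intervals.

    ``case_ids`` are the patients flagged by the case finder as of the
    stratum year. Zero-denominator strata are flagged (``flag`` column) and
    carry no estimate.
    """
    rows = []
    for key, members in strata.items():
        n = len(members)
        if n == 0:
            rows.append(
                {
                    "year": key.year, "age_group": key.age_group, "gender": key.gender,
                    "numerator": 0, "denominator": 0,
                    "observed": float("nan"), "observed_lo": float("nan"),
                    "observed_hi": float("nan"), "flag": "zero_denominator",
                }
            )
            continue
        k = len(case_ids & members)
        lo, hi = clopper_pearson(k, n)
        rows.append(
            {
                "year": key.year, "age_group": key.age_group, "gender": key.gender,
                "numerator": k, "denominator": n,
                "observed": k / n, "observed_lo": lo, "observed_hi": hi, "flag": "",
            }
        )
    return pd.DataFrame(rows)


def adjust_proportion(p: float, indices: ValidityIndices, method: str) -> float:
    """Map one observed proportion to an adjusted true-prevalence estimate."""
    if method == "rogan_gladen":
        se, sp = indices.sensitivity, indices.specificity
        if se + sp <= 1:
            raise ValueError("non-informative algorithm: Se + Sp must exceed 1")
        pi = (p + sp - 1) / (se + sp - 1)
    elif method == "ppv_npv_direct":
        pi = p * indices.ppv + (1 - p) * (1 - indices.npv)
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if pi < 0 or pi > 1:
        log.info("adjusted prevalence %.4f truncated to [0, 1]", pi)
    return min(max(pi, 0.0), 1.0)


def adjust_prevalence(
    estimates: pd.DataFrame, indices: ValidityIndices, method: str = "rogan_gladen"
) -> pd.DataFrame:
    """Add adjusted point estimates and endpoint-transformed intervals to an
    :func:`observed_prevalence` table."""
    out = estimates.copy()
    for src, dst in [
        ("observed", "adjusted"), ("observed_lo", "adjusted_lo"), ("observed_hi", "adjusted_hi"),
    ]:
        out[dst] = [
            adjust_proportion(p, indices, method) if pd.notna(p) else float("nan")
            for p in out[src]
        ]
    out["method"] = method
    return out


def gender_ratio(estimates: pd.DataFrame, column: str = "adjusted") -> pd.DataFrame:
    """Male-to-female prevalence ratio per year × age group.

    Ratios are reported to one decimal in the conventional "x:1" form; a zero
    or missing female estimate yields a flagged row with no ratio.
    """
    rows = []
    wide = estimates[estimates["gender"].isin(["M", "F"])].pivot_table(
        index=["year", "age_group"], columns="gender", values=column
    )
    for (year, group), r in wide.iterrows():
        male, female = r.get("M", float("nan")), r.get("F", float("nan"))
        if pd.isna(female) or female == 0 or pd.isna(male):
            rows.append({"year": year, "age_group": group, "ratio": float("nan"),
                         "display": "", "flag": "undefined"})
        else:
            ratio = male / female
            rows.append({"year": year, "age_group": group, "ratio": ratio,
                         "display": f"{ratio:.1f}:1", "flag": ""})
    return pd.DataFrame(rows)


def run_pipeline(
    ds: Dataset,
    case_cfg: CaseDefinitionConfig,
    indices: ValidityIndices | None,
    years: Iterable[int],
    method: str = "rogan_gladen",
) -> dict[str, pd.DataFrame]:
    """End-to-end yearly analysis: denominators, case finding, observed and
    (when indices are given) adjusted prevalence, and gender ratios.

    Returns ``{"population": ..., "prevalence": ..., "gender_ratios": ...}``.
    Deterministic given inputs.
    """
    years = list(years)
    tables = []
    for year in years:
        calls = find_cases(ds, case_cfg, as_of_year=year)
        case_ids = set(calls.loc[calls["is_case"], "patient_id"])
        strata = stratify(practice_population(ds, year), ds)
        obs = observed_prevalence(case_ids, strata)
        tables.append(obs)
    prev = pd.concat(tables, ignore_index=True)
    if indices is not None:
        prev = adjust_prevalence(prev, indices, method)
        ratios = gender_ratio(prev, column="adjusted")
    else:
        ratios = gender_ratio(prev, column="observed")
    prev = prev.sort_values(["year", "age_group", "gender"]).reset_index(drop=True)
    return {
        "population": population_table(ds, years),
        "prevalence": prev,
        "gender_ratios": ratios.sort_values(["year", "age_group"]).reset_index(drop=True),
    }


def format_prevalence_table(prev: pd.DataFrame, column: str = "adjusted") -> pd.DataFrame:
    """Year × age-group table of percentages "x.xx (lo, hi)" (both genders)."""
    sub = prev[prev["gender"] == "all"].copy()
    lo, hi = f"{column}_lo", f"{column}_hi"
    sub["cell"] = [
        f"{100 * p:.2f} ({100 * l:.2f}, {100 * h:.2f})" if pd.notna(p) else ""
        for p, l, h in zip(sub[column], sub[lo], sub[hi])
    ]
    table = sub.pivot_table(index="year", columns="age_group", values="cell", aggfunc="first")
    return table[[g for g in AGE_GROUPS if g in table.columns]]
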
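#!/usr/bin/env python
"""Yearly observed and adjusted ADHD prevalence in the synthetic world.

Reads scratch/synth_world/, estimates the algorithm's validity indices by an
exhaustive review of a separately generated validation clinic (predictive
values from the full confusion table, Se/Sp via the misclassification
identities), then runs the full pipeline over 2008-2015: practice-population
denominators, per-stratum observed prevalence with exact binomial intervals,
Rogan-Gladen-adjusted prevalence, and male:female ratios. Ends by comparing
adjusted estimates against the generator's ground truth for 2015.
"""

from pathlib import Path

import pandas as pd

from adhd_emr.case_finder import CaseDefinitionConfig
from adhd_emr.cohort import StratumKey, practice_population, stratify
from adhd_emr.prevalence import format_prevalence_table, run_pipeline
from adhd_emr.store import read_dataset
from adhd_emr.studies import _full_review_indices
from adhd_emr.synth import GeneratorConfig, generate

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "synth_world"
RESULTS = ROOT / "results"

YEARS = range(2008, 2016)


def main() -> None:
    if not DATA.exists():
        raise SystemExit(f"{DATA} not found - run analysis/01_simulate.py first")
    ds = read_dataset(DATA)
    truth = pd.read_csv(DATA / "ground_truth.csv")
    cfg = CaseDefinitionConfig()

    # validity indices from an independent synthetic validation clinic with
    # the same misclassification mechanisms and prevalence structure
    val_ds, val_truth = generate(
        GeneratorConfig(n_patients=20_000, year_range=(2014, 2015), seed=77)
    )
    counts, idx = _full_review_indices(val_ds, val_truth, cfg, year=2015)
    print(
        f"validation clinic: PPV {100 * idx.ppv:.1f}%  NPV {100 * idx.npv:.1f}%  "
        f"derived Se {100 * idx.sensitivity:.1f}%  Sp {100 * idx.specificity:.1f}%"
    )

    report = run_pipeline(ds, cfg, idx, YEARS, method="rogan_gladen")
    RESULTS.mkdir(exist_ok=True)
    report["population"].to_csv(RESULTS / "population_by_year.csv", index=False)
    report["prevalence"].to_csv(RESULTS / "prevalence_by_stratum.csv", index=False)
    report["gender_ratios"].to_csv(RESULTS / "gender_ratios.csv", index=False)

    print("\nadjusted prevalence, % of patients (95% CI):")
    print(format_prevalence_table(report["prevalence"], "adjusted").to_string())
    print("\nmale:female ratios (adjusted):")
    ratios = report["gender_ratios"].pivot(index="year", columns="age_group", values="display")
    print(ratios.to_string())

    # how close is the 2015 adjusted estimate to the generator's truth?
    strata = stratify(practice_population(ds, 2015), ds)
    truth_by_id = truth.set_index("patient_id")["is_true_case"]
    prev = report["prevalence"].set_index(["year", "age_group", "gender"])
    rows = []
    for g in ("4-17", "18-34", "35-64"):
        members = list(strata[StratumKey(2015, g, "all")])
        row = prev.loc[(2015, g, "all")]
        rows.append(
            {
                "age_group": g,
                "truth_pct": round(100 * truth_by_id.loc[members].mean(), 2),
                "observed_pct": round(100 * row["observed"], 2),
                "adjusted_pct": round(100 * row["adjusted"], 2),
            }
        )
    recovery = pd.DataFrame(rows)
    recovery.to_csv(RESULTS / "recovery_2015.csv", index=False)
    print("\n2015 adjusted vs ground truth:")
    print(recovery.to_string(index=False))


if __name__ == "__main__":
    main()
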
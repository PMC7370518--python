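#!/usr/bin/env python
"""Generate the synthetic multi-year primary-care population.

Writes the four EMR tables plus ground truth under scratch/synth_world/ (the
working dataset for the later drivers) and a small generation summary under
results/. The world: 30,000 patients rostered between 2007 and 2015, ADHD
prevalence by age and gender with the usual male excess, specialist-managed
misses at the chart-review-calibrated rate, coded rule-out visits, and a
sprinkle of invalid demographics and exclusionary conditions.
"""

from pathlib import Path

import pandas as pd

from adhd_emr.store import write_dataset
from adhd_emr.synth import GeneratorConfig, generate

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "synth_world"
RESULTS = ROOT / "results"


def main() -> None:
    cfg = GeneratorConfig(n_patients=30_000, year_range=(2007, 2015), seed=20_240)
    ds, truth = generate(cfg)
    write_dataset(ds, OUT)
    truth.to_csv(OUT / "ground_truth.csv", index=False)

    RESULTS.mkdir(exist_ok=True)
    summary = pd.DataFrame(
        [
            {"quantity": "patients", "value": len(ds.patients)},
            {"quantity": "encounters", "value": len(ds.encounters)},
            {"quantity": "diagnosis_rows", "value": len(ds.diagnoses)},
            {"quantity": "prescription_rows", "value": len(ds.prescriptions)},
            {"quantity": "true_cases", "value": int(truth["is_true_case"].sum())},
            {"quantity": "specialist_managed_cases",
             "value": int((truth["mechanism"] == "specialist_managed_case").sum())},
            {"quantity": "ruleout_non_cases",
             "value": int((truth["mechanism"] == "ruleout_non_case").sum())},
        ]
    )
    summary.to_csv(RESULTS / "synth_world_summary.csv", index=False)
    print(f"wrote dataset to {OUT}")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
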
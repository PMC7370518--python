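"""Observed prevalence, misclassification adjustment, ratios, pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from adhd_emr.case_finder import CaseDefinitionConfig
from adhd_emr.cohort import StratumKey
from adhd_emr.prevalence import (
    adjust_prevalence,
    adjust_proportion,
    gender_ratio,
    observed_prevalence,
    run_pipeline,
)
from adhd_emr.synth import GeneratorConfig, generate, no_misclassification
from adhd_emr.validity import ValidityIndices


def make_indices(se, sp, ppv=0.96, npv=0.96, p=0.0125):
    return ValidityIndices(
        ppv=ppv, npv=npv, sensitivity=se, specificity=sp,
        ci_ppv=(0, 1), ci_npv=(0, 1), ci_se=None, ci_sp=None,
        apparent_prevalence=p, true_prevalence_clinic=p,
    )


class TestObserved:
    def test_proportion_and_interval(self):
        strata = {StratumKey(2010, "4-17", "all"): frozenset(f"p{i}" for i in range(100))}
        out = observed_prevalence({f"p{i}" for i in range(5)}, strata)
        row = out.iloc[0]
        assert row["observed"] == 0.05 and row["numerator"] == 5 and row["denominator"] == 100
        assert row["observed_lo"] < 0.05 < row["observed_hi"]

    def test_zero_cases_boundary(self):
        strata = {StratumKey(2010, "4-17", "all"): frozenset(f"p{i}" for i in range(100))}
        row = observed_prevalence(set(), strata).iloc[0]
        assert row["observed"] == 0.0 and row["observed_lo"] == 0.0

    def test_zero_denominator_flagged(self):
        row = observed_prevalence(set(), {StratumKey(2010, "4-17", "F"): frozenset()}).iloc[0]
        assert row["flag"] == "zero_denominator" and np.isnan(row["observed"])


class TestAdjust:
    def test_perfect_indices_are_identity(self):
        idx = make_indices(1.0, 1.0, ppv=1.0, npv=1.0)
        assert adjust_proportion(0.07, idx, "rogan_gladen") == pytest.approx(0.07)
        assert adjust_proportion(0.07, idx, "ppv_npv_direct") == pytest.approx(0.07)

    def test_truncation_below_false_positive_floor(self):
        idx = make_indices(0.8, 0.95)
        assert adjust_proportion(0.02, idx, "rogan_gladen") == 0.0

    def test_noninformative_test_is_error(self):
        with pytest.raises(ValueError, match="non-informative"):
            adjust_proportion(0.1, make_indices(0.5, 0.5), "rogan_gladen")

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            adjust_proportion(0.1, make_indices(0.9, 0.9), "bogus")

    @given(st.floats(0.01, 0.2), st.floats(0.015, 0.2))
    def test_monotone_in_observed(self, p1, p2):
        """Strictly increasing in p for fixed indices (non-truncated range)."""
        idx = make_indices(0.9, 0.999, ppv=0.95, npv=0.99)
        lo, hi = sorted((p1, p2))
        if hi - lo < 1e-9:
            return
        for method in ("rogan_gladen", "ppv_npv_direct"):
            assert adjust_proportion(hi, idx, method) > adjust_proportion(lo, idx, method)

    @given(st.floats(0.02, 0.3), st.floats(0.6, 0.99), st.floats(0.9, 0.999))
    def test_methods_agree_at_validation_clinic_prevalence(self, pi, se, sp):
        """When the target p equals the clinic's apparent prevalence, the
        PPV/NPV-direct map and the Rogan-Gladen inversion coincide."""
        p = se * pi + (1 - sp) * (1 - pi)
        if not 0.001 < p < 0.999:
            return
        ppv = se * pi / p
        npv = sp * (1 - pi) / (1 - p)
        idx = make_indices(se, sp, ppv=ppv, npv=npv, p=p)
        a = adjust_proportion(p, idx, "rogan_gladen")
        b = adjust_proportion(p, idx, "ppv_npv_direct")
        assert a == pytest.approx(b, rel=1e-9)
        assert a == pytest.approx(pi, rel=1e-9)

    def test_interval_endpoints_transform_with_point(self):
        est = pd.DataFrame(
            [{"year": 2010, "age_group": "4-17", "gender": "all",
              "numerator": 50, "denominator": 1000, "observed": 0.05,
              "observed_lo": 0.037, "observed_hi": 0.065, "flag": ""}]
        )
        out = adjust_prevalence(est, make_indices(0.8, 1.0), "rogan_gladen")
        row = out.iloc[0]
        assert row["adjusted"] == pytest.approx(0.05 / 0.8)
        assert row["adjusted_lo"] == pytest.approx(0.037 / 0.8)
        assert row["adjusted_hi"] == pytest.approx(0.065 / 0.8)
        assert row["adjusted_lo"] < row["adjusted"] < row["adjusted_hi"]


class TestGenderRatio:
    def _frame(self, male, female):
        return pd.DataFrame(
            [
                {"year": 2010, "age_group": "4-17", "gender": "M", "adjusted": male},
                {"year": 2010, "age_group": "4-17", "gender": "F", "adjusted": female},
            ]
        )

    def test_symmetry_and_arithmetic(self):
        assert gender_ratio(self._frame(0.08, 0.08)).iloc[0]["display"] == "1.0:1"
        assert gender_ratio(self._frame(0.091, 0.070)).iloc[0]["display"] == "1.3:1"

    def test_zero_female_prevalence_flagged(self):
        row = gender_ratio(self._frame(0.08, 0.0)).iloc[0]
        assert row["flag"] == "undefined" and np.isnan(row["ratio"])


@pytest.fixture(scope="module")
def clean_world():
    cfg = no_misclassification(
        GeneratorConfig(n_patients=12_000, year_range=(2012, 2015), seed=13)
    )
    ds, truth = generate(cfg)
    return cfg, ds, truth


class TestPipeline:
    def test_yearly_tables_and_monotone_denominators(self, clean_world):
        _, ds, _ = clean_world
        rep = run_pipeline(ds, CaseDefinitionConfig(), None, range(2013, 2016))
        pop = rep["population"]
        assert list(pop["year"]) == [2013, 2014, 2015]
        # patients accrue (roster start years are spread), so denominators grow
        assert pop["n"].is_monotonic_increasing

    def test_no_misclassification_adjusted_matches_truth(self, clean_world):
        """With a perfect algorithm, observed ~= adjusted ~= ground truth."""
        cfg, ds, truth = clean_world
        idx = make_indices(1.0, 1.0, ppv=1.0, npv=1.0)
        rep = run_pipeline(ds, CaseDefinitionConfig(), idx, [2015])
        prev = rep["prevalence"]
        merged = truth.set_index("patient_id")
        from adhd_emr.cohort import practice_population, stratify

        strata = stratify(practice_population(ds, 2015), ds)
        for _, row in prev[prev["gender"] == "all"].iterrows():
            members = strata[StratumKey(2015, row["age_group"], "all")]
            true_frac = merged.loc[list(members), "is_true_case"].mean()
            assert row["adjusted"] == pytest.approx(row["observed"])
            # flagged set equals true set up to patients outside the denominator
            assert row["observed"] == pytest.approx(true_frac, abs=0.01)

    def test_gendered_counts_conserve(self, clean_world):
        _, ds, _ = clean_world
        rep = run_pipeline(ds, CaseDefinitionConfig(), None, [2015])
        prev = rep["prevalence"].set_index(["age_group", "gender"])
        for g in ("4-17", "18-34", "35-64"):
            assert (
                prev.loc[(g, "M"), "numerator"] + prev.loc[(g, "F"), "numerator"]
                == prev.loc[(g, "all"), "numerator"]
            )
            assert (
                prev.loc[(g, "M"), "denominator"] + prev.loc[(g, "F"), "denominator"]
                == prev.loc[(g, "all"), "denominator"]
            )

    def test_gender_ratio_recovers_generator_imbalance(self):
        """Male:female risk ratio 1.3 in children is recovered at scale."""
        prev_map = {("4-17", "M"): 0.091, ("4-17", "F"): 0.070}
        cfg = no_misclassification(
            GeneratorConfig(
                n_patients=40_000, year_range=(2014, 2015),
                true_prevalence_by_stratum=prev_map, seed=21,
            )
        )
        ds, _ = generate(cfg)
        rep = run_pipeline(ds, CaseDefinitionConfig(), None, [2015])
        ratios = rep["gender_ratios"].set_index("age_group")
        assert ratios.loc["4-17", "ratio"] == pytest.approx(1.3, abs=0.2)
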
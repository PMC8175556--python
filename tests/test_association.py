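"""Logistic association scan, BH FDR, DE calling, rank DE, list overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcatx.association import (
    bh_adjust,
    call_de_genes,
    covariates_from_clinical,
    feature_association,
    fit_logistic,
    overlap_de_lists,
    wilcoxon_de,
)
from tests.oracles import bh_stepup_loop, logit_beta_2x2


def _binary_design(n11, n10, n01, n00):
    y = np.array([1] * (n11 + n10) + [0] * (n01 + n00), dtype=float)
    x = np.array([1] * n11 + [0] * n10 + [1] * n01 + [0] * n00, dtype=float)
    return y, x


class TestFitLogistic:
    def test_2x2_cell_counts_give_log_odds_ratio(self):
        y, x = _binary_design(30, 10, 10, 30)
        model = fit_logistic(y, x)
        assert model.converged
        assert model.beta1 == pytest.approx(np.log(9), abs=1e-6)
        assert model.odds_ratio == pytest.approx(9.0, rel=1e-5)

    def test_balanced_independent_predictor_beta_zero(self):
        y, x = _binary_design(20, 20, 20, 20)
        model = fit_logistic(y, x)
        assert model.beta1 == pytest.approx(0.0, abs=1e-8)

    def test_perfect_separation_flagged_not_raised(self):
        y = np.array([1.0] * 10 + [0.0] * 10)
        x = np.concatenate([np.linspace(1, 2, 10), np.linspace(-2, -1, 10)])
        model = fit_logistic(y, x)
        assert not model.converged

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(np.ones(10), np.arange(10.0))

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=4, max_size=4))
    def test_matches_closed_form_over_random_tables(self, cells):
        n11, n10, n01, n00 = cells
        y, x = _binary_design(n11, n10, n01, n00)
        model = fit_logistic(y, x)
        if model.converged:
            assert model.beta1 == pytest.approx(logit_beta_2x2(*cells), abs=1e-6)


class TestCovariateDerivation:
    def test_stage_decomposition(self):
        clin = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c", "d"],
                "grade_group": ["1", "3", "5", "2"],
                "pt_stage": ["T2", "T3a", "T3b", "T4"],
                "pn_stage": ["N0", "NX", "N1", "N1"],
            }
        )
        cov = covariates_from_clinical(clin)
        assert cov.loc["a"].tolist() == [1.0, 0.0, 0.0, 0.0]
        assert cov.loc["b"].tolist() == [3.0, 1.0, 0.0, 0.0]
        assert cov.loc["c"].tolist() == [5.0, 1.0, 1.0, 1.0]
        assert cov.loc["d"].tolist() == [2.0, 1.0, 1.0, 1.0]
        # SVI implies EPE everywhere
        assert ((cov["svi"] == 1) <= (cov["epe"] == 1)).all()

    def test_unknown_stage_codes_listed(self):
        clin = pd.DataFrame(
            {
                "sample_id": ["a"],
                "grade_group": ["2"],
                "pt_stage": ["T9"],
                "pn_stage": ["N0"],
            }
        )
        with pytest.raises(ValueError, match="T9"):
            covariates_from_clinical(clin)


class TestBHAdjust:
    def test_stepup_hand_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04, 0.05])
        np.testing.assert_allclose(q, [0.05] * 5)

    def test_single_value_is_identity(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones_capped(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        np.testing.assert_allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_stepup_loop(p), atol=1e-12)


class TestFeatureAssociation:
    def test_planted_genes_recovered(self, small_cohort, outcome_and_cov):
        outcome, cov = outcome_and_cov
        res = feature_association(small_cohort.expression, outcome, cov)
        planted = list(small_cohort.truth["planted_effects"])
        hits = (res.loc[planted, "q_value"] < 0.05).sum()
        assert hits >= 8  # 1-SD shifts at n=120/100 are nearly always found
        assert (res.loc[planted, "beta1"] > 0).all()

    def test_constant_feature_excluded_run_continues(self, small_cohort, outcome_and_cov):
        outcome, cov = outcome_and_cov
        expr = small_cohort.expression.iloc[:20].copy()
        expr.iloc[0] = 1.0
        res = feature_association(expr, outcome, cov)
        assert not res["converged"].iloc[0]
        assert np.isnan(res["q_value"].iloc[0])
        assert res["converged"].iloc[1:].all()

    def test_invariant_to_feature_order(self, small_cohort, outcome_and_cov):
        outcome, cov = outcome_and_cov
        expr = small_cohort.expression.iloc[:30]
        a = feature_association(expr, outcome, cov)
        b = feature_association(expr.iloc[::-1], outcome, cov)
        np.testing.assert_allclose(
            a.sort_index()["p_value"], b.sort_index()["p_value"], rtol=1e-10
        )

    def test_group_relabel_flips_beta_sign(self, small_cohort, outcome_and_cov):
        outcome, cov = outcome_and_cov
        expr = small_cohort.expression.iloc[:15]
        a = feature_association(expr, outcome, cov)
        b = feature_association(expr, 1.0 - outcome, cov)
        np.testing.assert_allclose(a["beta1"], -b["beta1"], atol=1e-6)
        np.testing.assert_allclose(a["p_value"], b["p_value"], rtol=1e-6)

    def test_listwise_deletion_gives_common_n(self, small_cohort, outcome_and_cov):
        outcome, cov = outcome_and_cov
        res = feature_association(small_cohort.expression.iloc[:5], outcome, cov)
        expected_n = int((~cov.isna().any(axis=1)).sum())
        assert (res["n_used"] == expected_n).all()


class TestDECallsAndOverlap:
    def test_threshold_semantics(self):
        res = pd.DataFrame(
            {"beta1": [2.0, 2.0], "q_value": [1e-6, 0.5]},
            index=["gA", "gB"],
        )
        calls = call_de_genes(res, 1e-5)
        assert calls == {"up_group1": ["gA"], "up_group0": []}

    def test_threshold_one_calls_all_finite(self):
        res = pd.DataFrame(
            {"beta1": [1.0, -1.0, 0.5], "q_value": [0.2, 0.9, np.nan]},
            index=list("abc"),
        )
        calls = call_de_genes(res, 1.0)
        assert set(calls["up_group1"] + calls["up_group0"]) == {"a", "b"}

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (["A", "B", "C"], ["B", "C", "D"], (2, 0.5)),
            (["A"], ["B"], (0, 0.0)),
            (list("xyz"), list("xyz"), (3, 1.0)),
        ],
    )
    def test_overlap_and_jaccard(self, a, b, expected):
        res = overlap_de_lists(a, b)
        assert (res["overlap"], res["jaccard"]) == expected


class TestWilcoxonDE:
    def test_identical_gene_p_one(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], index=["g"],
                            columns=[f"s{i}" for i in range(6)])
        groups = pd.Series([1, 1, 1, 0, 0, 0], index=expr.columns, dtype=float)
        res = wilcoxon_de(expr, groups)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_direction_antisymmetric_under_relabeling(self, small_cohort):
        expr = small_cohort.expression.iloc[:10]
        groups = pd.Series(
            (small_cohort.clinical["group"] == "AAM").astype(float).to_numpy(),
            index=small_cohort.clinical["sample_id"].to_numpy(),
        )
        a = wilcoxon_de(expr, groups)
        b = wilcoxon_de(expr, 1.0 - groups)
        np.testing.assert_allclose(a["mean_diff"], -b["mean_diff"], atol=1e-12)
        np.testing.assert_allclose(a["p_value"], b["p_value"], rtol=1e-9)

    def test_planted_genes_enriched_at_validation_cohort_size(self):
        # mirrors a 37 vs 233 validation cohort
        from pcatx.synthetic import CohortSpec, generate_cohort

        planted = {f"G{i:05d}": 1.2 for i in range(1, 11)}
        cohort = generate_cohort(
            CohortSpec(n_group1=37, n_group0=233, n_genes=200, planted_effects=planted, seed=5)
        )
        groups = pd.Series(
            (cohort.clinical["group"] == "AAM").astype(float).to_numpy(),
            index=cohort.clinical["sample_id"].to_numpy(),
        )
        res = wilcoxon_de(cohort.expression, groups)
        planted_rank = res["p_value"].rank().loc[list(planted)]
        assert planted_rank.median() <= 30
        assert (res.loc[list(planted), "mean_diff"] > 0).all()
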
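"""Contingency-table and rank tests against enumeration oracles and hand values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pcatx.cohort_stats import (
    VariableDescriptor,
    build_table_one,
    chi_square_test,
    fisher_exact_test,
    group_percentage,
    mann_whitney_u,
    round1,
)
from tests.oracles import fisher_p_enumeration, mwu_p_enumeration


class TestChiSquare:
    def test_proportional_rows_give_zero_statistic(self):
        res = chi_square_test([[10, 10], [20, 20]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_df_matches_table_shape(self):
        res = chi_square_test([[5, 6, 7], [8, 9, 10], [11, 12, 13], [14, 15, 16]])
        assert res.df == 6

    def test_invariant_under_row_and_column_permutation(self):
        rng = np.random.default_rng(0)
        table = rng.integers(1, 40, size=(4, 3))
        base = chi_square_test(table)
        perm = chi_square_test(table[[2, 0, 3, 1]][:, [1, 2, 0]])
        assert perm.statistic == pytest.approx(base.statistic)
        assert perm.p_value == pytest.approx(base.p_value)

    def test_zero_margin_is_rejected_with_location(self):
        with pytest.raises(ValueError, match="zero-sum rows"):
            chi_square_test([[0, 0], [5, 6]])
        with pytest.raises(ValueError, match="zero-sum col"):
            chi_square_test([[0, 3], [0, 6]])


class TestFisherExact:
    def test_uniform_table_p_one(self):
        assert fisher_exact_test([[1, 1], [1, 1]]).p_value == pytest.approx(1.0)

    def test_diagonal_table_matches_enumeration(self):
        # [[5,0],[0,5]]: only the two extreme tables qualify -> 2/C(10,5)
        res = fisher_exact_test([[5, 0], [0, 5]])
        assert res.p_value == pytest.approx(2 / 252, rel=1e-9)

    def test_non_2x2_rejected(self):
        with pytest.raises(ValueError, match="2x2"):
            fisher_exact_test([[1, 2, 3], [4, 5, 6]])

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=15), min_size=4, max_size=4))
    def test_matches_hypergeometric_enumeration(self, cells):
        a, b, c, d = cells
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            return
        res = fisher_exact_test([[a, b], [c, d]])
        assert res.p_value == pytest.approx(fisher_p_enumeration(a, b, c, d), rel=1e-7)


class TestMannWhitney:
    def test_fully_separated_small_samples_exact(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.method == "mann-whitney-exact"
        assert res.p_value == pytest.approx(0.1)

    def test_symmetric_in_sample_order(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(size=25)
        assert mann_whitney_u(x, y).p_value == pytest.approx(mann_whitney_u(y, x).p_value)

    def test_identical_multisets_p_one(self):
        res = mann_whitney_u([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert res.p_value == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=1, max_value=6),
        st.integers(min_value=0, max_value=2**24),
    )
    def test_exact_path_matches_enumeration(self, n1, seed):
        rng = np.random.default_rng(seed)
        total = rng.integers(n1 + 1, 9)
        vals = rng.permutation(np.arange(1.0, total + 1.0))
        x, y = vals[:n1], vals[n1:]
        res = mann_whitney_u(x, y)
        assert res.p_value == pytest.approx(mwu_p_enumeration(x, y), rel=1e-9)


class TestPercentages:
    @pytest.mark.parametrize(
        "count, denom, expected",
        [(88 + 16, 596, 17.4), (63, 556, 11.3), (89, 596, 14.9), (54, 556, 9.7), (0, 596, 0.0)],
    )
    def test_published_percentages(self, count, denom, expected):
        assert round1(group_percentage(count, denom)) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            group_percentage(1, 0)

    def test_round_half_even(self):
        assert round1(0.25) == 0.2
        assert round1(0.35) == 0.4


class TestBuildTableOne:
    def test_categorical_percentages_sum_to_100(self, small_cohort):
        table = build_table_one(
            small_cohort.clinical, [VariableDescriptor("grade_group", "categorical")]
        )
        for grp in ("AAM", "EAM"):
            assert table[f"{grp}_pct"].sum() == pytest.approx(100.0, abs=0.3)

    def test_continuous_row_matches_direct_computation(self, small_cohort):
        clin = small_cohort.clinical
        table = build_table_one(clin, [VariableDescriptor("psa", "continuous")])
        row = table.iloc[0]
        vals = clin.loc[clin["group"] == "AAM", "psa"].astype(float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        assert row["AAM_summary"] == f"{med:.1f} ({q1:.1f}, {q3:.1f})"
        # P value agrees with a direct rank test on the same data
        other = clin.loc[clin["group"] == "EAM", "psa"].astype(float)
        direct = stats.mannwhitneyu(vals, other, alternative="two-sided", use_continuity=False)
        assert row["p_value"] == pytest.approx(direct.pvalue, rel=1e-6)

    def test_missing_values_reduce_analyzed_n(self, small_cohort):
        clin = small_cohort.clinical
        table = build_table_one(clin, [VariableDescriptor("pt_stage", "categorical")])
        assert table["n_analyzed"].iloc[0] == clin["pt_stage"].notna().sum()

    def test_unknown_column_rejected(self, small_cohort):
        with pytest.raises(KeyError, match="nonesuch"):
            build_table_one(small_cohort.clinical, [VariableDescriptor("nonesuch", "categorical")])

    def test_null_variable_rarely_significant(self):
        # identical distribution in both groups: P < 0.01 should be rare
        rng = np.random.default_rng(5)
        import pandas as pd

        hits = 0
        n_reps = 100
        for _ in range(n_reps):
            clin = pd.DataFrame(
                {
                    "sample_id": range(400),
                    "group": ["A"] * 200 + ["B"] * 200,
                    "value": rng.normal(size=400),
                }
            )
            tab = build_table_one(clin, [VariableDescriptor("value", "continuous")])
            hits += tab["p_value"].iloc[0] < 0.01
        assert hits <= 4
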
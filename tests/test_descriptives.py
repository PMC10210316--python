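"""Descriptive group tests against the published cohort table and oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from vvrkit import (
    ContingencyTable,
    GroupSummary,
    generate_frame,
    CohortConfig,
    mann_whitney_z,
    pearson_chi_square,
    summarize_cohort,
    welch_t,
)
from vvrkit.descriptives import mann_whitney_exact_p
from vvrkit.reference import (
    CATEGORICAL_TABLES,
    CONTINUOUS_SUMMARIES,
    PRINTED_CHI_SQUARE,
    PRINTED_WELCH_T,
)


class TestChiSquare:
    @pytest.mark.parametrize("name", sorted(PRINTED_CHI_SQUARE))
    def test_published_statistics_reproduce_to_3dp(self, name):
        """Every published categorical chi-square comes back from its
        printed counts without continuity correction."""
        res = pearson_chi_square(CATEGORICAL_TABLES[name])
        assert round(res.statistic, 3) == pytest.approx(PRINTED_CHI_SQUARE[name])

    def test_lvef_has_two_degrees_of_freedom(self):
        assert pearson_chi_square(CATEGORICAL_TABLES["lvef"]).df == 2

    def test_perfect_independence(self):
        res = pearson_chi_square(ContingencyTable(((10, 10), (10, 10))))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    @given(st.lists(st.tuples(st.integers(1, 80), st.integers(1, 80)),
                    min_size=2, max_size=5))
    def test_matches_scipy_without_correction(self, rows):
        """Formula path equals the independent scipy computation to 1e-9."""
        table = ContingencyTable(tuple(rows))
        res = pearson_chi_square(table)
        expected, p, df, _ = stats.chi2_contingency(table.array, correction=False)
        assert res.statistic == pytest.approx(expected, abs=1e-9)
        assert res.df == df
        assert res.p_value == pytest.approx(p, abs=1e-12)

    @given(st.integers(1, 50), st.integers(1, 50), st.integers(1, 50), st.integers(1, 50))
    def test_2x2_cross_product_identity(self, a, b, c, d):
        """2x2 statistic equals N (ad-bc)^2 / product of marginals."""
        res = pearson_chi_square(ContingencyTable(((a, b), (c, d))))
        n = a + b + c + d
        shortcut = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.statistic == pytest.approx(shortcut, abs=1e-9)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            ContingencyTable(((0, 0), (5, 5)))

    def test_small_expected_count_warns(self):
        with pytest.warns(UserWarning, match="expected count"):
            res = pearson_chi_square(ContingencyTable(((1, 1), (1, 200))))
        assert res.warnings


class TestWelch:
    @pytest.mark.parametrize("name", sorted(PRINTED_WELCH_T))
    def test_published_t_statistics_reproduce_to_2dp(self, name):
        a, b = CONTINUOUS_SUMMARIES[name]
        res = welch_t(a, b)
        assert round(res.statistic, 2) == pytest.approx(PRINTED_WELCH_T[name])

    def test_identical_groups(self):
        s = GroupSummary(50, 10.0, 2.0)
        res = welch_t(s, s)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_sign_flips_under_group_exchange(self):
        a, b = CONTINUOUS_SUMMARIES["bmi"]
        assert welch_t(a, b).statistic == pytest.approx(-welch_t(b, a).statistic)

    def test_from_sample_summarizes(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.5, 2, 30)
        ours = welch_t(GroupSummary.from_sample(x), GroupSummary.from_sample(y))
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)
        assert ours.df == pytest.approx(ref.df)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            GroupSummary(1, 0.0, 1.0)


class TestMannWhitney:
    def test_identical_samples_give_zero_z(self):
        res = mann_whitney_z([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_exact_enumeration_small_sample(self):
        """Exact two-sided p for [1,2] vs [3,4] is 2/6 by enumerating all
        C(4,2) group assignments."""
        assert mann_whitney_exact_p([1, 2], [3, 4]) == pytest.approx(2 / 6)

    def test_z_matches_hand_midrank_computation(self):
        # a = [1,2,3,10], b = [4,5,6,7]: ranks of a are 1,2,3,8 -> U1 = 4;
        # var (no ties) = n1 n2 (n+1)/12 = 12; Z = (4 - 8)/sqrt(12)
        res = mann_whitney_z([1, 2, 3, 10], [4, 5, 6, 7])
        assert res.statistic == pytest.approx(-4 / np.sqrt(12))

    def test_matches_scipy_asymptotic_with_ties(self, rng):
        a = rng.integers(0, 6, 60).astype(float)
        b = rng.integers(1, 7, 45).astype(float)
        res = mann_whitney_z(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    @given(st.lists(st.integers(-50, 50), min_size=3, max_size=12),
           st.lists(st.integers(-50, 50), min_size=3, max_size=12))
    def test_invariant_under_monotone_transform(self, a, b):
        from hypothesis import assume
        assume(len(set(a) | set(b)) > 1)
        z_raw = mann_whitney_z(a, b).statistic
        f = lambda x: np.exp(np.asarray(x) / 50.0)
        z_transformed = mann_whitney_z(f(a), f(b)).statistic
        assert z_raw == pytest.approx(z_transformed, abs=1e-12)

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError, match="tied"):
            mann_whitney_z([5, 5], [5, 5, 5])


class TestSummarizeCohort:
    def test_one_row_per_covariate_with_routed_tests(self, default_cohort):
        frame, _ = default_cohort
        report = summarize_cohort(frame)
        assert len(report) == 17
        routed = dict(zip(report["variable"], report["test"]))
        assert routed["Gender"] == "chi-square"
        assert routed["Age (year)"] == "welch-t"
        assert routed["VIS"] == "mann-whitney"

    def test_statistics_column_rounded_to_3dp(self, default_cohort):
        frame, _ = default_cohort
        report = summarize_cohort(frame)
        assert (report["statistic_3dp"] == report["statistic"].round(3)).all()

    def test_single_outcome_class_rejected(self):
        frame, _ = generate_frame(CohortConfig(n_patients=100, seed=2))
        frame["poor_prognosis"] = 0
        with pytest.raises(ValueError, match="single class"):
            summarize_cohort(frame)
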
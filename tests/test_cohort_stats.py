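"""Nonparametric group statistics against exact enumeration and formula oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sstats

from pulsewave.cohort_stats import (
    ContingencyTable,
    anova_from_summary,
    chi_square,
    compare_groups,
    comparison_frame,
    kruskal_wallis,
    mann_whitney_z,
    median_iqr,
)
from pulsewave.exceptions import ParameterError
from pulsewave.synthetic_data import sample_feature_cohort


def mann_whitney_enumeration_moments(x, y):
    """Observed U plus the exact permutation-null mean and SD of U.

    Enumerates every assignment of the pooled values to the two groups, so
    it is independent of the tie-correction formula under test.
    """
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sstats.rankdata(pooled)

    def u_of(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2

    us = np.array([u_of(c) for c in itertools.combinations(range(len(pooled)), n1)])
    return u_of(range(n1)), us.mean(), us.std(ddof=0)


class TestMedianIqr:
    def test_one_to_nine(self):
        assert median_iqr(range(1, 10)) == (5.0, 3.0, 7.0)

    def test_single_value(self):
        assert median_iqr([4.2]) == (4.2, 4.2, 4.2)

    def test_matches_percentile_oracle(self, rng):
        v = rng.normal(size=101)
        med, q1, q3 = median_iqr(v)
        s = np.sort(v)
        assert med == np.median(s)
        assert (q1, q3) == tuple(np.percentile(s, [25, 75]))

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            median_iqr([])


class TestMannWhitney:
    def test_fully_separated_samples(self):
        u, z, p = mann_whitney_z([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        # Z from the tie-free normal approximation: (U - n1 n2/2)/sqrt(var)
        expected_z = (0 - 4.5) / math.sqrt(3 * 3 * 7 / 12)
        assert z == pytest.approx(expected_z)

    def test_identical_multisets_give_zero_z(self):
        x = [1.0, 2.0, 5.0, 5.0]
        u, z, p = mann_whitney_z(x, list(x))
        assert z == 0.0 and p == 1.0

    def test_tie_correction_matches_direct_formula(self, rng):
        x = rng.integers(0, 4, size=25).astype(float)
        y = rng.integers(0, 4, size=30).astype(float)
        u, z, p = mann_whitney_z(x, y)
        # independent oracle: explicit tie-corrected variance formula
        n1, n2 = len(x), len(y)
        n = n1 + n2
        pooled = np.concatenate([x, y])
        _, counts = np.unique(pooled, return_counts=True)
        tie = np.sum(counts.astype(float) ** 3 - counts)
        var = n1 * n2 / 12 * ((n + 1) - tie / (n * (n - 1)))
        r1 = sstats.rankdata(pooled)[:n1].sum()
        z_oracle = (r1 - n1 * (n1 + 1) / 2 - n1 * n2 / 2) / math.sqrt(var)
        assert z == pytest.approx(z_oracle, abs=1e-12)

    def test_p_agrees_with_scipy_asymptotic(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(0.5, 1.0, size=35)
        _, _, p = mann_whitney_z(x, y)
        ref = sstats.mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic", use_continuity=False)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    @pytest.mark.parametrize("x,y", [
        ([1, 2, 3], [4, 5, 6]),
        ([1, 5, 2, 8], [3, 3, 9]),
        ([2, 2, 2], [2, 2, 3, 4]),
        ([0.5, 1.5, 1.5, 4], [1.5, 2, 2, 6]),
    ])
    def test_z_matches_exact_enumeration_moments(self, x, y):
        # the tie-corrected variance formula must equal the exact variance
        # of U over all enumerated labelings, so Z = (U - mean)/sd exactly
        x, y = np.array(x, float), np.array(y, float)
        u, z, _ = mann_whitney_z(x, y)
        u_obs, mean_u, sd_u = mann_whitney_enumeration_moments(x, y)
        assert u == pytest.approx(u_obs, abs=1e-12)
        assert z == pytest.approx((u_obs - mean_u) / sd_u, abs=1e-12)

    def test_tiny_samples_rejected(self):
        with pytest.raises(ParameterError):
            mann_whitney_z([1.0], [2.0, 3.0])


class TestKruskalWallis:
    def test_identical_groups_give_zero(self):
        h, df, p = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert df == 2

    def test_textbook_formula_on_separated_groups(self):
        groups = [[1, 2], [3, 4], [5, 6]]
        h, df, p = kruskal_wallis(groups)
        # rank sums 3, 7, 11 over N=6 -> H = 12/(6*7) * sum(R^2/n) - 3*7
        h_oracle = 12 / (6 * 7) * (9 / 2 + 49 / 2 + 121 / 2) - 21
        assert h == pytest.approx(h_oracle, abs=1e-12)

    def test_group_order_invariance(self, rng):
        groups = [rng.normal(size=8), rng.normal(size=12), rng.normal(size=5)]
        h1, _, _ = kruskal_wallis(groups)
        h2, _, _ = kruskal_wallis(groups[::-1])
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_matches_scipy_with_ties(self, rng):
        groups = [rng.integers(0, 5, size=n).astype(float) for n in (10, 14, 9)]
        h, df, p = kruskal_wallis(groups)
        ref = sstats.kruskal(*groups)
        assert h == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ParameterError):
            kruskal_wallis([[1, 2, 3]])


class TestChiSquare:
    def test_independent_table_gives_zero(self):
        table = np.outer([50, 100], [0.3, 0.7]) * 2
        x2, df, p = chi_square(table)
        assert x2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_pearson_formula_oracle(self, rng):
        counts = rng.integers(5, 60, size=(3, 2)).astype(float)
        x2, df, p = chi_square(counts)
        expected = np.outer(counts.sum(1), counts.sum(0)) / counts.sum()
        x2_oracle = np.sum((counts - expected) ** 2 / expected)
        assert x2 == pytest.approx(x2_oracle, abs=1e-10)
        assert df == 2

    def test_zero_marginal_rejected(self):
        with pytest.raises(ParameterError):
            chi_square(np.array([[0, 5], [0, 7]]))

    def test_degenerate_shapes_rejected(self):
        with pytest.raises(ParameterError):
            ContingencyTable(np.array([[1, 2]]))
        with pytest.raises(ParameterError):
            ContingencyTable(np.array([[1, -2], [3, 4]]))


class TestAnovaFromSummary:
    def test_equal_means_give_zero_f(self):
        f, df1, df2, p = anova_from_summary([5, 5, 5], [1, 2, 1.5], [10, 12, 9])
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_matches_raw_data_anova(self, rng):
        groups = [rng.normal(loc, 1.0, size=n) for loc, n in [(0, 20), (0.5, 25), (1, 15)]]
        f, df1, df2, p = anova_from_summary(
            [g.mean() for g in groups], [g.std(ddof=1) for g in groups],
            [len(g) for g in groups],
        )
        ref = sstats.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_small_groups_rejected(self):
        with pytest.raises(ParameterError):
            anova_from_summary([1, 2], [1, 1], [1, 5])


class TestCompareGroups:
    def test_injected_shift_is_detected_with_direction(self):
        df = sample_feature_cohort(21, (200, 200, 200))
        results = {r.feature: r for r in compare_groups(df)}
        res = results["h3_h1"]
        u, z, p = res.pairwise[(1, 2)]
        assert res.significant_pairs[(1, 2)]
        assert z < 0  # group 1 ranks below group 2: increase in group 2

    def test_null_cohort_flags_near_alpha(self):
        flags = total = 0
        for seed in range(60):
            df = sample_feature_cohort(seed, (40, 40, 40), null=True)
            for r in compare_groups(df, feature_names=["h2_h1", "t_s", "mse1"]):
                flags += r.significant_omnibus
                total += 1
        rate = flags / total
        se = math.sqrt(0.05 * 0.95 / total)
        assert abs(rate - 0.05) <= 4 * se

    def test_single_group_rejected(self):
        df = sample_feature_cohort(0, (5, 5, 5))
        df["group"] = 1
        with pytest.raises(ParameterError):
            compare_groups(df)

    def test_summaries_respect_quartile_ordering(self):
        df = sample_feature_cohort(5, (30, 30, 30))
        for res in compare_groups(df):
            for g, (m, q1, q3) in res.summaries.items():
                assert q1 <= m <= q3
            assert 0 <= res.p_omnibus <= 1

    def test_report_frame_has_all_contrasts(self):
        df = sample_feature_cohort(2, (20, 20, 20))
        results = compare_groups(df, feature_names=["h2_h1", "mse1"])
        frame = comparison_frame(results)
        contrasts = set(frame["contrast"])
        assert {"group1", "group2", "group3", "omnibus",
                "group1_vs_group2", "group2_vs_group3",
                "group1_vs_group3"} <= contrasts
        assert len(frame) == 2 * 7
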
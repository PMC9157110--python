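"""ANOVA, Tukey HSD, compact letter display, t tests, fold changes."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from pollenomics.stats import (
    compact_letter_display,
    fold_change,
    group_stats,
    group_stats_table,
    one_way_anova,
    star_code,
    tukey_hsd,
    tukey_q,
    two_sample_t,
)


class TestAnova:
    def test_hand_computed_fixture(self):
        # SSB = 6 (df 2), SSW = 6 (df 6) -> F = 3/1 = 3
        f, p = one_way_anova([(1, 2, 3), (2, 3, 4), (3, 4, 5)])
        assert f == pytest.approx(3.0)
        assert 0 < p < 1

    def test_equal_means_zero_f(self):
        f, _ = one_way_anova([(1, 2, 3), (3, 1, 2), (2, 3, 1)])
        assert f == pytest.approx(0.0)

    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(size=6), rng.normal(1, 1, size=8)
        f, p_f = one_way_anova([a, b])
        t, p_t = two_sample_t(a, b)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_degenerate_zero_variance(self):
        f, p = one_way_anova([(1, 1), (1, 1)])
        assert np.isnan(f)
        f, p = one_way_anova([(1, 1), (2, 2)])
        assert np.isinf(f) and p == 0.0

    def test_group_size_preconditions(self):
        with pytest.raises(ValueError):
            one_way_anova([(1, 2)])
        with pytest.raises(ValueError):
            one_way_anova([(1,), (2, 3)])

    def test_matches_scipy(self, rng):
        groups = [rng.normal(m, 1, size=5) for m in (0, 0.5, 1)]
        from scipy.stats import f_oneway

        f, p = one_way_anova(groups)
        ref = f_oneway(*groups)
        assert f == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestTukey:
    FIXTURE = [(1, 2, 3), (10, 11, 12), (2, 3, 4)]

    def test_q_statistic_fixture(self):
        # MSE = 1, n = 3: q = 9 / sqrt(1/3) = 15.588
        assert tukey_q(self.FIXTURE, 0, 1) == pytest.approx(15.588, abs=1e-3)

    def test_identical_groups_p_one(self):
        p = tukey_hsd([(1, 2, 3), (1, 2, 3), (1, 2, 3)])
        off_diag = p.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.all(off_diag > 0.999)

    def test_adjusted_p_not_below_pairwise_t(self, rng):
        groups = [rng.normal(m, 1, size=5) for m in (0, 0.3, 0.8)]
        p_adj = tukey_hsd(groups)
        # Tukey adjusts for all k(k-1)/2 comparisons: adjusted p >= t-test p
        # on the same contrast (same pooled MSE makes this hold per theory;
        # the plain two-sample t is a slightly different denominator, so
        # compare against the pooled-MSE t oracle)
        from scipy.stats import t as t_dist

        k = len(groups)
        n = [len(g) for g in groups]
        df = sum(n) - k
        mse = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups) / df
        for i in range(k):
            for j in range(i + 1, k):
                se = np.sqrt(mse * (1 / n[i] + 1 / n[j]))
                t_stat = abs(np.mean(groups[i]) - np.mean(groups[j])) / se
                p_t = 2 * t_dist.sf(t_stat, df)
                assert p_adj.iloc[i, j] >= p_t - 1e-12

    def test_matches_statsmodels_tukeyhsd(self, rng):
        groups = [rng.normal(m, 1, size=5) for m in (0, 1, 2, 0.5)]
        ours = tukey_hsd(groups)
        values = np.concatenate(groups)
        labels = np.repeat(np.arange(4), 5)
        ref = pairwise_tukeyhsd(values, labels)
        idx = 0
        for i in range(4):
            for j in range(i + 1, 4):
                assert ours.iloc[i, j] == pytest.approx(
                    ref.pvalues[idx], abs=1e-6
                )
                idx += 1

    def test_degenerate_mse(self):
        p = tukey_hsd([(1.0, 1.0), (2.0, 2.0), (1.0, 1.0)])
        assert p.iloc[0, 1] == 0.0
        assert p.iloc[0, 2] == 1.0

    def test_monotone_in_mean_difference(self):
        base = [(0.0, 1.0, 2.0), (0.0, 1.0, 2.0)]
        p_prev = 1.0
        for shift in (0.5, 1.0, 2.0, 4.0):
            groups = [base[0], tuple(x + shift for x in base[1])]
            p = tukey_hsd(groups).iloc[0, 1]
            assert p <= p_prev + 1e-12
            p_prev = p


class TestCld:
    def test_no_significant_pairs_single_letter(self):
        p = np.ones((3, 3))
        assert compact_letter_display(p) == {0: "a", 1: "a", 2: "a"}

    def test_all_pairs_significant_distinct_letters(self):
        p = np.full((3, 3), 0.001)
        np.fill_diagonal(p, 1.0)
        letters = compact_letter_display(p, means=[3, 2, 1])
        assert sorted(letters.values()) == ["a", "b", "c"]
        assert letters[0] == "a"  # highest mean gets 'a'

    def test_only_extremes_differ(self):
        p = np.array([[1.0, 0.5, 0.01], [0.5, 1.0, 0.5], [0.01, 0.5, 1.0]])
        letters = compact_letter_display(p, labels=[1, 2, 3])
        assert letters == {1: "a", 2: "ab", 3: "b"}

    def test_sharing_matches_significance_brute_force(self, rng):
        """Letter sharing must equal non-significance for random matrices."""
        for _ in range(100):
            k = int(rng.integers(3, 7))
            p = np.ones((k, k))
            iu = np.triu_indices(k, 1)
            vals = rng.random(len(iu[0]))
            p[iu] = vals
            p[(iu[1], iu[0])] = vals
            letters = compact_letter_display(p, alpha=0.05)
            for i in range(k):
                for j in range(i + 1, k):
                    share = bool(set(letters[i]) & set(letters[j]))
                    assert share == (p[i, j] > 0.05), (p[i, j], letters)

    def test_asymmetric_matrix_rejected(self):
        p = np.array([[1.0, 0.2], [0.3, 1.0]])
        with pytest.raises(ValueError):
            compact_letter_display(p)


class TestTwoSampleT:
    def test_identical_groups(self):
        t, p = two_sample_t((1, 2, 3), (1, 2, 3))
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_degenerate_separation(self):
        t, p = two_sample_t((0, 0, 0), (1, 1, 1))
        assert p == 0.0
        assert star_code(p) == "***"

    def test_star_thresholds(self):
        assert star_code(0.04) == "*"
        assert star_code(0.009) == "**"
        assert star_code(0.004) == "***"
        assert star_code(0.06) == ""

    def test_pooled_t_matches_permutation_oracle(self, rng):
        """Student t p approximates the permutation null for normal data."""
        from itertools import combinations

        a = rng.normal(0, 1, size=5)
        b = rng.normal(1.0, 1, size=5)
        t_obs, p_t = two_sample_t(a, b)
        pooled = np.concatenate([a, b])
        # exhaustive permutation distribution of |mean difference|
        diffs = []
        idx = set(range(10))
        obs = abs(a.mean() - b.mean())
        count = 0
        total = 0
        for comb in combinations(range(10), 5):
            left = pooled[list(comb)]
            right = pooled[list(idx - set(comb))]
            total += 1
            if abs(left.mean() - right.mean()) >= obs - 1e-12:
                count += 1
        p_perm = count / total
        assert p_t == pytest.approx(p_perm, abs=0.06)

    def test_welch_variant(self, rng):
        from scipy.stats import ttest_ind

        a, b = rng.normal(size=6), rng.normal(0, 3, size=9)
        t, p = two_sample_t(a, b, variant="welch")
        ref = ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestFoldChange:
    def test_equal_means(self):
        ratio, log2 = fold_change((1, 2, 3), (3, 2, 1))
        assert ratio == pytest.approx(1.0)
        assert log2 == pytest.approx(0.0)

    def test_reported_ratio(self):
        ratio, _ = fold_change((580, 580), (100, 100))
        assert ratio == pytest.approx(5.8)

    def test_reciprocal_identity(self):
        a, b = (2, 4, 6), (1, 3, 5)
        r1, _ = fold_change(a, b)
        r2, _ = fold_change(b, a)
        assert r1 * r2 == pytest.approx(1.0)

    def test_zero_denominator_flagged(self):
        ratio, log2 = fold_change((1, 2), (0, 0))
        assert np.isnan(ratio) and np.isnan(log2)


class TestGroupStats:
    def test_letters_consistent_with_pairwise_matrix(self):
        gs = group_stats(
            [(1, 2, 3), (10, 11, 12), (2, 3, 4)], labels=["a1", "a2", "a3"]
        )
        p = gs.pairwise_p
        for i, li in enumerate(gs.labels):
            for j, lj in enumerate(gs.labels):
                if i >= j:
                    continue
                share = bool(set(gs.letters[li]) & set(gs.letters[lj]))
                assert share == (p.iloc[i, j] > gs.alpha)

    def test_table_over_conditions(self):
        sheet = pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(6)],
                "condition": ["RT3"] * 3 + ["HS3+3"] * 3,
            }
        )
        values = pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(6)],
                "feature": ["x"] * 6,
                "value": [1.0, 1.1, 0.9, 5.0, 5.1, 4.9],
            }
        )
        out = group_stats_table(values, sheet, ["feature"], "value")
        assert len(out) == 1
        letters = dict(
            item.split("=") for item in out["letters"].iloc[0].split(";")
        )
        assert letters["RT3"] != letters["HS3+3"]
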
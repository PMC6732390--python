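"""Permutation tests and bootstrap CIs against enumeration oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

from dimorphtrade import (
    bootstrap_ci,
    perm_anova,
    perm_corr_test,
    perm_mean_zero_test,
    perm_sex_diff_test,
)


def exact_corr_p(x, y):
    """Exhaustive two-sided permutation p for Pearson r (tiny n only)."""
    r_obs = abs(stats.pearsonr(x, y)[0])
    perms = list(itertools.permutations(y))
    count = sum(abs(stats.pearsonr(x, np.array(p))[0]) >= r_obs - 1e-12
                for p in perms)
    return count / len(perms)


class TestPermCorr:
    def test_identical_vectors_hit_floor(self):
        # n = 12 so the only permutations tying |r| = 1 (identity and exact
        # reversal) are essentially never drawn; p sits at the add-one floor
        x = np.arange(12.0)
        res = perm_corr_test(x, x, n_perm=999, seed=0)
        assert res.observed_stat == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_matches_exhaustive_enumeration_n5(self, rng):
        x = rng.normal(size=5)
        y = 0.8 * x + rng.normal(size=5)
        p_exact = exact_corr_p(x, y)
        res = perm_corr_test(x, y, n_perm=4000, seed=1)
        se = np.sqrt(p_exact * (1 - p_exact) / 4000)
        assert abs(res.p_value - p_exact) < 4 * se + 2 / 4000

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            perm_corr_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_reproducible_under_seed(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=8)
        a = perm_corr_test(x, y, n_perm=500, seed=42)
        b = perm_corr_test(x, y, n_perm=500, seed=42)
        assert a.p_value == b.p_value and a.null_quantiles == b.null_quantiles


class TestPermSexDiff:
    def test_identical_sexes_give_zero_and_p_near_one(self):
        vals = np.array([0.1, 0.2, 0.3, 0.1, 0.2, 0.3])
        sexes = np.array(["female"] * 3 + ["male"] * 3)
        res = perm_sex_diff_test(vals, sexes, n_perm=999, seed=0)
        assert res.observed_stat == pytest.approx(0.0)
        assert res.p_value > 0.5

    def test_matches_enumeration_3v3(self, rng):
        vals = rng.normal(size=6)
        vals[:3] += 1.0
        sexes = np.array(["female"] * 3 + ["male"] * 3)
        obs = vals[:3].mean() - vals[3:].mean()
        # enumerate all C(6,3) = 20 relabelings
        count = 0
        combos = list(itertools.combinations(range(6), 3))
        for c in combos:
            f = vals[list(c)]
            m = vals[[i for i in range(6) if i not in c]]
            if abs(f.mean() - m.mean()) >= abs(obs) - 1e-12:
                count += 1
        p_exact = count / len(combos)
        res = perm_sex_diff_test(vals, sexes, n_perm=4000, seed=3)
        se = np.sqrt(p_exact * (1 - p_exact) / 4000)
        assert abs(res.p_value - p_exact) < 4 * se + 2 / 4000

    def test_huge_effect_hits_floor(self, rng):
        vals = np.concatenate([rng.normal(10, 0.1, 5), rng.normal(0, 0.1, 5)])
        sexes = np.array(["female"] * 5 + ["male"] * 5)
        res = perm_sex_diff_test(vals, sexes, n_perm=999, seed=0)
        assert res.p_value < 0.02

    def test_missing_sex_errors(self):
        with pytest.raises(ValueError, match="each sex"):
            perm_sex_diff_test([1.0, 2.0, 3.0], ["female", "female", "male"])


class TestPermMeanZero:
    def test_symmetric_pairs_give_zero(self):
        res = perm_mean_zero_test([0.5, -0.5, 0.2, -0.2], n_perm=999, seed=0)
        assert res.observed_stat == pytest.approx(0.0)
        assert res.p_value > 0.5

    def test_matches_sign_flip_enumeration_n4(self, rng):
        diffs = rng.normal(0.3, 0.5, size=4)
        obs = abs(diffs.mean())
        count = sum(abs((np.array(s) * diffs).mean()) >= obs - 1e-12
                    for s in itertools.product([-1, 1], repeat=4))
        p_exact = count / 16
        res = perm_mean_zero_test(diffs, n_perm=8000, seed=5)
        se = np.sqrt(p_exact * (1 - p_exact) / 8000)
        assert abs(res.p_value - p_exact) < 4 * se + 2 / 8000

    def test_all_same_sign_n10_near_floor(self, rng):
        diffs = np.abs(rng.normal(1.0, 0.1, size=10))
        res = perm_mean_zero_test(diffs, n_perm=20000, seed=7)
        # exact sign-flip p is near 2/2^10 (both all-plus and all-minus
        # patterns reach |mean|; nearby patterns may too)
        assert res.p_value < 0.01


class TestPermAnova:
    def test_shifted_group_hits_floor(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 6), rng.normal(10, 1, 6)])
        groups = np.array(["a"] * 6 + ["b"] * 6)
        res = perm_anova(vals, groups, n_perm=999, seed=0, pairwise=False)
        assert res.p_value < 0.02

    def test_matches_enumeration_6_species_2_groups(self, rng):
        vals = rng.normal(size=6)
        groups = np.array(["a", "a", "a", "b", "b", "b"])

        def F(v, g):
            return stats.f_oneway(v[g == "a"], v[g == "b"]).statistic

        obs = F(vals, groups)
        perms = set(itertools.permutations(groups))
        count = sum(F(vals, np.array(p)) >= obs - 1e-12 for p in perms)
        p_exact = count / len(perms)
        res = perm_anova(vals, groups, n_perm=4000, seed=2, pairwise=False)
        assert res.observed_stat == pytest.approx(obs)
        se = np.sqrt(p_exact * (1 - p_exact) / 4000)
        assert abs(res.p_value - p_exact) < 4 * se + 2 / 4000

    def test_observed_f_matches_scipy(self, rng):
        vals = rng.normal(size=15)
        groups = np.array(["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        res, pairs = perm_anova(vals, groups, n_perm=100, seed=0)
        expected = stats.f_oneway(vals[:5], vals[5:10], vals[10:]).statistic
        assert res.observed_stat == pytest.approx(expected)
        assert set(pairs) == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_small_group_errors(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            perm_anova([1.0, 2.0, 3.0], ["a", "a", "b"], n_perm=10)


class TestBootstrapCI:
    def test_constant_values_zero_width(self):
        ci = bootstrap_ci([2.0, 2.0, 2.0, 2.0], np.mean, n_boot=200, seed=0)
        assert ci.lower == ci.point == ci.upper == 2.0

    def test_normal_width_matches_asymptotics(self, rng):
        vals = rng.normal(0, 1, 100)
        ci = bootstrap_ci(vals, np.mean, n_boot=4000, seed=1)
        width = ci.upper - ci.lower
        expected = 2 * 1.96 * vals.std(ddof=1) / 10
        assert abs(width - expected) / expected < 0.2

    def test_ci_contains_point(self, rng):
        for seed in range(5):
            vals = rng.normal(size=12)
            ci = bootstrap_ci(vals, np.median, n_boot=500, seed=seed)
            assert ci.lower <= ci.point <= ci.upper


def test_add_one_pvalues_never_zero(rng):
    """All four tests respect the 1/(n_perm + 1) floor."""
    x = np.arange(10.0)
    results = [
        perm_corr_test(x, x, n_perm=99, seed=0),
        perm_sex_diff_test(np.r_[np.zeros(5), np.ones(5) * 9],
                           np.array(["female"] * 5 + ["male"] * 5),
                           n_perm=99, seed=0),
        perm_mean_zero_test(np.ones(12), n_perm=99, seed=0),
        perm_anova(np.r_[np.zeros(5), np.ones(5) * 9],
                   np.array(["a"] * 5 + ["b"] * 5), n_perm=99, seed=0,
                   pairwise=False),
    ]
    for res in results:
        assert res.p_value >= 1 / 100
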
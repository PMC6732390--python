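"""BM covariance, Pagel's lambda transform, PGLS and phylogenetic ANOVA."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from dimorphtrade import (
    bm_covariance,
    lambda_transform,
    pgls_fit,
    phyl_anova,
    read_newick,
)
from dimorphtrade.simulate import simulate_bm_trait, simulate_yule_tree


def brute_force_covariance(tree):
    """Oracle: C_ij = length of the shared root->tip path (edge intersection)."""
    paths = {}

    def walk(node, edges):
        for ch in node.child_nodes():
            e = edges + [(id(ch), ch.edge.length)]
            if ch.is_leaf():
                paths[ch.taxon.label] = e
            else:
                walk(ch, e)

    seed = tree.tree.seed_node
    stem = [(id(seed), seed.edge.length)] if seed.edge.length else []
    walk(seed, stem)
    labels = sorted(paths)
    n = len(labels)
    C = np.zeros((n, n))
    for i, a in enumerate(labels):
        ids_a = {eid for eid, _ in paths[a]}
        for j, b in enumerate(labels):
            C[i, j] = sum(l for eid, l in paths[b] if eid in ids_a)
    return labels, C


class TestBMCovariance:
    def test_star_tree_is_diagonal(self):
        tree = read_newick("(A:3,B:3,C:3,D:3);")
        cov = bm_covariance(tree)
        np.testing.assert_allclose(cov.C, 3.0 * np.eye(4))

    def test_hand_example(self, tree3):
        cov = bm_covariance(tree3).sub(["A", "B", "C"])
        expected = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        np.testing.assert_allclose(cov.C, expected)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_brute_force_on_random_trees(self, seed):
        tree = simulate_yule_tree(12, seed=seed)
        labels, C_oracle = brute_force_covariance(tree)
        cov = bm_covariance(tree).sub(labels)
        np.testing.assert_allclose(cov.C, C_oracle, atol=1e-12)


class TestLambdaTransform:
    def test_identity_at_one(self, tree3):
        cov = bm_covariance(tree3)
        np.testing.assert_allclose(lambda_transform(cov, 1.0).C, cov.C)

    def test_diagonal_at_zero(self, tree3):
        cov = bm_covariance(tree3)
        out = lambda_transform(cov, 0.0).C
        np.testing.assert_allclose(out, np.diag(np.diag(cov.C)))

    def test_out_of_bounds_errors(self, tree3):
        cov = bm_covariance(tree3)
        for bad in (-0.1, 1.1):
            with pytest.raises(ValueError):
                lambda_transform(cov, bad)

    @pytest.mark.parametrize("lam", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_stays_positive_definite(self, lam):
        tree = simulate_yule_tree(20, seed=9)
        C = lambda_transform(bm_covariance(tree), lam).C
        assert np.linalg.eigvalsh(C).min() > 0


class TestPGLS:
    def _data(self, n=40, seed=5):
        g = np.random.default_rng(seed)
        tree = simulate_yule_tree(n, seed=seed)
        cov = bm_covariance(tree)
        x = g.normal(size=n)
        y = 1.0 + 0.5 * x + g.normal(0, 0.5, n)
        X = np.column_stack([np.ones(n), x])
        return tree, cov, X, y

    def test_lambda_zero_on_ultrametric_tree_equals_ols(self):
        tree, cov, X, y = self._data()
        fit = pgls_fit(y, X, cov, lambda_mode="fixed", lambda_fixed=0.0)
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.coefficients, ols.params, atol=1e-10)
        assert fit.r_squared == pytest.approx(ols.rsquared, abs=1e-10)
        assert fit.p_value_slope == pytest.approx(ols.pvalues[1], abs=1e-10)

    def test_star_tree_any_lambda_equals_ols(self):
        tree = read_newick("(A:2,B:2,C:2,D:2,E:2,F:2,G:2,H:2);")
        g = np.random.default_rng(0)
        x = g.normal(size=8)
        y = 2.0 - 0.7 * x + g.normal(0, 0.3, 8)
        X = np.column_stack([np.ones(8), x])
        ols = sm.OLS(y, X).fit()
        for lam in (0.0, 0.5, 1.0):
            fit = pgls_fit(y, X, bm_covariance(tree), lambda_mode="fixed",
                           lambda_fixed=lam)
            np.testing.assert_allclose(fit.coefficients, ols.params, atol=1e-10)

    def test_loglik_maximized_at_lambda_hat(self):
        tree = simulate_yule_tree(40, seed=3)
        cov = bm_covariance(tree)
        g = np.random.default_rng(3)
        # half-BM residuals so lambda_hat lands in the interior
        L = np.linalg.cholesky(lambda_transform(cov, 0.6).C)
        y = 1.0 + L @ g.standard_normal(40)
        X = np.ones((40, 1))
        fit = pgls_fit(y, X, cov, lambda_mode="ML")
        for lam in (0.0, 0.5, 1.0):
            alt = pgls_fit(y, X, cov, lambda_mode="fixed", lambda_fixed=lam)
            assert fit.log_likelihood >= alt.log_likelihood - 1e-8

    def test_singular_design_errors(self):
        tree, cov, X, y = self._data()
        Xs = np.column_stack([X, X[:, 1]])
        with pytest.raises(ValueError, match="singular"):
            pgls_fit(y, Xs, cov)

    def test_lambda_recovery_small(self):
        """Quick recovery check (the full 100-tip run lives in acceptance)."""
        tree = simulate_yule_tree(60, seed=17)
        cov = bm_covariance(tree)
        L = np.linalg.cholesky(cov.C)
        g = np.random.default_rng(17)
        lams_bm, lams_iid = [], []
        sd = np.sqrt(np.diag(cov.C))
        for _ in range(20):
            y_bm = 1.0 + L @ g.standard_normal(60)
            y_iid = 1.0 + sd * g.standard_normal(60)
            X = np.ones((60, 1))
            lams_bm.append(pgls_fit(y_bm, X, cov).lambda_)
            lams_iid.append(pgls_fit(y_iid, X, cov).lambda_)
        assert np.median(lams_bm) > 0.8
        assert np.median(lams_iid) < 0.2


class TestPhylAnova:
    def test_f_obs_matches_scipy(self):
        tree = simulate_yule_tree(18, seed=2)
        cov = bm_covariance(tree)
        g = np.random.default_rng(2)
        trait = g.normal(size=18)
        groups = np.array(["a"] * 6 + ["b"] * 6 + ["c"] * 6)
        res = phyl_anova(trait, groups, cov, n_sim=200, seed=0)
        expected = stats.f_oneway(trait[:6], trait[6:12], trait[12:]).statistic
        assert res.F_obs == pytest.approx(expected)
        assert set(res.pairwise_p) == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_constant_trait_errors(self):
        tree = read_newick("(A:1,B:1,C:1,D:1);")
        with pytest.raises(ValueError, match="constant"):
            phyl_anova(np.ones(4), np.array(["a", "a", "b", "b"]),
                       bm_covariance(tree), n_sim=10)

    def test_small_group_errors(self):
        tree = simulate_yule_tree(5, seed=1)
        with pytest.raises(ValueError, match="fewer than 2"):
            phyl_anova(np.arange(5.0), np.array(["a"] * 4 + ["b"]),
                       bm_covariance(tree), n_sim=10)

    def test_agrees_with_permutation_p_for_iid_trait(self):
        """Random groups + iid trait: phylogenetic and permutation p agree."""
        from dimorphtrade import perm_anova

        tree = read_newick("(" + ",".join(f"t{i}:1" for i in range(24)) + ");")
        cov = bm_covariance(tree)  # star tree: BM null is iid
        g = np.random.default_rng(8)
        diffs = []
        for _ in range(10):
            trait = g.normal(size=24)
            groups = np.array(["a"] * 12 + ["b"] * 12)
            p_phylo = phyl_anova(trait, groups, cov, n_sim=600, seed=g).p_phylo
            p_perm = perm_anova(trait, groups, n_perm=600, seed=g,
                                pairwise=False).p_value
            diffs.append(p_phylo - p_perm)
        assert np.mean(np.abs(diffs)) < 0.1

    def test_reproducible_under_seed(self):
        tree = simulate_yule_tree(12, seed=4)
        cov = bm_covariance(tree)
        trait = np.arange(12.0)
        groups = np.array(["a", "b"] * 6)
        r1 = phyl_anova(trait, groups, cov, n_sim=300, seed=99)
        r2 = phyl_anova(trait, groups, cov, n_sim=300, seed=99)
        assert r1.p_phylo == r2.p_phylo and r1.pairwise_p == r2.pairwise_p
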
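import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from thermotree.errors import InvalidComparisonError
from thermotree.phylo import (
    ancestral_states,
    blomberg_k,
    compare_models,
    fit_ou_optimum,
    pagel_lambda,
    pgls_fit,
    phylo_correlogram,
    variance_partition,
)
from thermotree.synthdata import (
    TraitParams,
    simulate_trait_lambda,
    simulate_trait_ou,
    simulate_tree,
)
from thermotree.trees import CalibratedTree


def dense_bm_cov(tree: CalibratedTree):
    """Independent oracle: element-wise shared-path-length matrix."""
    labels = tree.tip_labels
    depths = tree.node_depths()
    nodes = list(tree.tree.preorder_node_iter())
    # ancestors per tip
    anc = {}
    for leaf in tree.tree.leaf_node_iter():
        chain = []
        nd = leaf
        while nd is not None:
            chain.append(nd)
            nd = nd.parent_node
        anc[leaf.taxon.label] = chain
    n = len(labels)
    C = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            shared = [nd for nd in anc[a] if nd in anc[b]]
            C[i, j] = max(depths[nd] for nd in shared)
    return labels, C


class TestAncestralStates:
    def test_symmetric_two_tip_root_is_midpoint(self):
        tree = CalibratedTree.from_newick("(t1:1,t2:1)root;")
        est = ancestral_states(tree, pd.Series({"t1": 40.0, "t2": 44.0}))
        assert est.loc["root", "estimate"] == pytest.approx(42.0)

    def test_star_tree_root_is_mean(self, star_five):
        y = pd.Series({f"t{i}": v for i, v in enumerate([40, 41, 43, 45, 46], 1)})
        est = ancestral_states(star_five, y)
        assert est["estimate"].iloc[0] == pytest.approx(43.0)

    def test_root_matches_dense_gls_oracle(self, five_tip_asym):
        y = pd.Series({"a": 40.0, "b": 41.5, "c": 44.0, "d": 39.0, "e": 42.0})
        labels, C = dense_bm_cov(five_tip_asym)
        Ci = np.linalg.inv(C)
        one = np.ones(5)
        yv = y.reindex(labels).to_numpy()
        expected = (one @ Ci @ yv) / (one @ Ci @ one)
        est = ancestral_states(five_tip_asym, y)
        assert est["estimate"].iloc[0] == pytest.approx(expected, abs=1e-8)

    def test_missing_tip_values_rejected(self, balanced_four):
        with pytest.raises(ValueError, match="t4"):
            ancestral_states(
                balanced_four, pd.Series({"t1": 1.0, "t2": 2.0, "t3": 3.0})
            )


class TestPagelLambda:
    def test_bm_trait_recovers_high_lambda(self):
        lams = []
        for rep in range(6):
            tree = simulate_tree(200, seed=50 + rep)
            y = simulate_trait_lambda(tree, 1.0, seed=rep)
            lams.append(pagel_lambda(tree, y).lambda_hat)
        assert np.mean(lams) > 0.9

    def test_shuffled_trait_destroys_signal(self):
        rng = np.random.default_rng(0)
        lams = []
        for rep in range(6):
            tree = simulate_tree(200, seed=60 + rep)
            y = simulate_trait_lambda(tree, 1.0, seed=100 + rep)
            shuffled = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            lams.append(pagel_lambda(tree, shuffled).lambda_hat)
        assert np.mean(lams) < 0.15

    def test_lambda_one_likelihood_equals_bm_pgls(self):
        tree = simulate_tree(50, seed=70)
        y = simulate_trait_lambda(tree, 1.0, seed=7)
        lam = pagel_lambda(tree, y)
        bm = pgls_fit(tree, y, None, "BM")
        if lam.lambda_hat > 0.999:
            assert lam.loglik == pytest.approx(bm.loglik, abs=1e-4)
        # the profile at lambda=1 must equal the BM likelihood regardless
        from thermotree.phylo import _profile_gls

        labels, C = tree.bm_covariance()
        ll1 = _profile_gls(
            np.ones((50, 1)), y.reindex(labels).to_numpy(), C
        )[2]
        assert ll1 == pytest.approx(bm.loglik, abs=1e-10)


class TestBlombergK:
    def test_zero_permutations_rejected(self, balanced_four):
        y = pd.Series({"t1": 1.0, "t2": 2.0, "t3": 3.0, "t4": 4.0})
        with pytest.raises(ValueError):
            blomberg_k(balanced_four, y, n_perm=0)

    def test_bm_trait_k_near_one(self):
        ks = []
        for rep in range(30):
            tree = simulate_tree(80, seed=200 + rep)
            y = simulate_trait_lambda(tree, 1.0, seed=300 + rep)
            ks.append(blomberg_k(tree, y, n_perm=1, seed=rep).k_hat)
        assert 0.8 < np.mean(ks) < 1.2

    def test_shuffled_trait_p_not_small(self):
        rng = np.random.default_rng(1)
        ps = []
        for rep in range(20):
            tree = simulate_tree(60, seed=400 + rep)
            y = rng.normal(size=60)  # no phylogenetic structure at all
            ps.append(blomberg_k(tree, y, n_perm=99, seed=rep).p_value)
        assert np.median(ps) > 0.3


class TestCorrelogram:
    def test_signal_decays_with_distance(self):
        tree = simulate_tree(120, seed=500)
        y = simulate_trait_ou(
            tree, TraitParams(beta0=0, beta_elev=0, alpha=2.0, sigma2=4.0),
            np.zeros(120), seed=5,
        )
        cg = phylo_correlogram(tree, y, n_classes=4, n_perm=49, seed=0)
        assert cg["moran_i"].iloc[0] > cg["moran_i"].iloc[-1]

    def test_shuffled_trait_flat(self):
        tree = simulate_tree(120, seed=501)
        y = np.random.default_rng(2).normal(size=120)
        cg = phylo_correlogram(tree, y, n_classes=4, n_perm=49, seed=0)
        assert np.all(np.abs(cg["moran_i"]) < 0.25)

    def test_two_tips_insufficient(self):
        tree = CalibratedTree.from_newick("(t1:1,t2:1);")
        with pytest.raises(ValueError):
            phylo_correlogram(tree, pd.Series({"t1": 1.0, "t2": 2.0}))


class TestPGLS:
    def test_star_model_equals_ols(self):
        tree = simulate_tree(40, seed=600)
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = pd.Series(2.0 + 0.5 * x + rng.normal(0, 0.3, 40),
                      index=tree.tip_labels)
        pred = pd.DataFrame({"x": x}, index=tree.tip_labels)
        fit = pgls_fit(tree, y, pred, "star")
        ols = sm.OLS(y.to_numpy(), sm.add_constant(x)).fit()
        np.testing.assert_allclose(
            fit.coef.to_numpy(), ols.params, atol=1e-8
        )

    def test_bm_fit_matches_dense_gls_oracle(self, five_tip_asym):
        y = pd.Series({"a": 40.0, "b": 41.5, "c": 44.0, "d": 39.0, "e": 42.0})
        pred = pd.DataFrame(
            {"elev": [100.0, 900.0, 300.0, 1200.0, 700.0]},
            index=["a", "b", "c", "d", "e"],
        )
        fit = pgls_fit(five_tip_asym, y, pred, "BM")
        labels, C = dense_bm_cov(five_tip_asym)
        Ci = np.linalg.inv(C)
        X = np.column_stack(
            [np.ones(5), pred["elev"].reindex(labels).to_numpy()]
        )
        yv = y.reindex(labels).to_numpy()
        beta = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ yv)
        np.testing.assert_allclose(fit.coef.to_numpy(), beta, atol=1e-8)

    def test_large_alpha_ou_approaches_star(self):
        tree = simulate_tree(40, seed=601, depth=1.0)
        rng = np.random.default_rng(4)
        y = pd.Series(rng.normal(40, 2, 40), index=tree.tip_labels)
        star = pgls_fit(tree, y, None, "star")
        # with iid data the OU alpha runs high and the fits coincide
        ou = pgls_fit(tree, y, None, "OU")
        assert ou.coef["intercept"] == pytest.approx(
            star.coef["intercept"], abs=1e-3
        )

    def test_aic_counts_parameters(self):
        tree = simulate_tree(30, seed=602)
        y = simulate_trait_lambda(tree, 1.0, seed=9)
        bm = pgls_fit(tree, y, None, "BM")
        ou = pgls_fit(tree, y, None, "OU")
        assert bm.aic == pytest.approx(2 * 2 - 2 * bm.loglik)
        assert ou.aic == pytest.approx(2 * 3 - 2 * ou.loglik)


class TestOUOptimum:
    def test_constant_trait_degenerate(self, balanced_four):
        y = pd.Series({"t1": 41.0, "t2": 41.0, "t3": 41.0, "t4": 41.0})
        fit = fit_ou_optimum(balanced_four, y)
        assert fit.theta == pytest.approx(41.0)
        assert fit.sigma2 == pytest.approx(0.0)

    def test_theta_equals_gls_mean_at_fitted_alpha(self):
        tree = simulate_tree(60, seed=700)
        y = simulate_trait_ou(
            tree, TraitParams(beta0=42.2, beta_elev=0, alpha=3, sigma2=6),
            np.zeros(60), seed=11,
        )
        fit = fit_ou_optimum(tree, y)
        labels, D = tree.patristic_matrix()
        V = np.exp(-fit.alpha * D)
        np.fill_diagonal(V, 1.0)
        Vi = np.linalg.inv(V)
        one = np.ones(60)
        yv = y.reindex(labels).to_numpy()
        expected = (one @ Vi @ yv) / (one @ Vi @ one)
        assert fit.theta == pytest.approx(expected, abs=1e-6)


class TestModelComparison:
    def test_identical_fits_tie_break_alphabetical(self):
        tree = simulate_tree(30, seed=800)
        y = simulate_trait_lambda(tree, 1.0, seed=12)
        bm = pgls_fit(tree, y, None, "BM")
        bm2 = pgls_fit(tree, y, None, "BM")
        ranked = compare_models([bm2, bm])
        assert list(ranked["delta_aic"]) == [0.0, 0.0]

    def test_mixed_sample_sizes_rejected(self):
        t1, t2 = simulate_tree(20, seed=801), simulate_tree(25, seed=802)
        f1 = pgls_fit(t1, simulate_trait_lambda(t1, 1.0, seed=1), None, "BM")
        f2 = pgls_fit(t2, simulate_trait_lambda(t2, 1.0, seed=2), None, "BM")
        with pytest.raises(InvalidComparisonError):
            compare_models([f1, f2])

    def test_ou_data_prefers_ou_model(self):
        wins = 0
        reps = 25
        for rep in range(reps):
            tree = simulate_tree(150, seed=900 + rep)
            y = simulate_trait_ou(
                tree, TraitParams(beta0=0, beta_elev=0, alpha=3.0, sigma2=6.0),
                np.zeros(150), seed=950 + rep,
            )
            bm = pgls_fit(tree, y, None, "BM")
            ou = pgls_fit(tree, y, None, "OU")
            wins += ou.aic < bm.aic
        assert wins / reps >= 0.8

    def test_bm_data_keeps_bm_competitive(self):
        close = 0
        reps = 15
        for rep in range(reps):
            tree = simulate_tree(100, seed=980 + rep)
            y = simulate_trait_lambda(tree, 1.0, seed=990 + rep)
            bm = pgls_fit(tree, y, None, "BM")
            ou = pgls_fit(tree, y, None, "OU")
            close += bm.aic <= min(bm.aic, ou.aic) + 2.0
        assert close / reps >= 0.7


class TestVariancePartition:
    def test_noise_predictor_contributes_nothing(self):
        tree = simulate_tree(100, seed=1000)
        y = simulate_trait_lambda(tree, 1.0, seed=20)
        rng = np.random.default_rng(21)
        pred = pd.DataFrame(
            {"noise": rng.normal(size=100)}, index=tree.tip_labels
        )
        parts = variance_partition(tree, y, pred, "BM")
        assert parts["noise"] < 0.02

    def test_independent_data_matches_classical_r2(self):
        tree = simulate_tree(150, seed=1001)
        rng = np.random.default_rng(22)
        x = rng.normal(size=150)
        y = pd.Series(1.0 + 0.8 * x + rng.normal(0, 1.0, 150),
                      index=tree.tip_labels)
        pred = pd.DataFrame({"x": x}, index=tree.tip_labels)
        parts = variance_partition(tree, y, pred, "OU")
        ols = sm.OLS(y.to_numpy(), sm.add_constant(x)).fit()
        assert parts["x"] == pytest.approx(ols.rsquared, abs=0.02)
        assert parts["phylogeny"] < 0.05
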
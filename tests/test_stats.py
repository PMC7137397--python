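"""Ring Index, class totals, PCA, imputation, CCA and tree operations."""

import numpy as np
import pandas as pd
import pytest

from archaeolipid.quantify import QUANT, CompositionProfile
from archaeolipid.simulate import simulate_env_lipid
from archaeolipid.stats import (
    ImputationConvergenceError,
    cca,
    class_totals,
    composition_tree,
    impute_iterative_pca,
    multiple_impute,
    pca,
    ring_index,
    significance_stars,
    tree_congruence,
)


class TestRingIndex:
    def test_acyclic_profile_scores_zero(self):
        assert ring_index({"GDGT-0": 50.0, "GMGT-0": 30.0, "GTGT-0": 20.0}) == 0.0

    def test_pure_four_ring_profile_scores_four(self):
        assert ring_index({"GDGT-4": 100.0}) == 4.0

    def test_reference_strain_row_by_hand(self, profiles):
        # hand evaluation of the formula on the printed P. furiosus row:
        # (2.4+4.4+0.1+2*0.8+3*0.2)/(11.7+38.9+2.2+2.4+4.4+0.1+0.8+0.2)
        pf = next(p for p in profiles if p.strain == "Pyrococcus furiosus")
        assert ring_index(pf) == pytest.approx(0.150, abs=0.001)

    def test_no_tetraethers_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            ring_index({"DGD": 100.0})

    def test_diethers_do_not_enter_the_formula(self):
        with_dgd = ring_index({"DGD": 50.0, "GDGT-1": 25.0, "GDGT-0": 25.0})
        without = ring_index({"GDGT-1": 25.0, "GDGT-0": 25.0})
        assert with_dgd == pytest.approx(without)

    def test_fixture_ring_indices_bounded(self, class_totals):
        # no strain exceeds the most ring-rich profiles (~0.15)
        ri = class_totals["ri"].dropna()
        assert ((ri >= 0) & (ri <= 0.2)).all()


class TestClassTotals:
    def test_reference_strain_gmgt_pool(self, profiles):
        pf = next(p for p in profiles if p.strain == "Pyrococcus furiosus")
        ct = class_totals(pf)
        assert ct.gmgt == pytest.approx(38.9 + 4.4)

    def test_pure_diether_profile_has_undefined_ri(self):
        ct = class_totals(CompositionProfile("x", {"DGD": 100.0}, {"DGD": QUANT}))
        assert ct.dgd == 100.0
        assert ct.ri is None

    def test_totals_conserve_closure(self, class_totals):
        sums = class_totals[["dgd", "gdgt", "gmgt", "gtgt"]].sum(axis=1)
        # transcription tolerance of the packaged table
        assert ((sums - 100).abs() <= 2.5).all()


class TestPca:
    def test_rank_one_data_explained_by_first_component(self):
        rng = np.random.default_rng(0)
        X = np.outer(rng.standard_normal(10), rng.standard_normal(4))
        res = pca(X)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        res = pca(rng.standard_normal((20, 5)))
        gram = res.loadings.T @ res.loadings
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-10)

    def test_matches_independent_svd_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((5, 4))
        res = pca(X)
        from sklearn.decomposition import PCA as SkPCA

        sk = SkPCA().fit(X)
        assert np.allclose(res.explained_variance, sk.explained_variance_, atol=1e-10)
        # columns may differ by sign only
        for k in range(res.loadings.shape[1]):
            dot = abs(res.loadings[:, k] @ sk.components_[k])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pca(np.ones((5, 3)))


class TestImputation:
    def test_complete_matrix_returned_unchanged(self):
        X = np.arange(12.0).reshape(4, 3)
        res = impute_iterative_pca(X, n_components=2)
        assert res.n_iter == 1
        assert np.array_equal(res.completed, X)

    def test_rank_one_cell_recovered_to_1e6(self):
        rng = np.random.default_rng(3)
        M = np.outer(rng.standard_normal(8), rng.standard_normal(5))
        Mm = M.copy()
        Mm[2, 3] = np.nan
        res = impute_iterative_pca(Mm, n_components=1, tol=1e-10, max_iter=5000)
        assert res.completed[2, 3] == pytest.approx(M[2, 3], abs=1e-6)

    def test_observed_cells_untouched(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((10, 6))
        Xm = X.copy()
        Xm[::3, 1] = np.nan
        res = impute_iterative_pca(Xm, n_components=2)
        mask = np.isnan(Xm)
        assert np.array_equal(res.completed[~mask], X[~mask])

    def test_observed_objective_non_increasing_unregularized(self):
        rng = np.random.default_rng(5)
        X = np.outer(rng.standard_normal(20), rng.standard_normal(6))
        X += 0.1 * rng.standard_normal(X.shape)
        X[rng.random(X.shape) < 0.15] = np.nan
        res = impute_iterative_pca(X, n_components=2, tol=1e-8, max_iter=2000,
                                   regularized=False)
        diffs = np.diff(res.objective)
        assert (diffs <= 1e-9).all()

    def test_nonconvergence_signals_and_carries_last_iterate(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((30, 8))
        X[rng.random(X.shape) < 0.2] = np.nan
        with pytest.raises(ImputationConvergenceError) as exc:
            impute_iterative_pca(X, n_components=6, tol=1e-14, max_iter=3)
        assert exc.value.result.completed.shape == X.shape
        assert not exc.value.result.converged

    def test_all_missing_column_rejected(self):
        X = np.ones((4, 3))
        X[:, 1] = np.nan
        with pytest.raises(ValueError, match="missing column"):
            impute_iterative_pca(X, n_components=1)

    def test_beats_column_mean_imputation(self):
        # low-rank-plus-noise with 10% MCAR: structure-aware completion
        # should beat the column mean nearly always
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            truth = rng.standard_normal((40, 8)) @ np.diag([3, 2, 1, 0, 0, 0, 0, 0])
            truth = truth @ rng.standard_normal((8, 8))
            noisy = truth + 0.1 * rng.standard_normal(truth.shape)
            mask = rng.random(noisy.shape) < 0.1
            holed = noisy.copy()
            holed[mask] = np.nan
            if np.isnan(holed).all(axis=0).any():
                continue
            comp = impute_iterative_pca(holed, n_components=3, tol=1e-7,
                                        max_iter=2000).completed
            col_mean = np.where(mask, np.nanmean(holed, axis=0), holed)
            rmse_pca = np.sqrt(np.mean((comp[mask] - noisy[mask]) ** 2))
            rmse_mean = np.sqrt(np.mean((col_mean[mask] - noisy[mask]) ** 2))
            wins += rmse_pca < rmse_mean
        assert wins >= 19


class TestMultipleImpute:
    def _holed_rank1(self):
        rng = np.random.default_rng(7)
        M = np.outer(rng.standard_normal(10), rng.standard_normal(5))
        M[3, 2] = np.nan
        M[7, 4] = np.nan
        return M

    def test_zero_noise_gives_zero_variance(self):
        sd = multiple_impute(self._holed_rank1(), n_draws=4, noise_scale=0.0,
                             n_components=1, tol=1e-8)
        mask = np.isnan(self._holed_rank1())
        assert np.allclose(sd[mask], 0.0)

    def test_variance_only_at_missing_cells(self):
        M = self._holed_rank1()
        sd = multiple_impute(M, n_draws=4, noise_scale=0.1, seed=8,
                             n_components=1, tol=1e-8)
        mask = np.isnan(M)
        assert np.isnan(sd[~mask]).all()
        assert np.isfinite(sd[mask]).all()

    def test_positive_finite_spread_under_noise(self):
        sd = multiple_impute(self._holed_rank1(), n_draws=10, noise_scale=0.1, seed=9,
                             n_components=1, tol=1e-8)
        vals = sd[np.isnan(self._holed_rank1())]
        assert (vals > 0).all() and np.isfinite(vals).all()


class TestCca:
    def test_identical_single_columns_correlate_perfectly(self):
        rng = np.random.default_rng(10)
        x = pd.DataFrame({"a": rng.standard_normal(50)})
        res = cca(x, x.rename(columns={"a": "b"}))
        assert res.canonical_correlations[0] == pytest.approx(1.0, abs=1e-8)

    def test_independent_blocks_have_small_leading_correlation(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.standard_normal((1000, 3)))
        Y = pd.DataFrame(rng.standard_normal((1000, 2)), columns=["u", "v"])
        assert cca(X, Y).canonical_correlations[0] < 0.15

    def test_matches_brute_force_eigendecomposition(self):
        # independent oracle: eigenvalues of Sxx^-1 Sxy Syy^-1 Syx
        rng = np.random.default_rng(12)
        X = rng.standard_normal((6, 3))
        Y = rng.standard_normal((6, 2))
        res = cca(pd.DataFrame(X), pd.DataFrame(Y))
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        Ys = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        n = len(X)
        Sxx, Syy, Sxy = Xs.T @ Xs / (n - 1), Ys.T @ Ys / (n - 1), Xs.T @ Ys / (n - 1)
        M = np.linalg.inv(Sxx) @ Sxy @ np.linalg.inv(Syy) @ Sxy.T
        oracle = np.sqrt(np.sort(np.real(np.linalg.eigvals(M)))[::-1][:2])
        assert np.allclose(res.canonical_correlations, oracle, atol=1e-8)

    def test_correlation_count_and_monotonicity(self):
        env, lip, _ = simulate_env_lipid(200, 4, 3, [0.7, 0.3], seed=13)
        rho = cca(env.data, lip).canonical_correlations
        assert len(rho) == 3
        assert (np.diff(rho) <= 1e-12).all()
        assert ((rho >= 0) & (rho <= 1)).all()

    def test_structure_correlations_are_pearson(self):
        env, lip, _ = simulate_env_lipid(300, 3, 2, [0.6], seed=14)
        res = cca(env.data, lip)
        expected = np.corrcoef(lip.iloc[:, 0], env.data.iloc[:, 0])[0, 1]
        assert res.structure_correlations.iloc[0, 0] == pytest.approx(expected, abs=1e-10)

    def test_singular_block_suggests_ridge(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})  # collinear
        Y = pd.DataFrame({"c": [1.0, 0, 1, 0]})
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            cca(X, Y)
        cca(X, Y, ridge=1e-8)  # with ridge it runs

    def test_incomplete_matrix_rejected(self):
        X = pd.DataFrame({"a": [1.0, np.nan, 3]})
        with pytest.raises(ValueError, match="impute"):
            cca(X, X)

    @pytest.mark.parametrize(
        "p, expected",
        [(0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.2, "")],
    )
    def test_star_thresholds(self, p, expected):
        assert significance_stars(p) == expected


class TestCompositionTree:
    def _matrix(self):
        return pd.DataFrame(
            [[50.0, 50.0], [50.0, 50.0], [10.0, 90.0], [90.0, 10.0]],
            index=["a", "b", "c", "d"], columns=["dgd", "gdgt"],
        )

    def test_identical_pair_joined_first(self):
        newick = composition_tree(self._matrix())
        assert "(a:0,b:0)" in newick.replace(" ", "")

    def test_output_is_valid_newick_with_all_labels(self):
        import dendropy

        newick = composition_tree(self._matrix())
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert {lf.taxon.label for lf in tree.leaf_node_iter()} == {"a", "b", "c", "d"}

    def test_duplicate_labels_rejected(self):
        m = self._matrix()
        m.index = ["a", "a", "c", "d"]
        with pytest.raises(ValueError, match="duplicate"):
            composition_tree(m)

    def test_deterministic_under_row_permutation(self):
        m = self._matrix()
        assert composition_tree(m) == composition_tree(m.iloc[::-1])

    def test_fixture_tree_parses(self, class_totals):
        import dendropy

        newick = composition_tree(class_totals[["dgd", "gdgt", "gmgt", "gtgt"]])
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert len(tree.leaf_nodes()) == 51


class TestTreeCongruence:
    def test_self_distance_zero(self):
        t = "((a,b),(c,d));"
        assert tree_congruence(t, t) == 0.0

    def test_maximally_different_caterpillars(self):
        a = "((((A,B),C),D),E);"
        b = "((((C,E),A),D),B);"
        assert tree_congruence(a, b) == pytest.approx(1.0)

    def test_symmetry(self):
        a = "((a,b),(c,(d,e)));"
        b = "((a,c),(b,(d,e)));"
        assert tree_congruence(a, b) == tree_congruence(b, a)

    def test_leaf_mismatch_lists_difference(self):
        with pytest.raises(ValueError, match="only in first"):
            tree_congruence("((a,b),c);", "((a,b),d);")
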
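"""PCA, NIPALS-PLSR/VIP/Q2, OPLS-DA, permutation test, volcano, clustering."""

import numpy as np
import pandas as pd
import pytest

import speceff as se
from speceff import chemometrics as cm
from speceff import metabolomics as mb


def _random_xy(seed, n=12, p=6, m=1):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    B = rng.normal(size=(p, m))
    Y = X @ B + 0.1 * rng.normal(size=(n, m))
    return X, Y


class TestAutoscale:
    def test_unit_variance_mean_zero_sd_one(self):
        X = np.random.default_rng(0).normal(3, 5, size=(20, 4))
        s = cm.autoscale(X)
        assert np.allclose(s.values.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(s.values.std(axis=0, ddof=1), 1, atol=1e-10)

    def test_mode_none_is_identity(self):
        X = np.arange(12.0).reshape(4, 3)
        assert np.array_equal(cm.autoscale(X, "none").values, X)

    def test_pareto_divides_by_sqrt_sd(self):
        rng = np.random.default_rng(1)
        col = rng.normal(0, 1, size=50)
        col = (col - col.mean()) / col.std(ddof=1) * 4.0  # sd exactly 4
        X = col[:, None]
        s = cm.autoscale(X, "pareto")
        expected = (col - col.mean()) / 2.0
        assert np.allclose(s.values[:, 0], expected)

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame({"ok": [1.0, 2, 3], "flat": [5.0, 5, 5]})
        with pytest.raises(ValueError, match="flat"):
            cm.autoscale(df)


class TestPCA:
    def test_collinear_data_single_component(self):
        t = np.linspace(-1, 1, 10)
        X = np.column_stack([t, 2 * t])
        model = cm.pca(X, 1)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_explained_ratios_sum_to_one(self):
        X = np.random.default_rng(2).normal(size=(8, 4))
        model = cm.pca(X)  # full rank
        assert model.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_matches_eigendecomposition_of_covariance(self):
        X = np.random.default_rng(3).normal(size=(8, 4))
        model = cm.pca(X)
        evals, evecs = np.linalg.eigh(np.cov(X, rowvar=False))
        order = np.argsort(evals)[::-1]
        evecs = evecs[:, order]
        for j in range(model.loadings.shape[1]):
            dot = abs(evecs[:, j] @ model.loadings[:, j])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_scores_orthogonal(self):
        X = np.random.default_rng(4).normal(size=(10, 5))
        model = cm.pca(X)
        G = model.scores.T @ model.scores
        assert np.allclose(G - np.diag(np.diag(G)), 0, atol=1e-8)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            cm.pca(np.eye(3), 5)


class TestPLSR:
    def test_perfect_fit_limit(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 4))
        Y = X @ rng.normal(size=(4, 2))
        model = cm.plsr_fit(X, Y, 4)
        assert model.r2y_cum[-1] == pytest.approx(1.0, abs=1e-8)

    def test_full_component_coefficients_equal_ols(self):
        X, Y = _random_xy(6, n=10, p=5)
        xs, ys = cm.autoscale(X), cm.autoscale(Y)
        model = cm.plsr_fit(xs, ys, 5)
        b_ols = np.linalg.lstsq(xs.values, ys.values, rcond=None)[0]
        assert np.max(np.abs(model.coefficients - b_ols)) < 1e-8

    def test_first_weight_proportional_to_xty(self):
        X, Y = _random_xy(7, n=10, p=4)
        xs, ys = cm.autoscale(X), cm.autoscale(Y)
        model = cm.plsr_fit(xs, ys, 1)
        w_ref = xs.values.T @ ys.values[:, 0]
        w_ref /= np.linalg.norm(w_ref)
        if w_ref[0] < 0:
            w_ref *= -1
        assert np.allclose(model.W[:, 0], w_ref, atol=1e-10)

    def test_r2_cumulative_non_decreasing_and_bounded(self):
        X, Y = _random_xy(8, n=14, p=6, m=2)
        model = cm.plsr_fit(X, Y, 4)
        for arr in (model.r2x_cum, model.r2y_cum):
            assert np.all(np.diff(arr) >= -1e-12)
            assert 0 <= arr[-1] <= 1 + 1e-12

    def test_scores_mutually_orthogonal(self):
        X, Y = _random_xy(9, n=12, p=5, m=2)
        model = cm.plsr_fit(X, Y, 4)
        G = model.T.T @ model.T
        assert np.allclose(G - np.diag(np.diag(G)), 0, atol=1e-8)

    def test_predictions_match_sklearn(self):
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        X, Y = _random_xy(10, n=12, p=5)
        model = cm.plsr_fit(X, Y, 2)
        pred_scaled = model.predict_scaled(model.x_scaler.values)
        ours = model.y_scaler.inverse(pred_scaled)
        ref = sklearn_pls.PLSRegression(n_components=2, scale=True).fit(X, Y)
        assert np.allclose(ours, ref.predict(X), atol=1e-8)

    def test_row_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cm.plsr_fit(np.random.default_rng(0).normal(size=(8, 3)),
                        np.random.default_rng(0).normal(size=(9, 1)), 2)


class TestVIP:
    def test_exchangeable_predictors_equal_vip(self):
        rng = np.random.default_rng(11)
        t = rng.normal(size=20)
        X = np.column_stack([t, t]) + 1e-12
        y = t[:, None]
        model = cm.plsr_fit(X, y, 1)
        v = cm.vip(model)
        assert v[0] == pytest.approx(v[1], rel=1e-6)
        assert v[0] == pytest.approx(1.0, rel=1e-6)

    def test_mean_squared_vip_is_one(self):
        for seed in range(5):
            X, Y = _random_xy(seed, n=12, p=7, m=2)
            model = cm.plsr_fit(X, Y, 3)
            assert np.mean(cm.vip(model) ** 2) == pytest.approx(1.0, abs=1e-10)

    def test_matches_brute_force_formula(self):
        X, Y = _random_xy(12, n=10, p=4, m=2)
        model = cm.plsr_fit(X, Y, 3)
        # independent evaluation from scores and loadings
        p = X.shape[1]
        ssy = np.array([
            (model.T[:, a] @ model.T[:, a]) * (model.C[:, a] @ model.C[:, a])
            for a in range(model.n_components)
        ])
        expected = np.array([
            np.sqrt(p * sum(ssy[a] * (model.W[j, a] / np.linalg.norm(model.W[:, a])) ** 2
                            for a in range(model.n_components)) / ssy.sum())
            for j in range(p)
        ])
        assert np.allclose(cm.vip(model), expected, atol=1e-10)


class TestQ2:
    def test_strong_signal_high_q2(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(30, 5))
        Y = X @ rng.normal(size=(5, 1))
        q2 = cm.q2_cross_validation(X, Y, 3, seed=0)
        assert q2[-1] > 0.95

    def test_pure_noise_mean_q2_non_positive(self):
        vals = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(16, 6))
            Y = rng.normal(size=(16, 1))
            vals.append(cm.q2_cross_validation(X, Y, 2, seed=seed)[-1])
        assert np.mean(vals) <= 0

    def test_seed_determinism(self):
        X, Y = _random_xy(14, n=14, p=5)
        a = cm.q2_cross_validation(X, Y, 3, seed=9)
        b = cm.q2_cross_validation(X, Y, 3, seed=9)
        assert np.array_equal(a, b)

    def test_bad_fold_count_rejected(self):
        X, Y = _random_xy(15, n=6, p=3)
        with pytest.raises(ValueError):
            cm.q2_cross_validation(X, Y, 2, n_folds=7)


class TestOPLSDA:
    def _separated(self, seed=16, n=10, p=8):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(2 * n, p))
        X[:n, :3] += 4.0
        labels = np.array(["g1"] * n + ["g2"] * n)
        return X, labels

    def test_predictive_scores_separate_classes(self):
        X, labels = self._separated()
        model = cm.oplsda_fit(X, labels)
        signs = np.sign(model.predictive_scores)
        assert len(set(signs[labels == "g1"])) == 1
        assert len(set(signs[labels == "g2"])) == 1
        assert signs[0] != signs[-1]

    def test_orthogonal_scores_uncorrelated_with_class(self):
        X, labels = self._separated(17)
        model = cm.oplsda_fit(X, labels, n_orthogonal=2)
        y = model.y
        for k in range(model.orthogonal_scores.shape[1]):
            cov = model.orthogonal_scores[:, k] @ y / (len(y) - 1)
            assert abs(cov) < 1e-10

    def test_s_plot_correlations_bounded(self):
        X, labels = self._separated(18)
        model = cm.oplsda_fit(X, labels)
        assert np.all(model.s_plot_corr >= -1) and np.all(model.s_plot_corr <= 1)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        with pytest.raises(ValueError):
            cm.oplsda_fit(X, ["a"] * 6)


class TestPermutationTest:
    def test_minimum_attainable_p(self):
        X, labels = TestOPLSDA()._separated(19, n=6, p=5)
        res = cm.permutation_test(X, labels, n_permutations=200, seed=0)
        for key in ("p_r2y", "p_q2"):
            assert 1 / 201 <= res[key] <= 1.0
        # strongly separated classes should be at the floor for R2Y
        assert res["p_r2y"] == pytest.approx(1 / 201)

    def test_seed_determinism(self):
        rng = np.random.default_rng(20)
        X = rng.normal(size=(12, 6))
        labels = np.array(["a"] * 6 + ["b"] * 6)
        a = cm.permutation_test(X, labels, 50, seed=3)
        b = cm.permutation_test(X, labels, 50, seed=3)
        assert a["p_q2"] == b["p_q2"] and a["p_r2y"] == b["p_r2y"]

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            cm.permutation_test(np.eye(4), ["a", "a", "b", "b"], 0)


class TestVolcano:
    def _table(self, values, groups=("A", "A", "A", "B", "B", "B")):
        samples = [f"s{i}" for i in range(len(groups))]
        df = pd.DataFrame(values, index=samples).astype(float)
        return mb.FeatureTable(
            intensities=df,
            groups=pd.Series(groups, index=samples),
            id_score=pd.Series(60.0, index=df.columns),
        )

    def test_equal_means_zero_log_fold_change(self):
        table = self._table({"F1": [5, 6, 7, 5, 6, 7], "F2": [1, 2, 3, 3, 2, 1]})
        res = cm.volcano(table)
        assert res.loc["F1", "log2_fold_change"] == pytest.approx(0.0)

    def test_exact_doubling_gives_fold_change_two(self):
        table = self._table({"F1": [2, 4, 6, 4, 8, 12], "F2": [5, 5, 6, 5, 5, 6]})
        res = cm.volcano(table)
        assert res.loc["F1", "fold_change"] == pytest.approx(2.0)
        assert res.loc["F1", "log2_fold_change"] == pytest.approx(1.0)

    def test_adjusted_p_at_least_raw(self):
        table, _ = se.simulate_metabolome(n_per_group=8, n_features=50,
                                          missing_rate=0.0, seed=21)
        res = cm.volcano(table)
        ok = res["p_value"].notna()
        assert (res.loc[ok, "p_adjusted"] >= res.loc[ok, "p_value"] - 1e-15).all()

    def test_planted_features_recovered(self):
        rates = []
        for seed in range(10):
            table, truth = se.simulate_metabolome(n_per_group=20, seed=seed)
            filtered, _ = mb.preprocess(table)
            res = cm.volcano(filtered, seed=seed)
            planted = [f for f in truth["differential_features"]
                       if f in res.index]
            rates.append(res.loc[planted, "selected"].mean())
        assert np.mean(rates) >= 0.9

    def test_tiny_group_rejected(self):
        table = self._table({"F1": [1, 2, 3]}, groups=("A", "B", "B"))
        with pytest.raises(ValueError):
            cm.volcano(table)


class TestHierarchicalClustering:
    def test_identical_rows_merge_first_at_zero(self):
        X = np.array([[1.0, 1.0], [1.0, 1.0], [9.0, 9.0]])
        Z, _ = cm.hierarchical_clustering(X)
        assert set(Z[0, :2].astype(int)) == {0, 1}
        assert Z[0, 2] == pytest.approx(0.0)

    def test_collinear_points_merge_nearest_pair(self):
        X = np.array([[0.0], [1.0], [10.0]])
        Z, order = cm.hierarchical_clustering(X)
        assert set(Z[0, :2].astype(int)) == {0, 1}

    def test_row_permutation_gives_same_tree(self):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(8, 3))
        perm = rng.permutation(8)
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import pdist, squareform

        Z1, _ = cm.hierarchical_clustering(X)
        Z2, _ = cm.hierarchical_clustering(X[perm])
        D1 = squareform(cophenet(Z1))
        D2 = squareform(cophenet(Z2))
        assert np.allclose(D1[np.ix_(perm, perm)], D2, atol=1e-10)

    def test_non_finite_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            cm.hierarchical_clustering(X)
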
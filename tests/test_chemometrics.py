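"""Scaling, PCA vs eigen-oracle, Hotelling, PLS/OPLS invariants, VIP, RF."""

import numpy as np
import pandas as pd
import pytest

from actinomet import chemometrics as cm
from actinomet.exceptions import ConfigurationError, StratificationError


def _random_matrix(seed, n=6, p=10):
    rng = np.random.default_rng(seed)
    return rng.normal(size=(n, p)) * rng.uniform(0.5, 3.0, p)


def _two_class(seed=0, n_per=12, p=30, n_markers=4, effect=4.0):
    """Separable two-class data: the first n_markers features carry the shift."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per, p))
    X[:n_per, :n_markers] += effect
    labels = ["a"] * n_per + ["b"] * n_per
    return cm.pareto_scale(pd.DataFrame(X)), labels


class TestParetoScale:
    def test_closed_form_two_point_column(self):
        out = cm.pareto_scale(np.array([[0.0, 1.0], [2.0, 3.0]]))
        sd = np.sqrt(2.0)  # sd of (0,2) with ddof=1
        expected = np.array([-1.0, 1.0]) / np.sqrt(sd)
        assert np.allclose(out.X[:, 0], expected)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_scaled_sd_is_sqrt_of_original(self, seed):
        X = _random_matrix(seed, n=20, p=5)
        out = cm.pareto_scale(X)
        assert np.allclose(
            out.X.std(axis=0, ddof=1), np.sqrt(X.std(axis=0, ddof=1))
        )

    def test_constant_column_dropped_with_warning(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            out = cm.pareto_scale(X)
        assert out.n_features == 1 and out.dropped_features == ["f0"]

    def test_unit_variance_column_unchanged_by_scaling_step(self):
        rng = np.random.default_rng(5)
        col = rng.normal(size=30)
        col = (col - col.mean()) / col.std(ddof=1)
        out = cm.pareto_scale(col[:, None])
        assert np.allclose(out.X[:, 0], col)

    def test_single_sample_rejected(self):
        with pytest.raises(ConfigurationError):
            cm.pareto_scale(np.ones((1, 3)))


class TestPCA:
    def test_rank_one_matrix_fully_explained_by_pc1(self):
        u = np.array([1.0, -2.0, 0.5, 3.0])
        v = np.arange(1.0, 6.0)
        Xs = cm.ScaledMatrix(
            X=np.outer(u - u.mean(), v), sample_names=list("abcd"),
            feature_names=[f"f{i}" for i in range(5)],
            column_means=np.zeros(5), column_sds=np.ones(5), scaling="none",
        )
        model = cm.fit_pca(Xs, 1)
        assert model.r2x_per_comp[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_equivalent_to_eigendecomposition_oracle(self, seed):
        X = _random_matrix(seed)
        Xs = cm.pareto_scale(X)
        model = cm.fit_pca(Xs, n_comp=3)
        # oracle: eigendecomposition of the covariance of the scaled matrix
        C = Xs.X.T @ Xs.X
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        assert np.allclose(
            model.r2x_per_comp, evals[:3] / np.sum(Xs.X**2), atol=1e-8
        )
        for a in range(3):
            dot = abs(model.P[:, a] @ evecs[:, a])
            assert dot == pytest.approx(1.0, abs=1e-8)  # same axis up to sign
            assert np.allclose(
                np.abs(model.T[:, a]), np.abs(Xs.X @ evecs[:, a]), atol=1e-8
            )

    def test_sign_convention_largest_loading_positive(self):
        model = cm.fit_pca(cm.pareto_scale(_random_matrix(4)), 2)
        for a in range(2):
            assert model.P[np.argmax(np.abs(model.P[:, a])), a] > 0

    def test_scores_orthogonal_and_r2x_sums_below_one(self):
        model = cm.fit_pca(cm.pareto_scale(_random_matrix(9, n=8, p=12)), 4)
        G = model.T.T @ model.T
        assert np.allclose(G - np.diag(np.diag(G)), 0, atol=1e-8)
        assert 0 < model.R2X_cum <= 1 + 1e-12

    def test_too_many_components_rejected(self):
        with pytest.raises(ConfigurationError):
            cm.fit_pca(cm.pareto_scale(_random_matrix(0)), 7)


class TestHotelling:
    def _model_with_scores(self, T):
        return cm.LatentModel(
            kind="PCA", T=T, P=np.zeros((2, T.shape[1])),
            r2x_per_comp=np.zeros(T.shape[1]), R2X_cum=0.0,
            n_components=T.shape[1],
            feature_names=["f0", "f1"],
            sample_names=[f"s{i}" for i in range(T.shape[0])],
        )

    def test_all_points_at_origin_no_outliers(self):
        res = cm.hotelling_ellipse(self._model_with_scores(np.zeros((10, 2))))
        assert not res.outliers.any()

    def test_gross_outlier_flagged(self):
        rng = np.random.default_rng(0)
        T = rng.normal(size=(20, 2))
        T[0] = (25.0, 25.0)
        res = cm.hotelling_ellipse(self._model_with_scores(T))
        assert res.outliers[0]

    def test_raising_alpha_never_decreases_outliers(self):
        T = np.random.default_rng(1).normal(size=(30, 2))
        model = self._model_with_scores(T)
        n_05 = cm.hotelling_ellipse(model, alpha=0.05).outliers.sum()
        n_50 = cm.hotelling_ellipse(model, alpha=0.5).outliers.sum()
        assert n_50 >= n_05

    def test_needs_more_samples_than_components(self):
        with pytest.raises(ConfigurationError):
            cm.hotelling_ellipse(self._model_with_scores(np.zeros((2, 2))))


class TestPLSDA:
    def test_separable_data_fits_and_predicts(self):
        Xs, labels = _two_class(seed=1)
        model = cm.fit_plsda(Xs, labels, n_comp=1)
        assert model.R2Y_cum > 0.9
        assert model.Q2_cum > 0.5
        assert model.Q2_cum <= model.R2Y_cum

    def test_q2_not_above_r2y_across_fits(self):
        for seed in range(3):
            Xs, labels = _two_class(seed=seed, effect=1.5)
            model = cm.fit_plsda(Xs, labels, n_comp=2)
            assert model.Q2_cum <= model.R2Y_cum + 1e-12

    def test_single_latent_variable_on_univariate_x_is_simple_regression(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(0, 1, 10), rng.normal(3, 1, 10)])
        labels = ["a"] * 10 + ["b"] * 10
        Xs = cm.pareto_scale(x[:, None])
        model = cm.fit_plsda(Xs, labels, n_comp=1, compute_q2=False)
        y = np.array([1.0] * 10 + [0.0] * 10)
        r2 = np.corrcoef(Xs.X[:, 0], y)[0, 1] ** 2
        assert model.R2Y_cum == pytest.approx(r2, abs=1e-10)

    def test_weights_unit_norm(self):
        Xs, labels = _two_class(seed=2)
        model = cm.fit_plsda(Xs, labels, n_comp=2, compute_q2=False)
        assert np.allclose(np.linalg.norm(model.W, axis=0), 1.0, atol=1e-10)

    def test_group_folds_losing_a_class_rejected(self):
        Xs, labels = _two_class(seed=3, n_per=4)
        # all of class "a" in one fold-group -> its training fold loses "a"
        fold_groups = ["ga"] * 4 + list("wxyz")
        with pytest.raises(StratificationError):
            cm.fit_plsda(Xs, labels, n_comp=1, cv_folds=5, fold_groups=fold_groups)

    def test_auto_component_selection_runs(self):
        Xs, labels = _two_class(seed=4)
        model = cm.fit_plsda(Xs, labels, n_comp="auto", max_auto_comp=4)
        assert 1 <= model.n_components <= 4


class TestOPLSDA:
    def test_zero_orthogonal_components_match_one_component_plsda(self):
        Xs, labels = _two_class(seed=5, effect=2.0)
        pls = cm.fit_plsda(Xs, labels, n_comp=1, compute_q2=False)
        opls, _ = cm.fit_oplsda(Xs, labels, n_orth=0, compute_q2=False)
        assert np.allclose(opls.T[:, 0], pls.T[:, 0], atol=1e-8)

    @pytest.mark.parametrize("n_orth", [1, 2])
    def test_predictive_score_orthogonal_to_orthogonal_block(self, n_orth):
        Xs, labels = _two_class(seed=6, effect=2.0)
        model, _ = cm.fit_oplsda(Xs, labels, n_orth=n_orth, compute_q2=False)
        for k in range(model.T_orth.shape[1]):
            assert abs(model.T[:, 0] @ model.T_orth[:, k]) < 1e-8 * (
                np.linalg.norm(model.T) * np.linalg.norm(model.T_orth[:, k]) + 1
            )

    def test_splot_signs_agree(self):
        Xs, labels = _two_class(seed=7)
        _, splot = cm.fit_oplsda(Xs, labels, n_orth=1, compute_q2=False)
        nz = (np.abs(splot.p) > 1e-12) & (np.abs(splot.pcorr) > 1e-12)
        assert np.all(np.sign(splot.p[nz]) == np.sign(splot.pcorr[nz]))
        assert np.all(np.abs(splot.pcorr) <= 1 + 1e-12)

    def test_markers_occupy_splot_extremes(self):
        Xs, labels = _two_class(seed=8, p=40, n_markers=3)
        _, splot = cm.fit_oplsda(Xs, labels, n_orth=1, compute_q2=False)
        top = set(splot.top_decile())
        assert {"0", "1", "2"} <= top

    def test_excessive_orthogonal_components_rejected(self):
        Xs, labels = _two_class(seed=9, n_per=3, p=4)
        with pytest.raises(ConfigurationError):
            cm.fit_oplsda(Xs, labels, n_orth=10, compute_q2=False)


class TestVIP:
    def test_sum_of_squares_identity(self):
        for seed in range(3):
            Xs, labels = _two_class(seed=seed)
            model = cm.fit_plsda(Xs, labels, n_comp=2, compute_q2=False)
            vip = cm.vip_scores(model)
            assert (vip**2).sum() == pytest.approx(Xs.n_features, abs=1e-8)

    def test_single_feature_model_vip_is_one(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 1, 8), rng.normal(2, 1, 8)])
        Xs = cm.pareto_scale(x[:, None])
        model = cm.fit_plsda(Xs, ["a"] * 8 + ["b"] * 8, n_comp=1, compute_q2=False)
        assert cm.vip_scores(model).iloc[0] == pytest.approx(1.0)

    def test_pca_model_rejected(self):
        model = cm.fit_pca(cm.pareto_scale(_random_matrix(2)), 2)
        with pytest.raises(ConfigurationError):
            cm.vip_scores(model)


class TestRandomForest:
    def test_single_separating_feature_ranks_first(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 10))
        X[:15, 4] += 6.0
        Xs = cm.pareto_scale(pd.DataFrame(X))
        ranked = cm.rank_features_rf(Xs, ["a"] * 15 + ["b"] * 15, k=3, seed=0)
        assert ranked.iloc[0]["feature_id"] == "4"

    def test_deterministic_under_seed(self):
        Xs, labels = _two_class(seed=10)
        r1 = cm.rank_features_rf(Xs, labels, k=5, seed=7)
        r2 = cm.rank_features_rf(Xs, labels, k=5, seed=7)
        pd.testing.assert_frame_equal(r1, r2)

    def test_k_clipped_with_warning(self):
        Xs, labels = _two_class(seed=11, p=5)
        with pytest.warns(UserWarning, match="k exceeds"):
            ranked = cm.rank_features_rf(Xs, labels, k=50, seed=0)
        assert len(ranked) == Xs.n_features

    def test_pure_noise_recall_near_chance(self):
        rng = np.random.default_rng(12)
        hits = 0
        for seed in range(5):
            X = rng.normal(size=(20, 40))
            Xs = cm.pareto_scale(pd.DataFrame(X))
            ranked = cm.rank_features_rf(Xs, ["a"] * 10 + ["b"] * 10, k=4, seed=seed)
            hits += sum(f in {"0", "1", "2", "3"} for f in ranked["feature_id"])
        # 4 "pseudo-markers" of 40 features, 4 slots: chance ~0.4 per run
        assert hits <= 8
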
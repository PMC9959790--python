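"""Scaling, PCA, NIPALS PLS, contiguous-block CV, thresholding and ROC."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA as SkPCA

import honeynmr as h


class TestScaling:
    def test_sd_scaling_examples(self):
        X = np.array([[1.0], [2.0], [3.0]])
        Xs, _ = h.scale_matrix(X, center=False)
        np.testing.assert_allclose(Xs.ravel(), [1.0, 2.0, 3.0])  # sd = 1
        Xc, _ = h.scale_matrix(X, center=True)
        np.testing.assert_allclose(Xc.ravel(), [-1.0, 0.0, 1.0])

    def test_output_columns_have_unit_sd(self, rng):
        X = rng.normal(0, 5, size=(40, 6))
        Xs, _ = h.scale_matrix(X)
        np.testing.assert_allclose(Xs.std(axis=0, ddof=1), 1.0)

    def test_constant_column_named_in_error(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            h.scale_matrix(X)


class TestPCA:
    def test_rank_one_explains_everything(self, rng):
        X = np.outer(rng.normal(size=20), rng.normal(size=5))
        m = h.pca(X, 1)
        assert m.explained_pct[0] == pytest.approx(100.0)

    def test_identity_matrix_splits_evenly(self):
        m = h.pca(np.eye(2), 2, center=False)
        np.testing.assert_allclose(m.explained_pct, [50.0, 50.0])

    def test_scores_loadings_reconstruct_full_rank(self, rng):
        X = rng.normal(size=(15, 4))
        m = h.pca(X, 4, center=False)
        np.testing.assert_allclose(m.scores @ m.loadings.T, X, atol=1e-10)
        assert m.explained_pct.sum() == pytest.approx(100.0, abs=1e-6)

    def test_centered_pca_matches_sklearn(self, rng):
        X = rng.normal(size=(30, 6))
        ours = h.pca(X, 3, center=True)
        sk = SkPCA(n_components=3).fit(X)
        np.testing.assert_allclose(
            np.abs(ours.loadings), np.abs(sk.components_.T), atol=1e-8
        )
        np.testing.assert_allclose(
            ours.explained_pct, 100 * sk.explained_variance_ratio_, atol=1e-8
        )

    def test_n_pc_too_large_errors(self, rng):
        with pytest.raises(ValueError):
            h.pca(rng.normal(size=(5, 3)), 4)


class TestPLS:
    def test_perfect_single_latent_predictor(self, rng):
        # rank-1 design: y proportional to the single underlying direction
        t = rng.normal(size=20)
        X = np.outer(t, [1.0, -2.0, 0.5, 3.0])
        y = 3.0 * X[:, 0]
        m = h.pls_fit(X, y, n_lv=1)
        np.testing.assert_allclose(h.pls_predict(m, X), y, atol=1e-10)

    def test_full_rank_matches_least_squares(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        m = h.pls_fit(X, y, n_lv=5)
        Xc = X - X.mean(0)
        beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        np.testing.assert_allclose(
            h.pls_predict(m, X), Xc @ beta + y.mean(), atol=1e-8
        )

    def test_first_weight_is_normalised_cross_covariance(self, rng):
        X = rng.normal(size=(4, 3))
        y = np.array([0.0, 1.0, 1.0, 0.0])
        m = h.pls_fit(X, y, n_lv=1)
        Xc, yc = X - X.mean(0), y - y.mean()
        w = Xc.T @ yc
        w /= np.linalg.norm(w)
        np.testing.assert_allclose(m.weights[:, 0], w, atol=1e-12)

    def test_matches_sklearn_predictions(self, rng):
        X = rng.normal(size=(40, 8))
        y = X @ rng.normal(size=8) + 0.5 * rng.normal(size=40)
        for k in (1, 3, 5):
            ours = h.pls_predict(h.pls_fit(X, y, n_lv=k), X)
            sk = PLSRegression(n_components=k, scale=False).fit(X, y)
            np.testing.assert_allclose(ours, sk.predict(X).ravel(), atol=1e-6)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="single"):
            h.pls_fit(rng.normal(size=(10, 3)), np.ones(10), n_lv=1)

    def test_predict_variable_mismatch(self, rng):
        m = h.pls_fit(rng.normal(size=(10, 3)), rng.normal(size=10), n_lv=2)
        with pytest.raises(ValueError, match="mismatch"):
            h.pls_predict(m, rng.normal(size=(4, 5)))


class TestCV:
    def test_block_sizes_300_by_7(self):
        sizes = [len(b) for b in h.contiguous_blocks(300, 7)]
        assert sizes == [43, 43, 43, 43, 43, 43, 42]
        assert sum(sizes) == 300

    def test_blocks_are_contiguous_and_larger_first(self):
        blocks = h.contiguous_blocks(10, 3)
        assert [len(b) for b in blocks] == [4, 3, 3]
        assert list(np.concatenate(blocks)) == list(range(10))

    def test_noiseless_latent_structure_chooses_one_lv(self, rng):
        t = rng.normal(size=42)
        X = np.outer(t, [1.0, -2.0, 0.5, 3.0])
        y = 2.0 * X[:, 0] + 1.0
        res = h.cv_pls(X, y, n_blocks=7, max_lv=3)
        assert res.chosen_n_lv == 1
        assert res.rmsecv[0] < 1e-8

    def test_rmsecv_matches_bruteforce_loop(self, rng):
        """Independent oracle: explicit per-fold, per-LV refit with NIPALS."""
        X = rng.normal(size=(30, 5))
        y = (X[:, 1] + 0.5 * rng.normal(size=30) > 0).astype(float)
        res = h.cv_pls(X, y, n_blocks=7, max_lv=4)
        for k in range(1, 5):
            sq = []
            for block in h.contiguous_blocks(30, 7):
                train = np.setdiff1d(np.arange(30), block)
                m = h.pls_fit(X[train], y[train], n_lv=k)
                sq.extend((h.pls_predict(m, X[block]) - y[block]) ** 2)
            np.testing.assert_allclose(res.rmsecv[k - 1], np.sqrt(np.mean(sq)), rtol=1e-12)

    def test_rmsec_non_increasing(self, rng):
        X = rng.normal(size=(40, 6))
        y = rng.normal(size=40)
        res = h.cv_pls(X, y, n_blocks=5, max_lv=6)
        assert np.all(np.diff(res.rmsec) <= 1e-12)

    def test_label_swap_symmetry(self, cohort):
        """Relabeling 0/1 -> 1/0 leaves RMSECV unchanged (y_hat -> 1 - y_hat)."""
        idx = np.random.default_rng(0).permutation(424)[:80]
        X = cohort.values.to_numpy()[idx]
        y = cohort.labels[idx].astype(float)
        Xs, _ = h.scale_matrix(X)
        a = h.cv_pls(Xs, y, n_blocks=4, max_lv=3)
        b = h.cv_pls(Xs, 1.0 - y, n_blocks=4, max_lv=3)
        np.testing.assert_allclose(a.rmsecv, b.rmsecv, rtol=1e-10)
        np.testing.assert_allclose(a.cv_predictions, 1.0 - b.cv_predictions, atol=1e-10)

    def test_single_class_fold_skipped_with_warning(self, rng):
        # all positives sit in the first block: removing it leaves a
        # single-class training set, so that fold is skipped with a warning
        X = rng.normal(size=(20, 3))
        y = np.array([1.0] * 7 + [0.0] * 13)
        with pytest.warns(UserWarning, match="single-class"):
            res = h.cv_pls(X, y, n_blocks=3, max_lv=2)
        assert res.skipped_folds == [0]
        assert np.isnan(res.cv_predictions[:7]).all()

    def test_all_folds_degenerate_errors(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.array([1.0] * 10 + [0.0] * 10)
        with pytest.raises(ValueError, match="degenerate"), pytest.warns(UserWarning):
            h.cv_pls(X, y, n_blocks=2, max_lv=1)


class TestClassifyROC:
    @pytest.mark.parametrize("yhat,expect", [(0.39, 0), (0.40, 1), (0.41, 1)])
    def test_threshold_rule(self, yhat, expect):
        assert h.classify([yhat])[0] == expect

    def test_threshold_above_range_all_negative(self):
        assert h.classify(np.linspace(0, 1, 11), threshold=1.1).sum() == 0

    def test_roc_hand_example(self):
        y = np.array([0, 0, 1, 0, 1, 1])
        yhat = np.array([0.1, 0.2, 0.4, 0.5, 0.7, 0.9])
        curve = h.roc(y, yhat, thresholds=np.array([0.45]))
        assert curve.sensitivity[0] == pytest.approx(2 / 3)
        assert curve.specificity[0] == pytest.approx(2 / 3)

    def test_roc_endpoints_and_perfect_separation(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        yhat = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        curve = h.roc(y, yhat)
        assert curve.sensitivity[0] == 1.0 and curve.sensitivity[-1] == 0.0
        best = np.minimum(curve.sensitivity, curve.specificity).max()
        assert best == 1.0

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            h.roc(np.ones(4), np.linspace(0, 1, 4))
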
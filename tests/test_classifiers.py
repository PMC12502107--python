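"""PCA, LDA, QDA, PLS-DA: oracle equivalences and toy geometry."""

import numpy as np
import pytest
from scipy.linalg import LinAlgError

from galda import (fit_lda, fit_pca, fit_plsda, fit_qda, fit_svm,
                   pca_transform, predict_lda, predict_plsda, predict_qda,
                   predict_svm)
from galda.classifiers import pca_inverse_transform, plsda_indicators


class TestPCA:
    def test_rank_one_cloud_explained_by_first_component(self, rng):
        t = rng.normal(size=50)
        X = np.column_stack([t, t])        # points on the line y = x
        model = fit_pca(X, 1)
        assert model.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_scores_uncorrelated_and_loadings_orthonormal(self, rng):
        X = rng.normal(size=(30, 6)) @ rng.normal(size=(6, 6))
        model = fit_pca(X, 3)
        scores = pca_transform(model, X)
        cov = np.cov(scores.T)
        assert abs(cov[0, 1]) < 1e-10 and abs(cov[0, 2]) < 1e-10
        np.testing.assert_allclose(model.loadings @ model.loadings.T,
                                   np.eye(3), atol=1e-8)
        assert np.all(np.diff(model.explained_variance_fraction) <= 1e-12)

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(12, 5))
        model = fit_pca(X, 5)
        rec = pca_inverse_transform(model, pca_transform(model, X))
        np.testing.assert_allclose(rec, X, atol=1e-8)

    def test_component_limit(self, rng):
        with pytest.raises(ValueError):
            fit_pca(rng.normal(size=(4, 10)), 4)


def _gaussian_discriminant_oracle(X, labels, Xnew):
    """Direct evaluation of the pooled-covariance Gaussian rule."""
    classes = sorted(set(labels))
    n, k = len(X), len(classes)
    means, scat = {}, np.zeros((X.shape[1], X.shape[1]))
    for c in classes:
        sub = X[np.asarray(labels) == c]
        means[c] = sub.mean(axis=0)
        d = sub - means[c]
        scat += d.T @ d
    cov_inv = np.linalg.inv(scat / (n - k))
    preds = []
    for x in Xnew:
        best, best_score = None, -np.inf
        for c in classes:
            prior = (np.asarray(labels) == c).mean()
            d = x - means[c]
            score = -d @ cov_inv @ d + 2 * np.log(prior)
            if score > best_score:
                best, best_score = c, score
        preds.append(best)
    return np.array(preds, dtype=object)


class TestLDA:
    def test_midpoint_boundary_equal_priors(self):
        X = np.array([[-1.0], [0.0], [1.0], [9.0], [10.0], [11.0]])
        y = np.array(["A", "A", "A", "B", "B", "B"], dtype=object)
        model = fit_lda(X, y, priors={"A": 0.5, "B": 0.5})
        pred, _ = predict_lda(model, np.array([[4.0], [6.0]]))
        assert pred.tolist() == ["A", "B"]
        train_pred, _ = predict_lda(model, X)
        assert (train_pred == y).all()

    def test_unequal_priors_shift_boundary_toward_rare_class(self):
        # 1-D equal-variance closed form: boundary at
        # (m1+m2)/2 + s^2 log(p1/p2) / (m2-m1)
        X = np.array([[-1.0], [0.0], [1.0], [9.0], [10.0], [11.0]])
        y = np.array(["A", "A", "A", "B", "B", "B"], dtype=object)
        model = fit_lda(X, y, priors={"A": 0.9, "B": 0.1})
        s2 = model.pooled_covariance[0, 0]
        boundary = 5.0 + s2 * np.log(0.9 / 0.1) / 10.0
        eps = 0.05
        pred, _ = predict_lda(model, np.array([[boundary - eps],
                                               [boundary + eps]]))
        assert pred.tolist() == ["A", "B"]
        assert boundary > 5.0     # moved toward the rare class B

    def test_matches_gaussian_discriminant_oracle(self, rng):
        for _ in range(25):
            n_per = int(rng.integers(2, 5))
            dims = int(rng.integers(1, 3))
            X = np.vstack([rng.normal(0, 1, size=(n_per, dims)),
                           rng.normal(2, 1, size=(n_per, dims))])
            y = np.array(["A"] * n_per + ["B"] * n_per, dtype=object)
            Xnew = rng.normal(1, 2, size=(6, dims))
            model = fit_lda(X, y)
            pred, _ = predict_lda(model, Xnew)
            np.testing.assert_array_equal(
                pred, _gaussian_discriminant_oracle(X, y, Xnew))

    def test_matches_sklearn_reference(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = rng.normal(size=(30, 4))
        X[:15] += 1.5
        y = np.array(["A"] * 15 + ["B"] * 15, dtype=object)
        ours, _ = predict_lda(fit_lda(X, y), X)
        ref = LinearDiscriminantAnalysis().fit(X, y.astype(str)).predict(X)
        np.testing.assert_array_equal(ours.astype(str), ref)

    def test_singular_covariance_suggests_shrinkage(self, rng):
        col = rng.normal(size=8)
        X = np.column_stack([col, col])     # rank-deficient
        y = np.array(["A"] * 4 + ["B"] * 4, dtype=object)
        with pytest.raises(LinAlgError, match="shrinkage"):
            fit_lda(X, y)
        fit_lda(X, y, shrinkage=0.1)        # stabilized fit succeeds


class TestQDA:
    def test_reduces_to_lda_under_equal_covariances(self, rng):
        X = np.vstack([rng.normal(0, 1, size=(20, 2)),
                       rng.normal(3, 1, size=(20, 2))])
        y = np.array(["A"] * 20 + ["B"] * 20, dtype=object)
        Xnew = rng.normal(1.5, 2, size=(30, 2))
        lda_pred, _ = predict_lda(fit_lda(X, y), Xnew)
        qda_pred, _ = predict_qda(fit_qda(X, y), Xnew)
        assert (lda_pred == qda_pred).mean() > 0.9

    def test_concentric_classes_need_qda(self, rng):
        inner = rng.normal(0, 0.5, size=(40, 2))
        outer = rng.normal(0, 4.0, size=(40, 2))
        X = np.vstack([inner, outer])
        y = np.array(["in"] * 40 + ["out"] * 40, dtype=object)
        qda_acc = (predict_qda(fit_qda(X, y), X)[0] == y).mean()
        lda_acc = (predict_lda(fit_lda(X, y), X)[0] == y).mean()
        assert qda_acc > 0.85
        # a linear boundary cannot separate the rings; QDA clearly wins
        assert qda_acc - lda_acc > 0.1

    def test_underdetermined_class_rejected(self, rng):
        X = rng.normal(size=(6, 5))
        y = np.array(["A"] * 3 + ["B"] * 3, dtype=object)
        with pytest.raises(ValueError, match="PCA"):
            fit_qda(X, y)


class TestPLSDA:
    def test_single_informative_variable(self, rng):
        X = rng.normal(size=(20, 5))
        X[:10, 2] += 5.0
        y = np.array(["A"] * 10 + ["B"] * 10, dtype=object)
        model = fit_plsda(X, y, 1)
        pred, _ = predict_plsda(model, X)
        assert (pred == y).all()

    def test_full_rank_matches_least_squares_on_indicators(self, rng):
        X = rng.normal(size=(20, 4))
        y = np.array(["A", "B", "C", "D"] * 5, dtype=object)
        model = fit_plsda(X, y, 4)
        ours = plsda_indicators(model, X)
        # closed-form indicator regression oracle
        Xc = X - X.mean(axis=0)
        Y = np.zeros((20, 4))
        for i, lab in enumerate(y):
            Y[i, sorted(set(y)).index(lab)] = 1.0
        B, *_ = np.linalg.lstsq(Xc, Y - Y.mean(axis=0), rcond=None)
        ref = Xc @ B + Y.mean(axis=0)
        np.testing.assert_allclose(ours, ref, atol=1e-8)

    def test_matches_sklearn_pls_regression(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(18, 6))
        X[:9] += 1.0
        y = np.array(["A"] * 9 + ["B"] * 9, dtype=object)
        model = fit_plsda(X, y, 2)
        Y = np.column_stack([(y == "A").astype(float),
                             (y == "B").astype(float)])
        ref = PLSRegression(n_components=2, scale=False).fit(X, Y)
        np.testing.assert_allclose(plsda_indicators(model, X),
                                   ref.predict(X), atol=1e-6)

    def test_permuted_labels_score_at_chance(self, rng):
        X = rng.normal(size=(24, 10))
        y = np.array(["A", "B"] * 12, dtype=object)
        y_perm = rng.permutation(y)
        # 4-fold CV accuracy under permuted labels
        correct = 0
        folds = np.array_split(rng.permutation(24), 4)
        for fold in folds:
            train = np.setdiff1d(np.arange(24), fold)
            m = fit_plsda(X[train], y_perm[train], 2)
            pred, _ = predict_plsda(m, X[fold])
            correct += int((pred == y_perm[fold]).sum())
        # binomial 99% band around chance for n=24, p=0.5
        assert 4 <= correct <= 20

    def test_latent_limit(self, rng):
        with pytest.raises(ValueError):
            fit_plsda(rng.normal(size=(5, 3)),
                      np.array(["A", "A", "B", "B", "B"], dtype=object), 5)


class TestSVMDelegate:
    def test_separable_toy(self, rng):
        X = np.vstack([rng.normal(0, 0.3, size=(10, 2)),
                       rng.normal(3, 0.3, size=(10, 2))])
        y = np.array(["A"] * 10 + ["B"] * 10, dtype=object)
        model = fit_svm(X, y)
        pred, _ = predict_svm(model, X)
        assert (pred == y.astype(str)).all()
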
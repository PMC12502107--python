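"""Uniform fit/predict wrappers for the model menu.

Every entry exposes ``fit(X, labels) -> self`` and ``predict(X) -> labels``
so the validation schemes can treat them interchangeably:

    pca_lda  - PCA compression + LDA (components chosen by training LOO-CV)
    pca_qda  - PCA compression + QDA
    pls_da   - PLS-DA (latent variables chosen by training LOO-CV)
    svm      - support vector machine (delegated)
    ga_lda   - GA variable selection + LDA
"""

from __future__ import annotations

import numpy as np

from . import classifiers as clf
from .ga import GAConfig, fit_galda, predict_galda

MAX_COMPONENT_SEARCH = 15


def _loo_error(fit_predict, X, y) -> float:
    n = X.shape[0]
    errors = 0
    for i in range(n):
        rest = np.setdiff1d(np.arange(n), [i])
        try:
            pred = fit_predict(X[rest], y[rest], X[i:i + 1])
        except Exception:
            return np.inf
        errors += int(pred[0] != y[i])
    return errors / n


def _select_components(fit_predict, X, y, upper: int) -> int:
    """Smallest component count minimizing the training LOO error."""
    best, best_err = 1, np.inf
    for a in range(1, upper + 1):
        err = _loo_error(lambda Xt, yt, Xe, a=a: fit_predict(Xt, yt, Xe, a),
                         X, y)
        if err < best_err:
            best, best_err = a, err
    return best


class PCALDA:
    """PCA score compression followed by LDA."""

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        upper = min(MAX_COMPONENT_SEARCH, X.shape[0] - 2, X.shape[1])

        def fp(Xt, yt, Xe, a=None):
            a = a or self.n_components
            pca = clf.fit_pca(Xt, a)
            lda = clf.fit_lda(clf.pca_transform(pca, Xt), yt, shrinkage="auto")
            return clf.predict_lda(lda, clf.pca_transform(pca, Xe))[0]

        if self.n_components is None:
            self.n_components = _select_components(fp, X, y, upper)
        self.pca = clf.fit_pca(X, self.n_components)
        self.lda = clf.fit_lda(clf.pca_transform(self.pca, X), y,
                               shrinkage="auto")
        self.class_order = self.lda.class_order
        return self

    def predict(self, X):
        return clf.predict_lda(self.lda, clf.pca_transform(self.pca, X))[0]


class PCAQDA:
    """PCA score compression followed by QDA."""

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        counts = [int((y == c).sum()) for c in set(y.tolist())]
        # QDA needs per-class covariances of full rank on the scores
        upper = max(1, min(MAX_COMPONENT_SEARCH, min(counts) - 2, X.shape[1]))

        def fp(Xt, yt, Xe, a=None):
            a = a or self.n_components
            pca = clf.fit_pca(Xt, a)
            qda = clf.fit_qda(clf.pca_transform(pca, Xt), yt, shrinkage=0.05)
            return clf.predict_qda(qda, clf.pca_transform(pca, Xe))[0]

        if self.n_components is None:
            self.n_components = _select_components(fp, X, y, upper)
        self.pca = clf.fit_pca(X, self.n_components)
        self.qda = clf.fit_qda(clf.pca_transform(self.pca, X), y,
                               shrinkage=0.05)
        self.class_order = self.qda.class_order
        return self

    def predict(self, X):
        return clf.predict_qda(self.qda, clf.pca_transform(self.pca, X))[0]


class PLSDA:
    def __init__(self, n_latent: int | None = None):
        self.n_latent = n_latent

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        upper = min(MAX_COMPONENT_SEARCH, X.shape[0] - 2, X.shape[1])

        def fp(Xt, yt, Xe, a=None):
            a = a or self.n_latent
            m = clf.fit_plsda(Xt, yt, a)
            return clf.predict_plsda(m, Xe)[0]

        if self.n_latent is None:
            self.n_latent = _select_components(fp, X, y, upper)
        self.model = clf.fit_plsda(X, y, self.n_latent)
        self.class_order = self.model.class_order
        return self

    def predict(self, X):
        return clf.predict_plsda(self.model, X)[0]


class SVM:
    def __init__(self, kernel: str = "linear", C: float = 1.0):
        self.kernel, self.C = kernel, C

    def fit(self, X, y):
        self.model = clf.fit_svm(X, y, kernel=self.kernel, C=self.C)
        self.class_order = self.model.class_order
        return self

    def predict(self, X):
        return clf.predict_svm(self.model, X)[0]


class GALDA:
    def __init__(self, config: GAConfig | None = None,
                 ppm: np.ndarray | None = None):
        self.config = config if config is not None else GAConfig()
        self.ppm = ppm

    def fit(self, X, y):
        self.model = fit_galda(X, y, self.config, ppm=self.ppm)
        self.class_order = self.model.lda.class_order
        return self

    def predict(self, X):
        return predict_galda(self.model, X)[0]


class FixedSelectionLDA:
    """LDA refit on a frozen variable subset (selection-fixed CV mode).

    ``bin_starts`` replays the ppm-binning of the GA-LDA model whose
    selection is being reused.
    """

    def __init__(self, selected_indices, bin_starts=None):
        self.selected_indices = np.asarray(selected_indices, dtype=int)
        self.bin_starts = bin_starts

    def _genes(self, X):
        from .ga import design_matrix
        return design_matrix(X, self.bin_starts)[:, self.selected_indices]

    def fit(self, X, y):
        self.lda = clf.fit_lda(self._genes(X), y, shrinkage="auto")
        self.class_order = self.lda.class_order
        return self

    def predict(self, X):
        return clf.predict_lda(self.lda, self._genes(X))[0]


MODEL_MENU = {
    "pca_lda": PCALDA,
    "pca_qda": PCAQDA,
    "pls_da": PLSDA,
    "svm": SVM,
    "ga_lda": GALDA,
}


def build_model(name: str, **kwargs):
    if name not in MODEL_MENU:
        raise ValueError(f"unknown model {name!r}; choose from "
                         f"{sorted(MODEL_MENU)}")
    return MODEL_MENU[name](**kwargs)
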
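"""Classifier menu: PCA, LDA, QDA, PLS-DA and an SVM delegate.

LDA/QDA follow the Gaussian discriminant rule: a sample is assigned to the
class minimizing its Mahalanobis distance to the class mean (pooled
covariance for LDA, per-class for QDA) minus 2 log prior.  The pooled
covariance can be stabilized by shrinkage toward its diagonal, which keeps
the rule well-posed when the number of selected variables approaches the
training sample count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve, eigh


# --------------------------------------------------------------------------
# PCA

@dataclass
class PCAModel:
    loadings: np.ndarray            # (components x variables), rows orthonormal
    explained_variance_fraction: np.ndarray
    center_means: np.ndarray
    singular_values: np.ndarray


def fit_pca(X: np.ndarray, n_components: int) -> PCAModel:
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    limit = min(n - 1, p)
    if not 1 <= n_components <= limit:
        raise ValueError(f"n_components must be in [1, {limit}]")
    means = X.mean(axis=0)
    Xc = X - means
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    return PCAModel(
        loadings=Vt[:n_components].copy(),
        explained_variance_fraction=frac[:n_components].copy(),
        center_means=means,
        singular_values=s[:n_components].copy(),
    )


def pca_transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=float) - model.center_means) @ model.loadings.T


def pca_inverse_transform(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    return scores @ model.loadings + model.center_means


# --------------------------------------------------------------------------
# LDA / QDA

def auto_shrinkage(n_vars: int, n_samples: int, gamma: float = 0.1) -> float:
    """Default stabilization rule: shrink toward the diagonal when the
    variable count reaches half the training sample count."""
    return gamma if n_vars >= n_samples / 2 else 0.0


def _shrink(cov: np.ndarray, gamma: float) -> np.ndarray:
    if gamma <= 0:
        return cov
    return (1.0 - gamma) * cov + gamma * np.diag(np.diag(cov))


def _class_stats(X: np.ndarray, labels: np.ndarray):
    # alphabetical class order (C < PD < T2D for the study's labels);
    # ties in discriminant scores resolve toward the earliest class
    classes = sorted(set(labels.tolist()), key=str)
    idx = {c: np.flatnonzero(labels == c) for c in classes}
    return classes, idx


@dataclass
class LDAModel:
    class_means: np.ndarray          # (classes x variables)
    pooled_covariance: np.ndarray
    priors: np.ndarray
    class_order: tuple
    shrinkage: float = 0.0
    _cho: tuple = field(default=None, repr=False, compare=False)

    def _factor(self):
        if self._cho is None:
            try:
                self._cho = cho_factor(self.pooled_covariance)
            except LinAlgError as exc:
                raise LinAlgError(
                    "singular pooled covariance; refit with shrinkage "
                    "(e.g. shrinkage='auto')"
                ) from exc
        return self._cho


def fit_lda(
    X: np.ndarray,
    labels: np.ndarray,
    priors: dict | np.ndarray | None = None,
    shrinkage: float | str | None = None,
) -> LDAModel:
    """Fit Gaussian LDA with pooled within-class covariance.

    ``priors=None`` uses empirical class frequencies.  ``shrinkage`` is a
    fraction in [0, 1] toward the covariance diagonal, ``'auto'`` for the
    default stabilization rule, or None for no shrinkage.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels, dtype=object)
    n, p = X.shape
    classes, idx = _class_stats(X, labels)
    k = len(classes)
    if k < 2:
        raise ValueError("LDA needs at least 2 classes")
    for c in classes:
        if idx[c].size < 2:
            raise ValueError(f"class {c!r} needs at least 2 samples")
    means = np.vstack([X[idx[c]].mean(axis=0) for c in classes])
    scatter = np.zeros((p, p))
    for ci, c in enumerate(classes):
        d = X[idx[c]] - means[ci]
        scatter += d.T @ d
    cov = scatter / (n - k)
    if shrinkage == "auto":
        gamma = auto_shrinkage(p, n)
    else:
        gamma = float(shrinkage or 0.0)
    cov = _shrink(cov, gamma)
    if priors is None:
        pri = np.array([idx[c].size / n for c in classes])
    elif isinstance(priors, dict):
        pri = np.array([float(priors[c]) for c in classes])
    else:
        pri = np.asarray(priors, dtype=float)
    pri = pri / pri.sum()
    model = LDAModel(
        class_means=means, pooled_covariance=cov, priors=pri,
        class_order=tuple(classes), shrinkage=gamma,
    )
    model._factor()  # fail fast on singular covariance
    return model


def lda_scores(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Discriminant score per class: -Mahalanobis^2 + 2 log prior."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    cho = model._factor()
    scores = np.empty((X.shape[0], len(model.class_order)))
    for ci in range(len(model.class_order)):
        d = X - model.class_means[ci]
        sol = cho_solve(cho, d.T)
        scores[:, ci] = -np.einsum("ij,ji->i", d, sol) + 2.0 * np.log(
            model.priors[ci])
    return scores


def predict_lda(model: LDAModel, X: np.ndarray):
    """Predicted labels (ties -> lowest class index) and discriminant scores."""
    scores = lda_scores(model, X)
    pred = np.array([model.class_order[i] for i in np.argmax(scores, axis=1)],
                    dtype=object)
    return pred, scores


def canonical_variates(model: LDAModel, n: int = 2) -> np.ndarray:
    """Discriminant-function directions (columns), for DF1 x DF2 score plots."""
    mu = model.class_means.mean(axis=0)
    d = model.class_means - mu
    Sb = d.T @ (d * model.priors[:, None])
    w, V = eigh(Sb, model.pooled_covariance)
    order = np.argsort(w)[::-1]
    return V[:, order[:n]]


@dataclass
class QDAModel:
    class_means: np.ndarray
    per_class_covariance: np.ndarray   # (classes x p x p)
    priors: np.ndarray
    class_order: tuple
    shrinkage: float = 0.0


def fit_qda(
    X: np.ndarray,
    labels: np.ndarray,
    priors: dict | np.ndarray | None = None,
    shrinkage: float | str | None = None,
) -> QDAModel:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels, dtype=object)
    n, p = X.shape
    classes, idx = _class_stats(X, labels)
    if len(classes) < 2:
        raise ValueError("QDA needs at least 2 classes")
    covs, means = [], []
    for c in classes:
        nc = idx[c].size
        if shrinkage is None and nc < p + 1:
            raise ValueError(
                f"class {c!r} has {nc} samples for {p} variables; "
                "compress with PCA first or use shrinkage"
            )
        mu = X[idx[c]].mean(axis=0)
        d = X[idx[c]] - mu
        cov = d.T @ d / max(nc - 1, 1)
        if shrinkage == "auto":
            gamma = auto_shrinkage(p, nc)
        else:
            gamma = float(shrinkage or 0.0)
        cov = _shrink(cov, gamma)
        try:
            cho_factor(cov)
        except LinAlgError as exc:
            raise LinAlgError(
                f"ill-conditioned covariance for class {c!r}; "
                "compress with PCA first or increase shrinkage"
            ) from exc
        means.append(mu)
        covs.append(cov)
    if priors is None:
        pri = np.array([idx[c].size / n for c in classes])
    elif isinstance(priors, dict):
        pri = np.array([float(priors[c]) for c in classes])
    else:
        pri = np.asarray(priors, dtype=float)
    pri = pri / pri.sum()
    return QDAModel(
        class_means=np.vstack(means), per_class_covariance=np.stack(covs),
        priors=pri, class_order=tuple(classes),
    )


def predict_qda(model: QDAModel, X: np.ndarray):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    k = len(model.class_order)
    scores = np.empty((X.shape[0], k))
    for ci in range(k):
        cov = model.per_class_covariance[ci]
        cho = cho_factor(cov)
        sign, logdet = np.linalg.slogdet(cov)
        d = X - model.class_means[ci]
        sol = cho_solve(cho, d.T)
        scores[:, ci] = (-np.einsum("ij,ji->i", d, sol) - logdet
                         + 2.0 * np.log(model.priors[ci]))
    pred = np.array([model.class_order[i] for i in np.argmax(scores, axis=1)],
                    dtype=object)
    return pred, scores


# --------------------------------------------------------------------------
# PLS-DA (NIPALS PLS2 on a one-hot class indicator matrix)

@dataclass
class PLSDAModel:
    n_latent: int
    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray      # W  (p x a)
    x_loadings: np.ndarray   # P  (p x a)
    y_loadings: np.ndarray   # Q  (k x a)
    coefficients: np.ndarray  # B (p x k)
    class_order: tuple


def _one_hot(labels: np.ndarray, classes) -> np.ndarray:
    Y = np.zeros((labels.size, len(classes)))
    lut = {c: i for i, c in enumerate(classes)}
    for i, lab in enumerate(labels):
        Y[i, lut[lab]] = 1.0
    return Y


def fit_plsda(X: np.ndarray, labels: np.ndarray, n_latent: int) -> PLSDAModel:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels, dtype=object)
    n, p = X.shape
    if not 1 <= n_latent <= min(n - 1, p):
        raise ValueError(f"n_latent must be in [1, {min(n - 1, p)}]")
    classes, _ = _class_stats(X, labels)
    Y = _one_hot(labels, classes)
    x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
    E, F = X - x_mean, Y - y_mean
    W = np.zeros((p, n_latent))
    P = np.zeros((p, n_latent))
    Q = np.zeros((Y.shape[1], n_latent))
    for a in range(n_latent):
        u = F[:, int(np.argmax((F**2).sum(axis=0)))].copy()
        for _ in range(500):
            w = E.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t = E @ w
            q = F.T @ t / (t @ t)
            u_new = F @ q / (q @ q)
            if np.linalg.norm(u_new - u) < 1e-12 * max(np.linalg.norm(u), 1.0):
                u = u_new
                break
            u = u_new
        t = E @ w
        tt = t @ t
        if tt == 0:
            break
        p_load = E.T @ t / tt
        q = F.T @ t / tt
        E = E - np.outer(t, p_load)
        F = F - np.outer(t, q)
        W[:, a], P[:, a], Q[:, a] = w, p_load, q
    B = W @ np.linalg.pinv(P.T @ W) @ Q.T
    return PLSDAModel(
        n_latent=n_latent, x_mean=x_mean, y_mean=y_mean, weights=W,
        x_loadings=P, y_loadings=Q, coefficients=B, class_order=tuple(classes),
    )


def plsda_indicators(model: PLSDAModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return (X - model.x_mean) @ model.coefficients + model.y_mean


def predict_plsda(model: PLSDAModel, X: np.ndarray):
    ind = plsda_indicators(model, X)
    pred = np.array([model.class_order[i] for i in np.argmax(ind, axis=1)],
                    dtype=object)
    return pred, ind


# --------------------------------------------------------------------------
# SVM comparison model (delegated to scikit-learn behind the common surface)

@dataclass
class SVMModel:
    estimator: object
    class_order: tuple


def fit_svm(X: np.ndarray, labels: np.ndarray, kernel: str = "linear",
            C: float = 1.0) -> SVMModel:
    from sklearn.svm import SVC

    est = SVC(kernel=kernel, C=C)
    labels = np.asarray(labels, dtype=object).astype(str)
    est.fit(np.asarray(X, dtype=float), labels)
    return SVMModel(estimator=est, class_order=tuple(est.classes_.tolist()))


def predict_svm(model: SVMModel, X: np.ndarray):
    pred = model.estimator.predict(np.asarray(X, dtype=float))
    return np.asarray(pred, dtype=object), None
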
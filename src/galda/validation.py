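"""Validation schemes and classification metrics.

Three schemes: leave-one-patient-out cross-validation, Monte-Carlo
cross-validation (repeated stratified random sub-sampling, reported as a
row-normalized percentage confusion matrix), and external test-set scoring.
Metrics are accuracy, sensitivity and specificity

    AC   = (TP + TN) / (TP + FP + TN + FN) x 100
    SENS = TP / (TP + FN) x 100
    SPEC = TN / (TN + FP) x 100

computed per class by a one-vs-rest collapse of the confusion matrix and
macro-averaged; overall accuracy is total-correct / total.  Ratios with a
zero denominator are reported as absent (None), never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import LabeledSpectraSet
from .preprocess import mean_center


@dataclass
class ConfusionMatrix:
    counts: np.ndarray            # rows = measured (true), columns = predicted
    class_order: tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over class_order")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class Metrics:
    AC: float
    SENS: float | None
    SPEC: float | None
    per_class: dict
    averaging: str = "macro"


@dataclass
class MCCVConfig:
    n_iterations: int = 1000
    fraction_out: float = 0.20
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction_out < 1.0:
            raise ValueError("fraction_out must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def confusion(true_labels, predicted_labels, class_order) -> ConfusionMatrix:
    true_labels = np.asarray(true_labels, dtype=object)
    predicted_labels = np.asarray(predicted_labels, dtype=object)
    if true_labels.size != predicted_labels.size:
        raise ValueError("label vectors must have equal length")
    lut = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in lut or p not in lut:
            raise ValueError(f"label {t if t not in lut else p!r} "
                             f"not in class_order {tuple(class_order)}")
        counts[lut[t], lut[p]] += 1
    return ConfusionMatrix(counts=counts, class_order=tuple(class_order))


def _safe_pct(num: float, den: float) -> float | None:
    return None if den == 0 else 100.0 * num / den


def metrics_from_confusion(cm: ConfusionMatrix) -> Metrics:
    counts = cm.counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    per_class = {}
    for ci, c in enumerate(cm.class_order):
        tp = counts[ci, ci]
        fn = counts[ci].sum() - tp
        fp = counts[:, ci].sum() - tp
        tn = total - tp - fn - fp
        per_class[c] = {
            "AC": _safe_pct(tp + tn, total),
            "SENS": _safe_pct(tp, tp + fn),
            "SPEC": _safe_pct(tn, tn + fp),
        }
    def macro(key):
        vals = [v[key] for v in per_class.values() if v[key] is not None]
        return float(np.mean(vals)) if vals else None
    return Metrics(
        AC=100.0 * np.trace(counts) / total,   # overall accuracy
        SENS=macro("SENS"),
        SPEC=macro("SPEC"),
        per_class=per_class,
    )


def _center_pair(train: LabeledSpectraSet, test: LabeledSpectraSet):
    tr = mean_center(train)
    te = mean_center(test, means=tr.column_means)
    return tr, te


def leave_one_patient_out_cv(
    fit, spectra: LabeledSpectraSet, class_order=None, recenter: bool = True
):
    """One fold per patient; per fold the centering means and the classifier
    are refit on the remaining samples.

    ``fit`` is a callable ``fit(X_train, y_train) -> model`` where the model
    exposes ``predict(X) -> labels`` (variable-selection nesting is the
    caller's choice: pass a fit that reruns selection for fully nested CV, or
    one that reuses a fixed selection).
    """
    n = spectra.n_samples
    if class_order is None:
        class_order = sorted(set(spectra.labels.tolist()), key=str)
    preds = np.empty(n, dtype=object)
    for i in range(n):
        rest = np.setdiff1d(np.arange(n), [i])
        train, test = spectra.subset(rest), spectra.subset([i])
        if recenter:
            train, test = _center_pair(train, test)
        model = fit(train.X, train.labels)
        preds[i] = np.asarray(model.predict(test.X), dtype=object)[0]
    cm = confusion(spectra.labels, preds, class_order)
    return cm, metrics_from_confusion(cm)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5))


def mccv_average_accuracy(percentage_matrix) -> float:
    """Average accuracy of a row-normalized percentage confusion matrix:
    the mean of its diagonal (per-class correct-classification rates)."""
    mat = np.asarray(percentage_matrix, dtype=float)
    return float(np.mean(np.diag(mat)))


def monte_carlo_cv(
    fit, spectra: LabeledSpectraSet, config: MCCVConfig | None = None,
    class_order=None, recenter: bool = True,
):
    """Repeated stratified random sub-sampling validation.

    Per iteration a stratified ``fraction_out`` of samples is held out, the
    model is refit on the rest and held-out predictions are accumulated into
    a counts matrix.  Returns ``(percentage_matrix, average_accuracy,
    counts_matrix)`` where the percentage matrix is row-normalized to 100 and
    the average accuracy is the mean of its diagonal.
    """
    cfg = config if config is not None else MCCVConfig()
    if class_order is None:
        class_order = sorted(set(spectra.labels.tolist()), key=str)
    rng = np.random.default_rng(cfg.seed)
    n = spectra.n_samples
    lut = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    cls_idx = spectra.class_indices()
    for _ in range(cfg.n_iterations):
        if cfg.stratified:
            held = []
            for c, idx in cls_idx.items():
                n_out = min(max(_round_half_away(cfg.fraction_out * idx.size), 1),
                            idx.size - 1)
                held.append(rng.choice(idx, size=n_out, replace=False))
            held = np.sort(np.concatenate(held))
        else:
            n_out = min(max(_round_half_away(cfg.fraction_out * n), 1), n - 1)
            held = np.sort(rng.choice(n, size=n_out, replace=False))
            if len(set(np.delete(spectra.labels, held).tolist())) < len(class_order):
                raise ValueError(
                    "a class was left empty in training; use stratified mode"
                )
        rest = np.setdiff1d(np.arange(n), held)
        train, test = spectra.subset(rest), spectra.subset(held)
        if recenter:
            train, test = _center_pair(train, test)
        model = fit(train.X, train.labels)
        pred = np.asarray(model.predict(test.X), dtype=object)
        for t, p in zip(test.labels, pred):
            counts[lut[t], lut[p]] += 1
    row_sums = counts.sum(axis=1, keepdims=True).astype(float)
    pct = np.zeros(counts.shape, dtype=float)
    np.divide(100.0 * counts, row_sums, out=pct, where=row_sums > 0)
    avg_accuracy = mccv_average_accuracy(pct)
    return pct, avg_accuracy, ConfusionMatrix(counts=counts,
                                              class_order=tuple(class_order))


def external_test(model, test_spectra: LabeledSpectraSet, class_order=None):
    """Score a fitted model on an external test set (no refitting).

    The test spectra must already be centered with the training means; if the
    model carries a ppm axis it is checked against the test axis.
    """
    if test_spectra.n_samples == 0:
        raise ValueError("empty test set")
    model_ppm = getattr(model, "ppm", None)
    if model_ppm is not None:
        if (model_ppm.size != test_spectra.ppm.size
                or not np.allclose(model_ppm, test_spectra.ppm)):
            raise ValueError("test ppm axis does not match the training axis")
    if class_order is None:
        class_order = getattr(model, "class_order", None) or sorted(
            set(test_spectra.labels.tolist()), key=str)
    pred = np.asarray(model.predict(test_spectra.X), dtype=object)
    cm = confusion(test_spectra.labels, pred, class_order)
    return cm, metrics_from_confusion(cm)
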
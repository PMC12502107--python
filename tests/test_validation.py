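"""Confusion matrices, AC/SENS/SPEC metrics and the three validation
schemes."""

import numpy as np
import pytest

from galda import (ConfusionMatrix, LabeledSpectraSet, MCCVConfig, confusion,
                   external_test, leave_one_patient_out_cv,
                   mccv_average_accuracy, metrics_from_confusion,
                   monte_carlo_cv)


class OneNearestNeighbour:
    """Memorizing classifier used as a CV plumbing probe."""

    def fit(self, X, y):
        self.X, self.y = np.asarray(X, float), np.asarray(y, dtype=object)
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, float))
        d = ((X[:, None, :] - self.X[None, :, :]) ** 2).sum(axis=2)
        return self.y[np.argmin(d, axis=1)]


class FixedThresholdRule:
    """Deterministic training-free rule: class by sign of the first value."""

    def fit(self, X, y):
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, float))
        return np.array(["pos" if v > 0 else "neg" for v in X[:, 0]],
                        dtype=object)


def _spectra(X, labels):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return LabeledSpectraSet(
        ppm=np.arange(X.shape[1], dtype=float), X=X, labels=labels,
        patient_ids=[f"p{i}" for i in range(X.shape[0])],
    )


class TestConfusion:
    def test_all_correct_two_class(self):
        t = ["A"] * 5 + ["B"] * 5
        cm = confusion(t, t, ("A", "B"))
        np.testing.assert_array_equal(cm.counts, [[5, 0], [0, 5]])

    def test_degenerate_single_column(self):
        t = ["A", "A", "B", "B"]
        cm = confusion(t, ["A"] * 4, ("A", "B"))
        np.testing.assert_array_equal(cm.counts, [[2, 0], [2, 0]])

    def test_three_class_single_crossover_error(self):
        # 27 training samples with exactly one T2D sample called C
        t = ["C"] * 8 + ["PD"] * 8 + ["T2D"] * 11
        p = list(t)
        p[t.index("T2D")] = "C"
        cm = confusion(t, p, ("C", "PD", "T2D"))
        assert cm.counts[2, 0] == 1
        assert cm.counts[2, 2] == 10
        assert np.trace(cm.counts) == 26
        m = metrics_from_confusion(cm)
        assert m.AC == pytest.approx(100 * 26 / 27)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="class_order"):
            confusion(["A"], ["X"], ("A", "B"))


class TestMetrics:
    def test_perfect_three_class(self):
        cm = ConfusionMatrix(np.diag([5, 6, 7]), ("C", "PD", "T2D"))
        m = metrics_from_confusion(cm)
        assert m.AC == 100.0 and m.SENS == 100.0 and m.SPEC == 100.0

    def test_binary_arithmetic(self):
        # TP=8 FN=2 / FP=5 TN=5 -> SENS 80, SPEC 50, AC 65
        cm = ConfusionMatrix(np.array([[8, 2], [5, 5]]), ("pos", "neg"))
        m = metrics_from_confusion(cm)
        pos = m.per_class["pos"]
        assert pos["SENS"] == pytest.approx(80.0)
        assert pos["SPEC"] == pytest.approx(50.0)
        assert pos["AC"] == pytest.approx(65.0)
        assert m.AC == pytest.approx(65.0)

    def test_undefined_specificity_reported_absent(self):
        cm = ConfusionMatrix(np.array([[4, 0], [0, 0]]), ("A", "B"))
        m = metrics_from_confusion(cm)
        assert m.per_class["A"]["SPEC"] is None     # no true negatives exist
        assert m.per_class["A"]["SENS"] == 100.0
        assert m.per_class["B"]["SENS"] is None

    def test_macro_equals_overall_for_balanced_classes(self, rng):
        t = np.repeat(["A", "B", "C"], 10)
        p = t.copy()
        flip = rng.choice(30, size=6, replace=False)
        p[flip] = [{"A": "B", "B": "C", "C": "A"}[x] for x in t[flip]]
        m = metrics_from_confusion(confusion(t, p, ("A", "B", "C")))
        assert m.AC == pytest.approx(m.SENS)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            metrics_from_confusion(ConfusionMatrix(np.zeros((2, 2), int),
                                                   ("A", "B")))


class TestLeaveOnePatientOut:
    def test_memorizer_with_duplicated_points_is_perfect(self):
        base = np.arange(6, dtype=float).reshape(-1, 1)
        X = np.vstack([base, base + 1e-9])
        y = np.array((["A"] * 3 + ["B"] * 3) * 2, dtype=object)
        s = _spectra(X, y)
        cm, m = leave_one_patient_out_cv(
            lambda Xt, yt: OneNearestNeighbour().fit(Xt, yt), s,
            recenter=False)
        assert m.AC == 100.0

    def test_one_fold_per_patient(self):
        calls = []

        class Probe(OneNearestNeighbour):
            def fit(self, X, y):
                calls.append(len(X))
                return super().fit(X, y)

        X = np.arange(8, dtype=float).reshape(-1, 1)
        y = np.array(["A"] * 4 + ["B"] * 4, dtype=object)
        leave_one_patient_out_cv(lambda Xt, yt: Probe().fit(Xt, yt),
                                 _spectra(X, y), recenter=False)
        assert len(calls) == 8
        assert all(c == 7 for c in calls)


class TestMonteCarloCV:
    def test_rows_normalize_to_100(self, rng):
        X = rng.normal(size=(18, 3))
        X[:9] += 3.0
        y = np.array(["A"] * 9 + ["B"] * 9, dtype=object)
        pct, avg, cm = monte_carlo_cv(
            lambda Xt, yt: OneNearestNeighbour().fit(Xt, yt),
            _spectra(X, y), MCCVConfig(n_iterations=25, seed=0),
            recenter=False)
        np.testing.assert_allclose(pct.sum(axis=1), 100.0, atol=0.1)

    def test_printed_matrix_average_accuracy(self):
        # published three-group percentage matrix: diagonal mean 76.2
        mat = [[74.0, 5.1, 20.9], [2.0, 80.5, 17.5], [14.0, 12.0, 74.0]]
        assert round(mccv_average_accuracy(mat), 1) == 76.2

    def test_separable_data_all_diagonal(self, rng):
        X = np.vstack([rng.normal(0, 0.1, size=(6, 2)),
                       rng.normal(5, 0.1, size=(6, 2))])
        y = np.array(["A"] * 6 + ["B"] * 6, dtype=object)
        pct, avg, cm = monte_carlo_cv(
            lambda Xt, yt: OneNearestNeighbour().fit(Xt, yt),
            _spectra(X, y), MCCVConfig(n_iterations=2, seed=1),
            recenter=False)
        assert avg == 100.0
        assert cm.counts[0, 1] == 0 and cm.counts[1, 0] == 0

    def test_converges_to_loocv_for_training_free_rule(self, rng):
        # with one sample out per iteration and a training-independent rule,
        # accumulated MCCV rates approach the LOOCV rates
        X = rng.normal(size=(8, 2))
        y = np.array(["pos" if v > 0 else "neg" for v in X[:, 0]],
                     dtype=object)
        flip = [0, 3]
        y[flip] = np.array([{"pos": "neg", "neg": "pos"}[v] for v in y[flip]],
                           dtype=object)
        s = _spectra(X, y)
        fit = lambda Xt, yt: FixedThresholdRule()
        _, loocv_m = leave_one_patient_out_cv(fit, s, recenter=False)
        pct, avg, cm = monte_carlo_cv(
            fit, s, MCCVConfig(n_iterations=600, fraction_out=1 / 8,
                               stratified=False, seed=3), recenter=False)
        overall = 100.0 * np.trace(cm.counts) / cm.counts.sum()
        assert overall == pytest.approx(loocv_m.AC, abs=3.0)

    def test_class_order_permutation_invariance(self, rng):
        X = rng.normal(size=(12, 2))
        X[:6] += 2.5
        y = np.array(["A"] * 6 + ["B"] * 6, dtype=object)
        fit = lambda Xt, yt: OneNearestNeighbour().fit(Xt, yt)
        pct1, _, _ = monte_carlo_cv(fit, _spectra(X, y),
                                    MCCVConfig(n_iterations=20, seed=5),
                                    class_order=("A", "B"), recenter=False)
        pct2, _, _ = monte_carlo_cv(fit, _spectra(X, y),
                                    MCCVConfig(n_iterations=20, seed=5),
                                    class_order=("B", "A"), recenter=False)
        np.testing.assert_allclose(pct1, pct2[::-1, ::-1])


class TestExternalTest:
    def test_training_score_dominates_test_score_on_average(self, rng):
        from galda import fit_lda, predict_lda

        train_wins = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.normal(size=(40, 3))
            X[:20] += 1.0
            y = np.array(["A"] * 20 + ["B"] * 20, dtype=object)
            perm = r.permutation(40)
            tr, te = perm[:24], perm[24:]
            model = fit_lda(X[tr], y[tr])
            acc_tr = (predict_lda(model, X[tr])[0] == y[tr]).mean()
            acc_te = (predict_lda(model, X[te])[0] == y[te]).mean()
            train_wins += int(acc_tr >= acc_te)
        assert train_wins >= 7

    def test_axis_mismatch_rejected(self, rng):
        class Model:
            ppm = np.arange(5.0)
            class_order = ("A", "B")

            def predict(self, X):
                return np.array(["A"] * len(X), dtype=object)

        s = _spectra(rng.normal(size=(3, 4)), ["A", "A", "B"])
        with pytest.raises(ValueError, match="axis"):
            external_test(Model(), s)

    def test_empty_test_set_rejected(self):
        s = _spectra(np.zeros((1, 3)), ["A"]).subset([])
        with pytest.raises(ValueError, match="empty"):
            external_test(OneNearestNeighbour(), s)
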
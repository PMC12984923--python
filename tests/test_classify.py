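"""Classifier, metric and ROC contracts, with independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from entrosel.classify import (
    ClassifierSpec,
    confusion_counts,
    confusion_metrics,
    cross_validate,
    knn_predict,
    roc_auc,
    standardize,
    svm_train_predict,
)
from entrosel.errors import InvalidInputError


class TestStandardize:
    def test_train_columns_zero_mean_unit_sd(self, rng):
        x = rng.normal(5, 3, size=(50, 4))
        z, _, _ = standardize(x)
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=0), 1, atol=1e-9)

    def test_constant_column_maps_to_zeros_with_flag(self, rng):
        x = rng.normal(size=(20, 3))
        x[:, 1] = 7.0
        z, _, (_, _, degenerate) = standardize(x)
        assert degenerate[1] and not degenerate[0]
        np.testing.assert_array_equal(z[:, 1], 0.0)

    def test_apply_row_at_train_mean_maps_to_zero(self, rng):
        x = rng.normal(size=(30, 5))
        _, z, _ = standardize(x, x.mean(axis=0, keepdims=True))
        np.testing.assert_allclose(z, 0, atol=1e-9)


class TestKnn:
    def test_query_on_train_point_returns_its_label(self):
        x = np.array([[0.0, 0.0], [5.0, 5.0]])
        y = np.array([0, 1])
        labels, _ = knn_predict(x, y, np.array([[5.0, 5.0]]), k=1)
        assert labels[0] == 1

    def test_nearer_label_wins_at_k1(self):
        x = np.array([[1.0], [2.0]])
        y = np.array([1, 0])
        labels, _ = knn_predict(x, y, np.array([[0.0]]), k=1)
        assert labels[0] == 1

    def test_k3_matches_brute_force_distances(self, rng):
        train = rng.normal(size=(5, 2))
        y = np.array([0, 1, 0, 1, 1])
        queries = rng.normal(size=(10, 2))
        labels, _ = knn_predict(train, y, queries, k=3)
        for q, got in zip(queries, labels):
            d = [(float(np.linalg.norm(q - t)), i) for i, t in enumerate(train)]
            nn = sorted(d)[:3]
            votes = [y[i] for _, i in nn]
            expected = 1 if sum(votes) >= 2 else 0
            assert got == expected

    def test_resubstitution_accuracy_is_one_for_distinct_points(self, rng):
        x = rng.normal(size=(20, 3))
        y = rng.integers(0, 2, 20)
        labels, _ = knn_predict(x, y, x, k=1)
        assert (labels == y).all()

    def test_margin_score_sign_tracks_class(self):
        x = np.array([[0.0], [10.0]])
        y = np.array([0, 1])
        _, scores = knn_predict(x, y, np.array([[1.0], [9.0]]), k=1)
        assert scores[0] < 0 < scores[1]


class TestSvm:
    def test_separable_fixture_fits_perfectly(self):
        x = np.array([[0.0, 0.0], [0.0, 1.0], [3.0, 3.0], [3.0, 4.0]])
        y = np.array([0, 0, 1, 1])
        labels, dv = svm_train_predict(x, y, x)
        assert (labels == y).all()
        assert (dv[:2] < 0).all() and (dv[2:] > 0).all()

    def test_single_class_train_rejected(self):
        with pytest.raises(InvalidInputError):
            svm_train_predict(np.zeros((4, 2)), np.zeros(4), np.zeros((1, 2)))

    def test_matches_independent_qp_solution(self):
        """Six-point fixture checked against a dual QP solved with scipy."""
        from scipy.optimize import minimize

        x = np.array([[0.0, 0.0], [1.0, 0.5], [0.5, 1.0],
                      [3.0, 3.0], [4.0, 2.5], [2.5, 4.0]])
        y_pm = np.array([-1, -1, -1, 1, 1, 1], dtype=float)
        y = (y_pm > 0).astype(int)
        gram = (x @ x.T) * np.outer(y_pm, y_pm)

        def neg_dual(a):
            return 0.5 * a @ gram @ a - a.sum()

        cons = {"type": "eq", "fun": lambda a: a @ y_pm}
        res = minimize(neg_dual, np.full(6, 0.1), bounds=[(0, 1.0)] * 6,
                       constraints=cons, method="SLSQP")
        a = res.x
        w = (a * y_pm) @ x
        sv = (a > 1e-6) & (a < 1.0 - 1e-6)
        b = np.mean(y_pm[sv] - x[sv] @ w)
        queries = np.array([[0.5, 0.5], [3.5, 3.0], [1.8, 1.8], [2.2, 2.0]])
        qp_pred = (queries @ w + b > 0).astype(int)
        labels, _ = svm_train_predict(x, y, queries)
        np.testing.assert_array_equal(labels, qp_pred)


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1])
        rep = confusion_metrics(y, y)
        assert rep.accuracy == rep.precision == rep.recall == rep.f1 == 1.0

    def test_all_wrong_predictions(self):
        y = np.array([0, 1, 0, 1])
        rep = confusion_metrics(y, 1 - y)
        assert rep.accuracy == rep.precision == rep.recall == rep.f1 == 0.0

    def test_accuracy_arithmetic_on_fixed_matrix(self):
        # TP=127 TN=126 FP=2 FN=1 -> accuracy 253/256
        y_true = np.array([1] * 128 + [0] * 128)
        y_pred = np.array([1] * 127 + [0] + [1] * 2 + [0] * 126)
        cm = confusion_counts(y_true, y_pred)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (127, 126, 2, 1)
        assert math.isclose(confusion_metrics(y_true, y_pred).accuracy, 253 / 256)

    @settings(derandomize=True, max_examples=50)
    @given(st.tuples(st.integers(1, 40), st.integers(1, 40),
                     st.integers(0, 40), st.integers(0, 40)))
    def test_metric_identities_on_random_matrices(self, cells):
        """Accuracy/precision/recall/F1 match their closed forms for any
        integer confusion matrix."""
        tp, tn, fp, fn = cells
        y_true = np.array([1] * (tp + fn) + [0] * (tn + fp))
        y_pred = np.array([1] * tp + [0] * fn + [0] * tn + [1] * fp)
        rep = confusion_metrics(y_true, y_pred)
        assert math.isclose(rep.accuracy, (tp + tn) / (tp + tn + fp + fn))
        p_pos = tp / (tp + fp) if tp + fp else 0.0
        r_pos = tp / (tp + fn) if tp + fn else 0.0
        f_pos = 2 * p_pos * r_pos / (p_pos + r_pos) if p_pos + r_pos else 0.0
        p_neg = tn / (tn + fn) if tn + fn else 0.0
        r_neg = tn / (tn + fp) if tn + fp else 0.0
        f_neg = 2 * p_neg * r_neg / (p_neg + r_neg) if p_neg + r_neg else 0.0
        assert math.isclose(rep.precision, (p_pos + p_neg) / 2)
        assert math.isclose(rep.recall, (r_pos + r_neg) / 2)
        assert math.isclose(rep.f1, (f_pos + f_neg) / 2)

    def test_macro_equals_accuracy_for_symmetric_matrix(self):
        y_true = np.array([1] * 10 + [0] * 10)
        y_pred = np.array([1] * 8 + [0] * 2 + [0] * 8 + [1] * 2)
        rep = confusion_metrics(y_true, y_pred)
        assert math.isclose(rep.precision, rep.accuracy)
        assert math.isclose(rep.recall, rep.accuracy)


class TestRocAuc:
    def test_perfect_and_reversed_ordering(self):
        labels = np.array([0, 0, 1, 1])
        _, auc = roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), labels)
        assert auc == 1.0
        _, auc = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), labels)
        assert auc == 0.0

    def test_worked_example(self):
        _, auc = roc_auc(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1]))
        assert math.isclose(auc, 0.75)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_pairwise_rank_statistic(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=40), 1)  # rounding forces ties
        labels = rng.integers(0, 2, 40)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        _, auc = roc_auc(scores, labels)
        assert math.isclose(auc, oracles.auc_rank_oracle(scores, labels), abs_tol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestCrossValidate:
    def _blobs(self, n=60, sep=8.0, seed=0):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        x = rng.normal(size=(n, 3))
        x[y == 1] += sep
        return x, y

    def test_partition_and_stratification_contracts(self):
        x, y = self._blobs(sep=1.0)
        rep = cross_validate(x, y, folds=5, seed=1)
        assert rep.confusion.total == len(y)  # every sample predicted once
        assert len(rep.fold_accuracies) == 5

    def test_separable_clusters_score_perfectly(self):
        x, y = self._blobs(sep=10.0)
        rep = cross_validate(x, y, folds=10, seed=0)
        assert rep.accuracy == 1.0 and rep.auc == 1.0

    def test_reproducible_for_fixed_seed(self):
        x, y = self._blobs(sep=2.0, seed=3)
        r1 = cross_validate(x, y, folds=5, seed=9)
        r2 = cross_validate(x, y, folds=5, seed=9)
        assert r1.accuracy == r2.accuracy and r1.fold_accuracies == r2.fold_accuracies

    def test_class_smaller_than_folds_rejected(self):
        x = np.zeros((12, 2))
        y = np.array([1] * 3 + [0] * 9)
        with pytest.raises(InvalidInputError):
            cross_validate(x, y, folds=5, seed=0)

    def test_svm_spec_path(self):
        x, y = self._blobs(sep=6.0)
        rep = cross_validate(x, y, ClassifierSpec(kind="svm"), folds=5, seed=0)
        assert rep.accuracy == 1.0
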
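"""Metric suite: confusion matrices, kappa, log-loss, OvR AUC.

The reference values for the three-class osteosarcoma test split come
from the published confusion matrices; random-instance checks use
scikit-learn as the independent oracle.
"""

import numpy as np
import pytest

from osteovote import (ConfusionMatrix, accuracy, confusion_matrix, kappa,
                       metric_report, multiclass_log_loss, one_vs_rest_counts,
                       ovr_auc, report_from_matrix)
from osteovote.metrics import (class_accuracy, f1_score, precision, recall,
                               BinaryCounts)


class TestConfusionMatrix:
    def test_direct_count(self):
        cm = confusion_matrix([0, 0, 1], [0, 1, 1], 2)
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 1]])

    def test_perfect_prediction_is_diagonal(self):
        y = [0, 1, 2, 2, 1]
        cm = confusion_matrix(y, y, 3)
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 1], [0], 2)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 3], [0, 1], 2)


class TestOneVsRest:
    def test_viable_class_decomposition(self, cnn_cm):
        bc = one_vs_rest_counts(cnn_cm, 2)
        assert (bc.tpos, bc.fng, bc.fpos, bc.tng) == (57, 3, 1, 168)

    def test_diagonal_matrix_has_no_errors(self):
        cm = ConfusionMatrix(np.diag([4, 5, 6]))
        for k in range(3):
            bc = one_vs_rest_counts(cm, k)
            assert bc.fpos == 0 and bc.fng == 0

    def test_single_class_edge(self):
        cm = ConfusionMatrix(np.array([[7]]))
        bc = one_vs_rest_counts(cm, 0)
        assert bc.tng == 0 and bc.total == 7

    def test_out_of_range_class_rejected(self, cnn_cm):
        with pytest.raises(ValueError):
            one_vs_rest_counts(cnn_cm, 3)


class TestScalarMetrics:
    def test_reference_cnn_accuracy(self, cnn_cm):
        assert accuracy(cnn_cm) == pytest.approx(219 / 229)
        assert round(100 * accuracy(cnn_cm), 2) == 95.63

    def test_non_tumor_precision(self, cnn_cm):
        bc = one_vs_rest_counts(cnn_cm, 0)
        assert precision(bc) == pytest.approx(108 / 109)
        assert round(100 * precision(bc)) == 99

    def test_perfect_diagonal_scores_one(self):
        cm = ConfusionMatrix(np.diag([3, 4, 5]))
        assert accuracy(cm) == 1.0
        for k in range(3):
            bc = one_vs_rest_counts(cm, k)
            assert precision(bc) == recall(bc) == f1_score(bc) == class_accuracy(bc) == 1.0
        assert kappa(cm) == pytest.approx(1.0)

    def test_zero_denominator_warns_and_returns_zero(self):
        bc = BinaryCounts(tpos=0, tng=5, fpos=0, fng=0)
        with pytest.warns(RuntimeWarning):
            assert precision(bc) == 0.0
        with pytest.warns(RuntimeWarning):
            assert recall(bc) == 0.0


class TestKappa:
    def test_reference_cnn_kappa(self, cnn_cm):
        # p_o = 219/229, p_e = 19316/52441
        assert kappa(cnn_cm) == pytest.approx(
            (219 / 229 - 19316 / 52441) / (1 - 19316 / 52441))
        assert round(100 * kappa(cnn_cm), 2) == 93.09

    def test_chance_agreement_scores_zero(self):
        assert kappa(ConfusionMatrix(np.array([[5, 5], [5, 5]]))) == pytest.approx(0.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 30, (4, 4))
        counts[0, 0] += 1  # ensure non-empty
        perm = rng.permutation(4)
        a = kappa(ConfusionMatrix(counts))
        b = kappa(ConfusionMatrix(counts[np.ix_(perm, perm)]))
        assert a == pytest.approx(b)

    def test_degenerate_single_cell_warns(self):
        cm = ConfusionMatrix(np.array([[5, 0], [0, 0]]))
        with pytest.warns(RuntimeWarning):
            assert kappa(cm) == 0.0


class TestLogLoss:
    def test_uniform_predictions_give_ln_k(self):
        probs = np.full((10, 3), 1 / 3)
        assert multiclass_log_loss([0] * 10, probs) == pytest.approx(np.log(3))

    def test_half_confidence_single_sample(self):
        assert multiclass_log_loss([0], np.array([[0.5, 0.25, 0.25]])) == pytest.approx(
            -np.log(0.5))

    def test_one_hot_clipped_to_near_zero(self):
        probs = np.eye(3)[[0, 1, 2]]
        assert multiclass_log_loss([0, 1, 2], probs) <= 3.5e-15

    def test_unnormalized_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            multiclass_log_loss([0], np.array([[0.5, 0.4, 0.05]]))


class TestOvrAuc:
    def test_perfect_separation(self):
        y = [0, 0, 1, 1]
        probs = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        out = ovr_auc(y, probs)
        assert out["per_class"] == [1.0, 1.0]
        assert out["macro"] == 1.0 and out["micro"] == 1.0

    def test_three_of_four_concordant_pairs(self):
        # positives score {0.9, 0.4}, negatives {0.6, 0.1}
        y = [1, 1, 0, 0]
        scores = np.array([0.9, 0.4, 0.6, 0.1])
        probs = np.column_stack([1 - scores, scores])
        assert ovr_auc(y, probs)["per_class"][1] == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        y = [0, 0, 1, 1]
        probs = np.full((4, 2), 0.5)
        out = ovr_auc(y, probs)
        assert out["per_class"] == [pytest.approx(0.5)] * 2

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        scores = rng.random(50)
        probs = np.column_stack([1 - scores, scores])
        warped = np.column_stack([1 - scores**3, scores**3])
        warped /= warped.sum(axis=1, keepdims=True)
        a = ovr_auc(y, probs)["per_class"][1]
        b = ovr_auc(y, warped)["per_class"][1]
        assert a == pytest.approx(b)

    def test_one_sided_class_flagged(self):
        y = [0, 0, 1, 1]  # class 2 never occurs
        probs = np.full((4, 3), 1 / 3)
        with pytest.warns(RuntimeWarning):
            out = ovr_auc(y, probs)
        assert out["per_class"][2] is None


class TestAgainstSklearn:
    """Independent oracle: recompute everything with scikit-learn on random data."""

    @pytest.mark.parametrize("seed", range(8))
    def test_random_instances(self, seed):
        import sklearn.metrics as skm

        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        n = int(rng.integers(30, 120))
        y = rng.integers(0, k, n)
        y[:k] = np.arange(k)  # every class present
        probs = rng.dirichlet(np.ones(k) * 2, size=n)
        pred = probs.argmax(axis=1)

        rep = metric_report(y, y_pred=pred, probs=probs, n_classes=k, class_names=None)
        np.testing.assert_array_equal(rep.cm.counts, skm.confusion_matrix(y, pred, labels=range(k)))
        assert rep.accuracy == pytest.approx(skm.accuracy_score(y, pred))
        assert rep.kappa == pytest.approx(skm.cohen_kappa_score(y, pred))
        assert rep.log_loss == pytest.approx(skm.log_loss(y, probs, labels=list(range(k))))
        assert rep.macro_precision == pytest.approx(
            skm.precision_score(y, pred, average="macro", zero_division=0))
        assert rep.weighted_recall == pytest.approx(
            skm.recall_score(y, pred, average="weighted", zero_division=0))
        assert rep.macro_f1 == pytest.approx(
            skm.f1_score(y, pred, average="macro", zero_division=0))
        assert rep.macro_auc == pytest.approx(
            skm.roc_auc_score(y, probs if k > 2 else probs[:, 1],
                              multi_class="ovr", average="macro"))
        assert rep.micro_auc == pytest.approx(
            skm.roc_auc_score(np.eye(k, dtype=int)[y].ravel(), probs.ravel()))

    @pytest.mark.parametrize("seed", range(4))
    def test_micro_precision_equals_accuracy(self, seed):
        """Algebraic identity for single-label multiclass predictions."""
        rng = np.random.default_rng(seed + 100)
        k = int(rng.integers(2, 6))
        y = rng.integers(0, k, 200)
        pred = rng.integers(0, k, 200)
        cm = confusion_matrix(y, pred, k)
        tp = sum(one_vs_rest_counts(cm, c).tpos for c in range(k))
        fp = sum(one_vs_rest_counts(cm, c).fpos for c in range(k))
        fn = sum(one_vs_rest_counts(cm, c).fng for c in range(k))
        micro_precision = tp / (tp + fp)
        micro_recall = tp / (tp + fn)
        assert micro_precision == pytest.approx(accuracy(cm))
        assert micro_recall == pytest.approx(accuracy(cm))


class TestMetricReport:
    def test_reference_cnn_presentation_rounding(self, cnn_cm):
        rep = report_from_matrix(cnn_cm)
        assert rep.pct(rep.kappa, 2) == 93.09
        assert rep.pct(rep.accuracy, 2) == 95.63
        assert rep.pct(rep.per_class_recall[1], 0) == 98  # Necrotic-Tumor
        assert rep.pct(rep.per_class_accuracy[2], 2) == 98.25  # Viable

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            metric_report(np.array([]), y_pred=np.array([]))

    def test_kappa_not_larger_than_accuracy_when_beating_chance(self, cnn_cm):
        rep = report_from_matrix(cnn_cm)
        assert rep.kappa <= rep.accuracy
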
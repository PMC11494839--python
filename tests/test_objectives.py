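"""Analytic oracles and invariants for losses and metrics."""

import warnings

import numpy as np
import pytest

from duralseg.nn import Tensor
from duralseg.objectives import (
    ConfusionCounts,
    LossConfig,
    classification_metrics,
    dice_coefficient,
    dice_loss,
    focal_loss,
    iou,
    multitask_loss,
    roc_auc,
    softmax_probs,
)


class TestDiceCoefficient:
    def test_identical_masks(self):
        m = np.zeros((4, 4), dtype=int)
        m[1:3, 1:3] = 1
        assert dice_coefficient(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), dtype=int)
        b = np.zeros((4, 4), dtype=int)
        a[0, 0] = 1
        b[3, 3] = 1
        assert dice_coefficient(a, b) == 0.0

    def test_hand_counted_overlap(self):
        # truth 4 px, pred 6 px, overlap 3 px -> 2*3/(4+6) = 0.6
        truth = np.zeros((4, 4), dtype=int)
        truth[0, 0:4] = 1
        pred = np.zeros((4, 4), dtype=int)
        pred[0, 1:4] = 1
        pred[1, 0:3] = 1
        assert np.logical_and(pred, truth).sum() == 3
        assert dice_coefficient(pred, truth) == pytest.approx(0.6)

    def test_both_empty_convention(self):
        z = np.zeros((3, 3), dtype=int)
        assert dice_coefficient(z, z) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_coefficient(np.zeros((2, 2)), np.zeros((3, 3)))


class TestIoU:
    def test_identical(self):
        m = np.eye(4, dtype=int)
        assert iou(m, m) == 1.0

    def test_hand_counted(self):
        # overlap 3, union 7 -> 3/7
        a = np.zeros(10, dtype=int)
        b = np.zeros(10, dtype=int)
        a[:5] = 1
        b[2:7] = 1
        assert iou(a, b) == pytest.approx(3 / 7)

    def test_dice_jaccard_identity_on_seeded_masks(self):
        """D = 2J/(1+J) must hold on every random binary fixture."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = rng.random((8, 8)) > rng.uniform(0.2, 0.8)
            b = rng.random((8, 8)) > rng.uniform(0.2, 0.8)
            d = dice_coefficient(a, b)
            j = iou(a, b)
            assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)


class TestDiceLoss:
    def test_perfect_hard_prediction(self):
        t = np.zeros((8, 8))
        t[2:6, 2:6] = 1
        assert dice_loss(t, t, smooth=0) == pytest.approx(0.0)

    def test_total_miss(self):
        t = np.zeros((4, 4))
        t[:2] = 1
        assert dice_loss(1 - t, t, smooth=0) == pytest.approx(1.0)

    def test_uniform_half_on_full_foreground(self):
        # 1 - (2*0.5*N)/(0.5N + N) = 1/3 on an all-ones 8x8 mask
        t = np.ones((8, 8))
        assert dice_loss(np.full((8, 8), 0.5), t, smooth=0) == pytest.approx(1 / 3)

    def test_complements_soft_dice_and_differentiable(self):
        rng = np.random.default_rng(0)
        p = rng.random((6, 6))
        t = (rng.random((6, 6)) > 0.5).astype(float)
        tp = Tensor(p, requires_grad=True)
        loss = dice_loss(tp, t, smooth=1.0)
        loss.backward()
        assert tp.grad is not None
        soft_dice = (2 * (p * t).sum() + 1) / (p.sum() + t.sum() + 1)
        assert float(loss.data) == pytest.approx(1 - soft_dice)


class TestFocalLoss:
    def test_confident_correct_is_zero(self):
        assert focal_loss(np.array([[1.0, 0.0]]), [0]) == pytest.approx(0.0, abs=1e-9)

    def test_reduces_to_cross_entropy(self):
        p = np.array([[0.7, 0.3]])
        assert focal_loss(p, [0], gamma=0, alpha=0.999999) == pytest.approx(
            -np.log(0.7), rel=1e-5)

    def test_hand_value(self):
        # p_t=0.5, gamma=2, alpha=0.25 -> 0.25 * 0.25 * ln 2 = 0.043321...
        p = np.array([[0.5, 0.5]])
        assert focal_loss(p, [1], gamma=2, alpha=0.25) == pytest.approx(
            0.25 * 0.25 * np.log(2), rel=1e-9)

    def test_tensor_path_matches_numpy_path(self):
        rng = np.random.default_rng(1)
        logits = rng.standard_normal((5, 2))
        probs_t = softmax_probs(Tensor(logits, requires_grad=True))
        labels = rng.integers(0, 2, 5)
        lt = focal_loss(probs_t, labels)
        ln = focal_loss(probs_t.data, labels)
        assert float(lt.data) == pytest.approx(ln, rel=1e-6)
        lt.backward()  # gradient exists for training


class TestMultitaskLoss:
    def test_perfect_prediction_is_zero(self):
        t = np.zeros((4, 4))
        t[1:3, 1:3] = 1
        loss = multitask_loss(t, t, np.array([[0.0, 1.0]]), [1],
                              LossConfig(smooth=0))
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_delta_zero_is_focal_alone(self):
        t = np.zeros((4, 4))
        probs = np.array([[0.6, 0.4]])
        cfg = LossConfig(balance_delta=0.0, smooth=0)
        assert multitask_loss(np.full((4, 4), 0.3), t, probs, [0], cfg) == \
            pytest.approx(focal_loss(probs, [0]))

    def test_linearity_in_delta(self):
        t = np.zeros((4, 4))
        t[0] = 1
        p = np.full((4, 4), 0.4)
        probs = np.array([[0.8, 0.2]])
        a = focal_loss(probs, [0])
        b = dice_loss(p, t, smooth=0)
        got = multitask_loss(p, t, probs, [0], LossConfig(balance_delta=2.0, smooth=0))
        assert got == pytest.approx(a + 2 * b)


class TestClassificationMetrics:
    def test_hand_confusion(self):
        m = classification_metrics(ConfusionCounts(tp=3, fp=1, tn=5, fn=1))
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["precision"] == pytest.approx(0.75)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(5 / 6)
        assert m["f1"] == pytest.approx(0.75)

    def test_perfect_classifier(self):
        m = classification_metrics(ConfusionCounts(tp=7, fp=0, tn=9, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_zero_denominator_is_nan_with_warning(self):
        with pytest.warns(RuntimeWarning, match="precision"):
            m = classification_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=1))
        assert np.isnan(m["precision"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)

    def test_accuracy_symmetric_under_class_swap(self):
        cm = ConfusionCounts(tp=3, fp=2, tn=8, fn=1)
        swapped = ConfusionCounts(tp=cm.tn, fp=cm.fn, tn=cm.tp, fn=cm.fp)
        assert classification_metrics(cm)["accuracy"] == pytest.approx(
            classification_metrics(swapped)["accuracy"])


def _mann_whitney_auc(scores, labels):
    """Brute-force pairwise oracle: P(random positive outscores random negative)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((1.0 if p > n else 0.5 if p == n else 0.0)
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == pytest.approx(1.0)

    def test_matches_mann_whitney_on_seeded_scores(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            labels = rng.integers(0, 2, 30)
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.random(30), 2)  # rounding forces ties
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(_mann_whitney_auc(scores, labels), abs=1e-12)

    def test_label_inversion_symmetry(self):
        rng = np.random.default_rng(5)
        labels = np.array([0, 1] * 10)
        scores = rng.random(20)
        _, auc = roc_auc(scores, labels)
        _, auc_inv = roc_auc(scores, 1 - labels)
        assert auc_inv == pytest.approx(1 - auc, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.5, 0.6], [1, 1])


class TestLossConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"balance_delta": -1}, {"focal_gamma": -0.5},
        {"focal_alpha": 0.0}, {"focal_alpha": 1.5}, {"smooth": -1},
    ])
    def test_invalid_ranges(self, kw):
        with pytest.raises(ValueError):
            LossConfig(**kw)
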
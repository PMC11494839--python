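"""Losses and evaluation metrics.

Training losses (soft dice, focal, and their weighted multi-task sum)
operate on autodiff tensors so gradients flow; evaluation metrics
(dice, IoU, confusion-matrix scalars, ROC/AUC) operate on plain arrays.

Conventions: a dice or IoU comparison of two empty masks scores 1 (perfect
agreement on absence).  Undefined confusion-matrix ratios (zero
denominators) are reported as NaN with a warning, never silently as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve

from .nn import autograd as ag
from .nn.autograd import Tensor


@dataclass
class LossConfig:
    """Weights and stabilizers for the multi-task objective.

    balance_delta weighs the dice segmentation term against the focal
    classification term; smooth is the dice smoothing added to numerator
    and denominator during training (the reported metric uses 0).
    """

    balance_delta: float = 1.0
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    smooth: float = 1.0

    def __post_init__(self):
        if self.balance_delta < 0 or self.focal_gamma < 0 or self.smooth < 0:
            raise ValueError("balance_delta, focal_gamma and smooth must be >= 0")
        if not 0 < self.focal_alpha < 1:
            raise ValueError("focal_alpha must lie in (0, 1)")


# ---------------------------------------------------------------------------
# segmentation overlap
# ---------------------------------------------------------------------------

def dice_coefficient(pred, truth, smooth: float = 0.0) -> float:
    """Dice similarity 2|P∩T| / (|P|+|T|) between binary masks."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    inter = np.logical_and(pred, truth).sum()
    total = pred.sum() + truth.sum()
    if total == 0 and smooth == 0:
        return 1.0
    return float((2.0 * inter + smooth) / (total + smooth))


def iou(pred, truth) -> float:
    """Jaccard index |P∩T| / |P∪T| between binary masks."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    union = np.logical_or(pred, truth).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(pred, truth).sum() / union)


def dice_loss(pred_probs, truth, smooth: float = 1.0):
    """1 - soft dice; intersection and sums are taken on probabilities.

    Accepts autodiff tensors (returns a scalar Tensor) or arrays (returns
    a float).  ``truth`` is a binary mask of the same shape.
    """
    if isinstance(pred_probs, Tensor):
        t = Tensor(np.asarray(truth, dtype=pred_probs.data.dtype))
        inter = ag.tsum(pred_probs * t)
        total = ag.tsum(pred_probs) + ag.tsum(t)
        dice = ag.add_scalar(inter * 2.0, smooth) * ag.pow_scalar(
            ag.add_scalar(total, smooth), -1.0)
        return ag.add_scalar(-dice, 1.0)
    p = np.asarray(pred_probs, dtype=np.float64)
    t = np.asarray(truth, dtype=np.float64)
    inter = (p * t).sum()
    total = p.sum() + t.sum()
    return float(1.0 - (2.0 * inter + smooth) / (total + smooth))


# ---------------------------------------------------------------------------
# classification losses
# ---------------------------------------------------------------------------

def softmax_probs(logits: Tensor) -> Tensor:
    """Softmax over the last axis of a (B, K) logits tensor (max-shifted)."""
    shift = logits.data.max(axis=-1, keepdims=True)
    e = ag.texp(logits - Tensor(shift))
    return e * ag.pow_scalar(ag.tsum(e, axis=-1, keepdims=True), -1.0)


def focal_loss(class_probs, true_labels, gamma: float = 2.0, alpha: float = 0.25):
    """Mean focal loss  -alpha * (1 - p_t)^gamma * log(p_t).

    ``class_probs`` is (B, K) probabilities (Tensor or array), with
    ``true_labels`` integer class indices of length B.  p_t is clamped away
    from zero before the log.
    """
    labels = np.atleast_1d(np.asarray(true_labels, dtype=int))
    if isinstance(class_probs, Tensor):
        k = class_probs.shape[-1]
        onehot = np.eye(k, dtype=class_probs.data.dtype)[labels]
        pt = ag.tsum(class_probs * Tensor(onehot), axis=-1)
        pt = ag.clip_min(pt, 1e-12)
        focus = ag.pow_scalar(ag.add_scalar(-pt, 1.0), gamma) if gamma != 0 else None
        term = ag.tlog(pt) * (-alpha)
        if focus is not None:
            term = term * focus
        return ag.tmean(term)
    probs = np.atleast_2d(np.asarray(class_probs, dtype=np.float64))
    pt = np.clip(probs[np.arange(len(labels)), labels], 1e-12, None)
    return float(np.mean(-alpha * (1.0 - pt) ** gamma * np.log(pt)))


def multitask_loss(seg_out, seg_truth, class_out, class_truth,
                   cfg: LossConfig | None = None):
    """Joint objective: focal classification term + delta * dice segmentation term."""
    cfg = cfg or LossConfig()
    focal = focal_loss(class_out, class_truth, gamma=cfg.focal_gamma,
                       alpha=cfg.focal_alpha)
    dice = dice_loss(seg_out, seg_truth, smooth=cfg.smooth)
    if isinstance(focal, Tensor) or isinstance(dice, Tensor):
        return focal + dice * cfg.balance_delta
    return focal + cfg.balance_delta * dice


# ---------------------------------------------------------------------------
# confusion-matrix metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self):
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive=1):
        y_true = np.asarray(y_true) == positive
        y_pred = np.asarray(y_pred) == positive
        return cls(tp=int(np.sum(y_true & y_pred)),
                   fp=int(np.sum(~y_true & y_pred)),
                   tn=int(np.sum(~y_true & ~y_pred)),
                   fn=int(np.sum(y_true & ~y_pred)))


def _ratio(num, den, name):
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def classification_metrics(cm: ConfusionCounts) -> dict:
    """Accuracy, precision, specificity, sensitivity and F1 from counts."""
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    return {
        "accuracy": _ratio(tp + tn, cm.total, "accuracy"),
        "precision": _ratio(tp, tp + fp, "precision"),
        "specificity": _ratio(tn, tn + fp, "specificity"),
        "sensitivity": _ratio(tp, tp + fn, "sensitivity"),
        "f1": _ratio(2 * tp, 2 * tp + fp + fn, "f1"),
    }


def roc_auc(scores, labels):
    """ROC points and trapezoidal AUC for positive-class scores.

    AUC equals the Mann-Whitney probability that a random positive outscores
    a random negative (ties counting one half).  Raises on single-class input.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: need at least one positive and one negative")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


@dataclass
class MetricsReport:
    """Everything the evaluation stage reports, per class and aggregate."""

    confusion: ConfusionCounts
    classification: dict
    dice_per_class: dict
    iou_per_class: dict
    mean_dice: float
    mean_iou: float
    roc_points: np.ndarray | None = None
    auc: float | None = None

    def to_dict(self):
        out = {
            "confusion": {"tp": self.confusion.tp, "fp": self.confusion.fp,
                          "tn": self.confusion.tn, "fn": self.confusion.fn},
            "dice_per_class": self.dice_per_class,
            "iou_per_class": self.iou_per_class,
            "mean_dice": self.mean_dice,
            "mean_iou": self.mean_iou,
            "auc": self.auc,
        }
        out.update(self.classification)
        return out
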
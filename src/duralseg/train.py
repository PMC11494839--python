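"""Seeded training/evaluation loop: Adam, plateau LR decay, best-checkpoint.

Defaults follow the method's published training recipe: learning rate 1e-4
halved on validation plateau, 60 epochs, batch size 16, Adam, and the
multi-task dice + focal objective.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np

from .network import CSRUNet, ModelConfig, build_model
from .nn import Adam, Tensor
from .objectives import (
    ConfusionCounts,
    LossConfig,
    MetricsReport,
    classification_metrics,
    dice_coefficient,
    iou,
    multitask_loss,
    roc_auc,
    softmax_probs,
)
from .records import DatasetManifest, LABELS, SDH

LABEL_INDEX = {lab: i for i, lab in enumerate(LABELS)}  # SDH=0, EDH=1
POSITIVE_CLASS = SDH  # minority class is the ROC positive


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    lr_decay_factor: float = 0.5
    lr_patience: int = 10
    epochs: int = 60
    batch_size: int = 16
    val_fraction: float = 0.1
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    min_delta: float = 1e-4  # improvement below this counts as stagnation
    stop_at_train_dice: float | None = None  # optional early stop for smoke runs

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 < self.lr_decay_factor < 1:
            raise ValueError("lr_decay_factor must lie in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    train_dice: list = field(default_factory=list)
    train_pixel_accuracy: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_dice: list = field(default_factory=list)
    lr_trace: list = field(default_factory=list)
    best_epoch: int = -1


def manifest_to_arrays(manifest: DatasetManifest):
    """Stack a manifest into (images (N,1,H,W), masks (N,1,H,W), labels (N,))."""
    if len(manifest) == 0:
        raise ValueError("empty dataset")
    imgs = np.stack([r.image for r in manifest]).astype(np.float32)[:, None]
    masks = np.stack([
        r.mask if r.mask is not None else np.zeros_like(r.image, dtype=np.uint8)
        for r in manifest]).astype(np.float32)[:, None]
    labels = np.array([LABEL_INDEX[r.label] for r in manifest], dtype=int)
    return imgs, masks, labels


def _epoch_eval(model, imgs, masks, labels, cfg):
    """Eval-mode loss/dice over a dataset in batches (no gradients kept)."""
    model.eval()
    losses, dices = [], []
    for s in range(0, len(imgs), cfg.batch_size):
        xb = imgs[s:s + cfg.batch_size]
        seg, logits = model.forward(Tensor(xb))
        probs = softmax_probs(logits)
        loss = multitask_loss(seg, masks[s:s + cfg.batch_size], probs,
                              labels[s:s + cfg.batch_size], cfg.loss)
        losses.append(float(loss.data))
        for i in range(len(xb)):
            dices.append(dice_coefficient(seg.data[i, 0] > 0.5,
                                          masks[s + i, 0] > 0.5))
    model.train()
    return float(np.mean(losses)), float(np.mean(dices))


def train_model(model: CSRUNet, train_set, val_set=None,
                cfg: TrainConfig | None = None):
    """Train with Adam on the multi-task objective; return (best_state, history).

    Per-epoch: seeded shuffle, batched forward/backward/step, then
    validation loss and dice.  The learning rate is multiplied by
    ``lr_decay_factor`` after ``lr_patience`` epochs without validation-loss
    improvement, and the returned state dict is the epoch with the best
    validation dice (training dice when no validation set is given).
    """
    cfg = cfg or TrainConfig()
    imgs, masks, labels = (train_set if isinstance(train_set, tuple)
                           else manifest_to_arrays(train_set))
    if val_set is not None:
        vimgs, vmasks, vlabels = (val_set if isinstance(val_set, tuple)
                                  else manifest_to_arrays(val_set))
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history = TrainHistory()
    best_metric, best_state = -np.inf, None
    plateau_best, stagnant = np.inf, 0

    model.train()
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(imgs))
        ep_losses, ep_dice, ep_pixacc = [], [], []
        for s in range(0, len(order), cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            xb, mb, yb = imgs[idx], masks[idx], labels[idx]
            seg, logits = model.forward(Tensor(xb))
            probs = softmax_probs(logits)
            loss = multitask_loss(seg, mb, probs, yb, cfg.loss)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss {loss.data} at epoch {epoch}; aborting")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_losses.append(float(loss.data))
            hard = seg.data > 0.5
            ep_pixacc.append(float((hard == (mb > 0.5)).mean()))
            for i in range(len(idx)):
                ep_dice.append(dice_coefficient(hard[i, 0], mb[i, 0] > 0.5))

        history.train_loss.append(float(np.mean(ep_losses)))
        history.train_dice.append(float(np.mean(ep_dice)))
        history.train_pixel_accuracy.append(float(np.mean(ep_pixacc)))
        history.lr_trace.append(opt.lr)

        if val_set is not None:
            vloss, vdice = _epoch_eval(model, vimgs, vmasks, vlabels, cfg)
            history.val_loss.append(vloss)
            history.val_dice.append(vdice)
            monitor_loss, metric = vloss, vdice
        else:
            monitor_loss, metric = history.train_loss[-1], history.train_dice[-1]

        if metric > best_metric:
            best_metric = metric
            best_state = model.state_dict()
            history.best_epoch = epoch

        if monitor_loss < plateau_best - cfg.min_delta:
            plateau_best, stagnant = monitor_loss, 0
        else:
            stagnant += 1
            if stagnant >= cfg.lr_patience:
                opt.lr *= cfg.lr_decay_factor
                stagnant = 0

        if (cfg.stop_at_train_dice is not None
                and history.train_dice[-1] >= cfg.stop_at_train_dice):
            break

    if best_state is None:  # pragma: no cover - epochs >= 1 guarantees a state
        best_state = model.state_dict()
    return best_state, history


def evaluate_model(model: CSRUNet, test_set, batch_size: int = 16) -> MetricsReport:
    """Full metric suite on a held-out set (resized+normalized inputs only).

    Per-class dice/IoU evaluate the binary lesion mask on images of each
    true class; the confusion matrix and derived scalars come from the
    classification head with SDH as the positive class, plus ROC/AUC on
    the positive-class probability.
    """
    imgs, masks, labels = (test_set if isinstance(test_set, tuple)
                           else manifest_to_arrays(test_set))
    if len(imgs) == 0:
        raise ValueError("empty test set")
    seg_all, prob_all = [], []
    for s in range(0, len(imgs), batch_size):
        seg, probs = model.predict(imgs[s:s + batch_size, 0])
        seg_all.append(seg)
        prob_all.append(probs)
    seg_all = np.concatenate(seg_all)
    prob_all = np.concatenate(prob_all)
    pred_labels = prob_all.argmax(axis=1)

    dice_by, iou_by = {}, {}
    for lab, li in LABEL_INDEX.items():
        sel = np.where(labels == li)[0]
        if len(sel):
            dice_by[lab] = float(np.mean([
                dice_coefficient(seg_all[i] > 0.5, masks[i, 0] > 0.5) for i in sel]))
            iou_by[lab] = float(np.mean([
                iou(seg_all[i] > 0.5, masks[i, 0] > 0.5) for i in sel]))
    mean_dice = float(np.mean([
        dice_coefficient(seg_all[i] > 0.5, masks[i, 0] > 0.5)
        for i in range(len(imgs))]))
    mean_iou = float(np.mean([
        iou(seg_all[i] > 0.5, masks[i, 0] > 0.5) for i in range(len(imgs))]))

    pos = LABEL_INDEX[POSITIVE_CLASS]
    cm = ConfusionCounts.from_predictions(labels == pos, pred_labels == pos,
                                          positive=True)
    roc_points, auc = None, None
    if len(np.unique(labels)) > 1:
        roc_points, auc = roc_auc(prob_all[:, pos], (labels == pos).astype(int))
    return MetricsReport(confusion=cm,
                         classification=classification_metrics(cm),
                         dice_per_class=dice_by, iou_per_class=iou_by,
                         mean_dice=mean_dice, mean_iou=mean_iou,
                         roc_points=roc_points, auc=auc)


def save_checkpoint(path, model: CSRUNet, history: TrainHistory | None = None):
    """Persist model config + weights (and optionally history) to disk."""
    payload = {"config": model.config, "state": model.state_dict(),
               "history": history}
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_checkpoint(path) -> tuple[CSRUNet, TrainHistory | None]:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    model = build_model(payload["config"])
    model.load_state_dict(payload["state"])
    return model, payload.get("history")
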
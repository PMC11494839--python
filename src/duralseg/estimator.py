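"""scikit-learn-style estimator facade over the network and training loop."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .network import ModelConfig, build_model
from .objectives import LossConfig
from .records import LABELS
from .train import (
    LABEL_INDEX,
    TrainConfig,
    evaluate_model,
    train_model,
)


class DuralHemorrhageNet(BaseEstimator):
    """Joint lesion segmenter and SDH/EDH classifier with a fit/predict API.

    Wraps the spatial-attention CSR-U-Net and its multi-task training loop
    in a scikit-learn estimator: ``fit(X, y, masks=...)`` trains on a stack
    of grayscale slices, ``predict`` returns class labels, ``predict_proba``
    class probabilities and ``predict_mask`` per-pixel lesion probability
    maps.  Composes with sklearn model selection via get_params/set_params.

    Parameters
    ----------
    base_filters : first-encoder width; deeper stages double it.
    epochs, batch_size, learning_rate, lr_decay_factor, lr_patience :
        training-loop hyperparameters (defaults follow the published recipe).
    balance_delta, focal_gamma, focal_alpha : multi-task loss weights.
    val_fraction : stratified share of the training data held out for
        checkpoint selection (0 selects on training dice).
    random_state : seed for weight init, shuffling and the validation split.
    """

    def __init__(self, base_filters=64, se_reduction=16, attention_kernel=7,
                 leaky_slope=0.001, epochs=60, batch_size=16, learning_rate=1e-4,
                 lr_decay_factor=0.5, lr_patience=10, balance_delta=1.0,
                 focal_gamma=2.0, focal_alpha=0.25, val_fraction=0.1,
                 random_state=0):
        self.base_filters = base_filters
        self.se_reduction = se_reduction
        self.attention_kernel = attention_kernel
        self.leaky_slope = leaky_slope
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.lr_decay_factor = lr_decay_factor
        self.lr_patience = lr_patience
        self.balance_delta = balance_delta
        self.focal_gamma = focal_gamma
        self.focal_alpha = focal_alpha
        self.val_fraction = val_fraction
        self.random_state = random_state

    # -- helpers --------------------------------------------------------
    def _coerce_X(self, X):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[:, None]
        if X.ndim != 4:
            raise ValueError("X must be (n_samples, H, W) or (n_samples, 1, H, W)")
        return X

    def _coerce_y(self, y):
        y = np.asarray(y)
        if y.dtype.kind in "UO":
            return np.array([LABEL_INDEX[str(v)] for v in y], dtype=int)
        return y.astype(int)

    # -- estimator API --------------------------------------------------
    def fit(self, X, y, masks=None):
        """Train on slices X with class labels y and (optional) lesion masks."""
        X = self._coerce_X(X)
        y = self._coerce_y(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if masks is None:
            masks = np.zeros_like(X)
        else:
            masks = np.asarray(masks, dtype=np.float32)
            if masks.ndim == 3:
                masks = masks[:, None]

        model_cfg = ModelConfig(base_filters=self.base_filters,
                                se_reduction=self.se_reduction,
                                attention_kernel=self.attention_kernel,
                                leaky_slope=self.leaky_slope,
                                seed=self.random_state)
        train_cfg = TrainConfig(
            learning_rate=self.learning_rate, lr_decay_factor=self.lr_decay_factor,
            lr_patience=self.lr_patience, epochs=self.epochs,
            batch_size=self.batch_size, val_fraction=self.val_fraction,
            seed=self.random_state,
            loss=LossConfig(balance_delta=self.balance_delta,
                            focal_gamma=self.focal_gamma,
                            focal_alpha=self.focal_alpha))

        val = None
        train_tuple = (X, masks, y)
        if self.val_fraction and len(X) >= 10:
            rng = np.random.default_rng(self.random_state)
            val_idx = []
            for cls in np.unique(y):
                idx = np.where(y == cls)[0]
                n_val = int(np.rint(self.val_fraction * len(idx)))
                val_idx.extend(rng.permutation(idx)[:n_val].tolist())
            val_idx = np.array(sorted(val_idx), dtype=int)
            tr_idx = np.setdiff1d(np.arange(len(X)), val_idx)
            if len(val_idx):
                val = (X[val_idx], masks[val_idx], y[val_idx])
                train_tuple = (X[tr_idx], masks[tr_idx], y[tr_idx])

        model = build_model(model_cfg)
        best_state, history = train_model(model, train_tuple, val, train_cfg)
        model.load_state_dict(best_state)
        model.eval()
        self.model_ = model
        self.history_ = history
        self.classes_ = np.array(LABELS)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        X = self._coerce_X(X)
        probs = []
        for s in range(0, len(X), self.batch_size):
            _, p = self.model_.predict(X[s:s + self.batch_size, 0])
            probs.append(p)
        return np.concatenate(probs)

    def predict(self, X):
        """Predicted class labels ('SDH' or 'EDH') for each slice."""
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]

    def predict_mask(self, X, threshold=None):
        """Per-pixel lesion probability maps (or binary masks at a threshold)."""
        check_is_fitted(self, "model_")
        X = self._coerce_X(X)
        segs = []
        for s in range(0, len(X), self.batch_size):
            m, _ = self.model_.predict(X[s:s + self.batch_size, 0])
            segs.append(m)
        seg = np.concatenate(segs)
        return seg if threshold is None else (seg > threshold).astype(np.uint8)

    def score(self, X, y):
        """Classification accuracy on (X, y)."""
        return float(np.mean(self._coerce_y(y) ==
                             self._coerce_y(self.predict(X))))

    def evaluate(self, X, y, masks):
        """Full metrics report (dice/IoU per class, confusion scalars, AUC)."""
        check_is_fitted(self, "model_")
        X = self._coerce_X(X)
        masks = np.asarray(masks, dtype=np.float32)
        if masks.ndim == 3:
            masks = masks[:, None]
        return evaluate_model(self.model_, (X, masks, self._coerce_y(y)),
                              batch_size=self.batch_size)
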
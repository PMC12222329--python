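"""Scikit-learn style estimator wrapping the hybrid CNN-SNN network.

:class:`HybridSNNClassifier` owns the whole training protocol: Adam with L2
weight decay, mini-batches, optional on-the-fly augmentation, early stopping
on validation loss with best-weight restore, and per-epoch learning curves.
It composes with sklearn model selection (``get_params``/``set_params``,
``clone``) and exposes ``fit`` / ``predict`` / ``predict_proba`` / ``score``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_is_fitted

from ._layers import Adam, softmax
from .data import AugmentConfig, augment_batch
from .lif import LIFParams
from .model import HybridConfig, HybridNet

__all__ = ["HybridSNNClassifier", "TrainHistory", "early_stopping_update"]


@dataclass
class TrainHistory:
    """Per-epoch learning curves and the epoch at which training stopped."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    stopped_epoch: int = 0


def early_stopping_update(
    best_so_far: float,
    current_val_loss: float,
    epochs_without_improvement: int,
    patience: int,
) -> tuple[float, int, bool]:
    """One step of the patience rule.

    Strict improvement resets the counter; otherwise it increments, and the
    stop flag raises once ``patience`` consecutive non-improving epochs have
    accumulated.
    """
    if patience < 1:
        raise ValueError("patience must be >= 1")
    if current_val_loss < best_so_far:
        return current_val_loss, 0, False
    counter = epochs_without_improvement + 1
    return best_so_far, counter, counter >= patience


def _cross_entropy(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    probs = softmax(scores)
    n = len(y)
    loss = float(-np.mean(np.log(probs[np.arange(n), y] + 1e-12)))
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


def _mse_on_rates(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    n, c = scores.shape
    onehot = np.zeros_like(scores)
    onehot[np.arange(n), y] = 1.0
    diff = scores - onehot
    loss = float(np.mean(diff**2))
    return loss, 2.0 * diff / (n * c)


_LOSSES = {"cross_entropy": _cross_entropy, "mse_on_rates": _mse_on_rates}


class HybridSNNClassifier(BaseEstimator, ClassifierMixin):
    """Hybrid CNN + spiking-LIF image classifier.

    Parameters mirror the reference training protocol: Adam at learning rate
    1e-4, L2 weight decay 1e-5, at most 30 epochs with patience-5 early
    stopping, categorical cross-entropy on the softmaxed class scores.
    ``model_kind="cnn_only"`` swaps the spiking head for a plain 128→64→3
    projection (the ablation baseline).

    Attributes set by :meth:`fit` carry a trailing underscore: ``net_``
    (the trained network), ``history_`` (learning curves), ``classes_``.
    """

    def __init__(
        self,
        model_kind: str = "hybrid",
        input_shape: tuple[int, int, int] = (128, 128, 3),
        conv_channels: tuple[int, int] = (16, 32),
        kernel_size: int = 3,
        pool_size: int = 2,
        dropout_rate: float = 0.5,
        feature_dim: int = 128,
        hidden_dim: int = 64,
        n_classes: int = 3,
        alpha: float = 0.95,
        v_th: float = 1.0,
        v_reset: float = 0.0,
        n_steps: int = 25,
        surrogate_slope: float = 5.0,
        learning_rate: float = 1e-4,
        weight_decay: float = 1e-5,
        max_epochs: int = 30,
        patience: int = 5,
        batch_size: int = 32,
        loss_kind: str = "cross_entropy",
        augment: AugmentConfig | None = None,
        augment_factor: int = 4,
        random_state: int = 0,
    ) -> None:
        self.model_kind = model_kind
        self.input_shape = input_shape
        self.conv_channels = conv_channels
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.dropout_rate = dropout_rate
        self.feature_dim = feature_dim
        self.hidden_dim = hidden_dim
        self.n_classes = n_classes
        self.alpha = alpha
        self.v_th = v_th
        self.v_reset = v_reset
        self.n_steps = n_steps
        self.surrogate_slope = surrogate_slope
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.loss_kind = loss_kind
        self.augment = augment
        self.augment_factor = augment_factor
        self.random_state = random_state

    # ---- configuration ------------------------------------------------------

    def _hybrid_config(self) -> HybridConfig:
        return HybridConfig(
            input_shape=tuple(self.input_shape),
            conv_channels=tuple(self.conv_channels),
            kernel_size=self.kernel_size,
            pool_size=self.pool_size,
            dropout_rate=self.dropout_rate,
            feature_dim=self.feature_dim,
            hidden_dim=self.hidden_dim,
            n_classes=self.n_classes,
            lif=LIFParams(
                alpha=self.alpha,
                v_th=self.v_th,
                v_reset=self.v_reset,
                n_steps=self.n_steps,
                surrogate_slope=self.surrogate_slope,
            ),
        )

    def _validate_images(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        h, w, c = self.input_shape
        if X.ndim != 4 or X.shape[1:] != (h, w, c):
            raise ValueError(
                f"X must have shape (n, {h}, {w}, {c}), got {X.shape}"
            )
        return X

    # ---- training -----------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> "HybridSNNClassifier":
        """Train on (X, y); if a validation set is given, apply early
        stopping on its loss and restore the best weights."""
        X = self._validate_images(X)
        y = np.asarray(y)
        if len(X) == 0:
            raise ValueError("empty training set")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if self.loss_kind not in _LOSSES:
            raise ValueError(f"unknown loss_kind {self.loss_kind!r}")
        self.classes_ = unique_labels(y)
        if len(self.classes_) > self.n_classes:
            raise ValueError(
                f"{len(self.classes_)} classes found but n_classes="
                f"{self.n_classes}"
            )
        y_idx = np.searchsorted(self.classes_, y)
        loss_fn = _LOSSES[self.loss_kind]

        ss = np.random.SeedSequence(self.random_state)
        init_rng, shuffle_rng, aug_rng = (
            np.random.default_rng(s) for s in ss.spawn(3)
        )
        net = HybridNet(self._hybrid_config(), init_rng, self.model_kind)
        optim = Adam(net.layers, lr=self.learning_rate,
                     weight_decay=self.weight_decay)
        history = TrainHistory()

        have_val = X_val is not None and y_val is not None
        if have_val:
            X_val = self._validate_images(X_val)
            y_val_idx = np.searchsorted(self.classes_, np.asarray(y_val))
            if len(X_val) == 0:
                raise ValueError("empty validation set")
        best_loss, counter = np.inf, 0
        best_state = None

        n = len(X)
        bs = min(self.batch_size, n)
        # With augmentation on, each epoch presents every training image
        # augment_factor times (independently perturbed) — augmentation as
        # dataset expansion rather than mere jitter.
        repeats = self.augment_factor if self.augment is not None else 1
        if repeats < 1:
            raise ValueError("augment_factor must be >= 1")
        for epoch in range(1, self.max_epochs + 1):
            order = np.concatenate(
                [shuffle_rng.permutation(n) for _ in range(repeats)]
            )
            n_pres = len(order)
            losses, hits, seen = [], 0, 0
            for start in range(0, n_pres, bs):
                idx = order[start:start + bs]
                xb = X[idx]
                if self.augment is not None:
                    xb = augment_batch(xb, self.augment, aug_rng)
                scores = net.scores(xb, training=True)
                loss, dscores = loss_fn(scores, y_idx[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch} (loss={loss})"
                    )
                net.backward(dscores.astype(np.float32))
                optim.step()
                losses.append(loss * len(idx))
                hits += int((scores.argmax(1) == y_idx[idx]).sum())
                seen += len(idx)
            history.train_loss.append(sum(losses) / seen)
            history.train_accuracy.append(hits / seen)

            if have_val:
                val_scores = self._batched_scores(net, X_val)
                val_loss, _ = loss_fn(val_scores, y_val_idx)
                history.val_loss.append(val_loss)
                history.val_accuracy.append(
                    float((val_scores.argmax(1) == y_val_idx).mean())
                )
                improved = val_loss < best_loss
                best_loss, counter, stop = early_stopping_update(
                    best_loss, val_loss, counter, self.patience
                )
                if improved:
                    best_state = net.state_copy()
                if stop:
                    history.stopped_epoch = epoch
                    break
        if history.stopped_epoch == 0:
            history.stopped_epoch = len(history.train_loss)
        if best_state is not None:
            net.set_parameters(best_state)

        self.net_ = net
        self.history_ = history
        self.n_features_in_ = int(np.prod(self.input_shape))
        return self

    def _batched_scores(self, net: HybridNet, X: np.ndarray) -> np.ndarray:
        bs = max(1, self.batch_size)
        return np.concatenate([
            net.scores(X[i:i + bs], training=False)
            for i in range(0, len(X), bs)
        ])

    # ---- inference ----------------------------------------------------------

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Raw class scores: spike rates (hybrid) or logits (cnn_only)."""
        check_is_fitted(self, "net_")
        return self._batched_scores(self.net_, self._validate_images(X))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Softmax class probabilities."""
        return softmax(self.decision_scores(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Penultimate 128-d CNN features (for external embedding tools)."""
        check_is_fitted(self, "net_")
        X = self._validate_images(X)
        bs = max(1, self.batch_size)
        return np.concatenate([
            self.net_.features(X[i:i + bs], training=False)
            for i in range(0, len(X), bs)
        ])

    # ---- persistence --------------------------------------------------------

    def save(self, path: str) -> None:
        check_is_fitted(self, "net_")
        self.net_.save(path, seed=self.random_state)

    @classmethod
    def from_checkpoint(cls, path: str) -> "HybridSNNClassifier":
        net, seed = HybridNet.load(path)
        cfg = net.config
        est = cls(
            model_kind=net.model_kind,
            input_shape=cfg.input_shape,
            conv_channels=cfg.conv_channels,
            kernel_size=cfg.kernel_size,
            pool_size=cfg.pool_size,
            dropout_rate=cfg.dropout_rate,
            feature_dim=cfg.feature_dim,
            hidden_dim=cfg.hidden_dim,
            n_classes=cfg.n_classes,
            alpha=cfg.lif.alpha,
            v_th=cfg.lif.v_th,
            v_reset=cfg.lif.v_reset,
            n_steps=cfg.lif.n_steps,
            surrogate_slope=cfg.lif.surrogate_slope,
            random_state=seed if seed is not None else 0,
        )
        est.net_ = net
        est.classes_ = np.arange(cfg.n_classes)
        est.history_ = TrainHistory()
        est.n_features_in_ = int(np.prod(cfg.input_shape))
        return est
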
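"""Training protocol wrappers: single-split training and 5-fold CV.

These are thin functional fronts over :class:`~hybridsnn.estimator.
HybridSNNClassifier`, which owns the optimisation loop.  Cross-validation
reproduces the leakage-free protocol: augmentation and SMOTE oversampling are
applied to the training side of each fold only, and fold accuracies are
aggregated as mean and standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import AugmentConfig, Dataset, smote_oversample, stratified_kfold
from .estimator import HybridSNNClassifier, TrainHistory, early_stopping_update
from .evaluate import MetricsReport, evaluate_predictions

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "CVResult",
    "train_model",
    "early_stopping_update",
    "cross_validate",
    "aggregate_fold_accuracies",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimiser and schedule settings (defaults follow the study protocol)."""

    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    max_epochs: int = 30
    patience: int = 5
    batch_size: int = 32
    loss_kind: str = "cross_entropy"
    folds: int = 5
    seed: int = 0
    model_kind: str = "hybrid"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.max_epochs <= 0:
            raise ValueError("learning_rate and max_epochs must be positive")
        if not 1 <= self.patience <= self.max_epochs:
            raise ValueError("need 1 <= patience <= max_epochs")
        if self.loss_kind not in ("cross_entropy", "mse_on_rates"):
            raise ValueError(f"unknown loss_kind {self.loss_kind!r}")
        if self.model_kind not in ("hybrid", "cnn_only"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")


@dataclass
class CVResult:
    """Per-fold accuracies/reports and their mean and standard deviation."""

    fold_accuracies: list[float]
    reports: list[MetricsReport]
    mean_accuracy: float
    std_accuracy: float
    histories: list[TrainHistory] = field(default_factory=list)


def aggregate_fold_accuracies(accuracies) -> tuple[float, float]:
    """Mean and (population) standard deviation of fold accuracies."""
    acc = np.asarray(list(accuracies), dtype=float)
    if acc.size == 0:
        raise ValueError("no fold accuracies to aggregate")
    return float(acc.mean()), float(acc.std())


def _make_estimator(model_config: dict | None, cfg: TrainConfig,
                    augment: AugmentConfig | None) -> HybridSNNClassifier:
    params = dict(model_config or {})
    return HybridSNNClassifier(
        model_kind=cfg.model_kind,
        learning_rate=cfg.learning_rate,
        weight_decay=cfg.weight_decay,
        max_epochs=cfg.max_epochs,
        patience=cfg.patience,
        batch_size=cfg.batch_size,
        loss_kind=cfg.loss_kind,
        random_state=cfg.seed,
        augment=augment,
        **params,
    )


def train_model(
    train_set: Dataset,
    val_set: Dataset | None,
    model_config: dict | None = None,
    train_config: TrainConfig = TrainConfig(),
    augment: AugmentConfig | None = None,
) -> tuple[HybridSNNClassifier, TrainHistory]:
    """Train one model on pre-split data; returns the fitted estimator and
    its learning curves."""
    if len(train_set) == 0:
        raise ValueError("empty training set")
    if val_set is not None:
        overlap = set(train_set.source_ids) & set(val_set.source_ids)
        if overlap:
            raise ValueError(f"train/validation sets overlap: {sorted(overlap)[:3]}")
    clf = _make_estimator(model_config, train_config, augment)
    clf.fit(
        train_set.images, train_set.labels,
        None if val_set is None else val_set.images,
        None if val_set is None else val_set.labels,
    )
    return clf, clf.history_


def cross_validate(
    dataset: Dataset,
    model_config: dict | None = None,
    train_config: TrainConfig = TrainConfig(),
    augment: AugmentConfig | None = AugmentConfig(),
    smote: bool = True,
    smote_k: int = 5,
) -> CVResult:
    """Stratified k-fold cross-validation with per-fold SMOTE/augmentation.

    Oversampling runs strictly inside each fold's training split, so no
    held-out sample can ever act as a SMOTE parent; a source-id audit
    enforces this at run time.
    """
    folds = stratified_kfold(dataset, k=train_config.folds,
                             seed=train_config.seed)
    accuracies, reports, histories = [], [], []
    for fold in range(folds.k):
        train_idx, val_idx = folds.split(fold)
        train_ds = dataset.subset(train_idx)
        val_ds = dataset.subset(val_idx)
        if smote:
            train_ds = smote_oversample(
                train_ds, k_neighbors=smote_k,
                seed=np.random.default_rng([train_config.seed, fold]),
            )
        _audit_no_leakage(train_ds, val_ds)
        cfg = TrainConfig(**{**train_config.__dict__,
                             "seed": train_config.seed + fold})
        clf, history = train_model(train_ds, val_ds, model_config, cfg,
                                   augment)
        probs = clf.predict_proba(val_ds.images)
        y_idx = np.searchsorted(clf.classes_, val_ds.labels)
        report = evaluate_predictions(y_idx, probs.argmax(1), probs,
                                      k=len(clf.classes_))
        accuracies.append(report.accuracy)
        reports.append(report)
        histories.append(history)
    mean, std = aggregate_fold_accuracies(accuracies)
    return CVResult(
        fold_accuracies=accuracies, reports=reports,
        mean_accuracy=mean, std_accuracy=std, histories=histories,
    )


def _audit_no_leakage(train_ds: Dataset, val_ds: Dataset) -> None:
    """No validation source id may appear in training data or as a SMOTE
    parent of a synthetic training sample."""
    val_ids = set(val_ds.source_ids)
    for sid in train_ds.source_ids:
        if sid in val_ids:
            raise RuntimeError(f"leakage: {sid} in both splits")
        if sid.startswith("smote:"):
            parents = sid[len("smote:"):].split("+")
            bad = val_ids.intersection(parents)
            if bad:
                raise RuntimeError(
                    f"leakage: SMOTE parents {sorted(bad)} are validation "
                    "samples"
                )
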
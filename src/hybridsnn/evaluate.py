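"""Classification metrics, noise robustness and attention maps.

Metrics follow the one-vs-rest convention for the 3-class problem: per-class
TP/TN/FP/FN counts give precision = TP/(TP+FP), recall = TP/(TP+FN), F1 =
their harmonic mean, and pooled accuracy = (TP+TN)/(TP+TN+FP+FN); macro
averages are the unweighted class means.  Zero denominators report 0 and set
a flag rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score

from .data import CLASS_NAMES, Dataset
from .estimator import HybridSNNClassifier

__all__ = [
    "MetricsReport",
    "NoiseSpec",
    "AttentionMap",
    "confusion",
    "metrics_from_confusion",
    "evaluate_predictions",
    "auc_ovr",
    "inject_speckle",
    "inject_salt_pepper",
    "gaussian_blur",
    "apply_noise",
    "DEFAULT_NOISE_GRID",
    "robustness_grid",
    "attention_map",
    "ablation_compare",
]


@dataclass
class MetricsReport:
    """Per-class and macro-averaged classification metrics in [0, 1]."""

    accuracy: float
    precision: np.ndarray  # per class
    recall: np.ndarray
    f1: np.ndarray
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    degenerate_classes: list[int] = field(default_factory=list)
    auc: np.ndarray | None = None
    macro_auc: float | None = None

    def as_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
        }
        if self.macro_auc is not None:
            d["macro_auc"] = self.macro_auc
        for i, name in enumerate(CLASS_NAMES[: len(self.precision)]):
            d[f"precision_{name}"] = float(self.precision[i])
            d[f"recall_{name}"] = float(self.recall[i])
            d[f"f1_{name}"] = float(self.f1[i])
        return d


@dataclass(frozen=True)
class NoiseSpec:
    """A single corruption: kind, level (sigma or p) and seed."""

    kind: str  # speckle | salt_pepper | gaussian_blur
    level: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("speckle", "salt_pepper", "gaussian_blur"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.level < 0:
            raise ValueError("noise level must be >= 0")
        if self.kind == "salt_pepper" and self.level > 1:
            raise ValueError("salt-and-pepper probability must be <= 1")


@dataclass
class AttentionMap:
    """Gradient-weighted class-activation heatmap for one image."""

    heatmap: np.ndarray  # (H, W) in [0, 1]
    overlay: np.ndarray  # (H, W, 3) blended visualisation
    target_class: int
    degenerate: bool = False


# ---- confusion & metrics ----------------------------------------------------

def confusion(y_true: np.ndarray, y_pred: np.ndarray, k: int = 3) -> np.ndarray:
    """k x k count matrix, rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    labels = np.concatenate([y_true, y_pred])
    if labels.size and (labels.min() < 0 or labels.max() >= k):
        raise ValueError(f"labels must lie in [0, {k})")
    return _sk_confusion(y_true, y_pred, labels=np.arange(k))


def metrics_from_confusion(cm: np.ndarray) -> MetricsReport:
    """One-vs-rest metrics from a confusion matrix.

    For a 1x1 "matrix" of shape (2, 2) laid out as [[TP, FN], [FP, TN]] use
    :func:`metrics_from_counts` instead; here rows are true classes.
    """
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    k = cm.shape[0]
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = total - tp - fp - fn
    precision = np.zeros(k)
    recall = np.zeros(k)
    f1 = np.zeros(k)
    degenerate = []
    for i in range(k):
        pd, rd = tp[i] + fp[i], tp[i] + fn[i]
        if pd == 0 or rd == 0:
            degenerate.append(i)
        precision[i] = tp[i] / pd if pd else 0.0
        recall[i] = tp[i] / rd if rd else 0.0
        s = precision[i] + recall[i]
        f1[i] = 2 * precision[i] * recall[i] / s if s else 0.0
    accuracy = float(tp.sum() / total)
    return MetricsReport(
        accuracy=accuracy,
        precision=precision, recall=recall, f1=f1,
        tp=tp, tn=tn, fp=fp, fn=fn,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        degenerate_classes=degenerate,
    )


def metrics_from_counts(tp: int, fn: int, fp: int, tn: int) -> dict:
    """Binary metrics straight from the four counts (worked-example form)."""
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    accuracy = (tn + tp) / (tn + tp + fn + fp)
    return {"recall": recall, "precision": precision, "f1": f1,
            "accuracy": accuracy}


def auc_ovr(y_true: np.ndarray, probabilities: np.ndarray
            ) -> tuple[np.ndarray, float]:
    """One-vs-rest ranking AUC per class (ties count 1/2) and macro average.

    Classes absent from ``y_true`` (or covering it entirely) have no ranking
    problem; they contribute 0 and are skipped in the macro mean.
    """
    y_true = np.asarray(y_true)
    probabilities = np.asarray(probabilities, dtype=float)
    k = probabilities.shape[1]
    aucs = np.zeros(k)
    valid = []
    for c in range(k):
        pos = y_true == c
        if pos.all() or not pos.any():
            continue
        aucs[c] = roc_auc_score(pos.astype(int), probabilities[:, c])
        valid.append(c)
    macro = float(np.mean(aucs[valid])) if valid else 0.0
    return aucs, macro


def evaluate_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                         probabilities: np.ndarray | None = None,
                         k: int = 3) -> MetricsReport:
    """Full report from labels, predictions and (optionally) probabilities."""
    report = metrics_from_confusion(confusion(y_true, y_pred, k))
    if probabilities is not None:
        aucs, macro = auc_ovr(y_true, probabilities)
        report.auc = aucs
        report.macro_auc = macro
    return report


# ---- noise operators --------------------------------------------------------

def inject_speckle(image: np.ndarray, sigma: float, seed: int = 0) -> np.ndarray:
    """Multiplicative Gaussian noise: ``clip(x * (1 + n), 0, 1)``."""
    image = np.asarray(image, dtype=np.float32)
    if sigma == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    n = rng.normal(0.0, sigma, image.shape).astype(np.float32)
    return np.clip(image * (1.0 + n), 0.0, 1.0)


def inject_salt_pepper(image: np.ndarray, p: float, seed: int = 0) -> np.ndarray:
    """Corrupt each pixel with probability ``p`` to 0 or 1 (equal chance).

    Corruption is decided per spatial pixel and applied across channels, so
    grey-scale inputs stay grey-scale.
    """
    image = np.asarray(image, dtype=np.float32)
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if p == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    h, w = image.shape[:2]
    corrupt = rng.random((h, w)) < p
    value = (rng.random((h, w)) < 0.5).astype(np.float32)  # salt=1, pepper=0
    out = image.copy()
    if image.ndim == 3:
        out[corrupt] = value[corrupt][:, None]
    else:
        out[corrupt] = value[corrupt]
    return out


def gaussian_blur(image: np.ndarray, sigma: float) -> np.ndarray:
    """Channel-wise Gaussian smoothing (kernel truncated at 4 sigma,
    reflect boundary).  ``sigma = 0`` is the identity."""
    image = np.asarray(image, dtype=np.float32)
    if sigma == 0:
        return image.copy()
    sigmas = (sigma, sigma, 0) if image.ndim == 3 else (sigma, sigma)
    return gaussian_filter(image, sigma=sigmas, truncate=4.0, mode="reflect")


def apply_noise(image: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    if spec.kind == "speckle":
        return inject_speckle(image, spec.level, spec.seed)
    if spec.kind == "salt_pepper":
        return inject_salt_pepper(image, spec.level, spec.seed)
    return gaussian_blur(image, spec.level)


#: The nine-cell robustness grid: three levels for each noise family.
DEFAULT_NOISE_GRID = tuple(
    [NoiseSpec("speckle", s) for s in (0.1, 0.2, 0.3)]
    + [NoiseSpec("salt_pepper", p) for p in (0.05, 0.1, 0.15)]
    + [NoiseSpec("gaussian_blur", s) for s in (0.2, 0.4, 0.6)]
)


def robustness_grid(
    clf: HybridSNNClassifier,
    X: np.ndarray,
    y: np.ndarray,
    grid: tuple[NoiseSpec, ...] = DEFAULT_NOISE_GRID,
    seed: int = 0,
) -> "pd.DataFrame":
    """Evaluate a trained classifier on noise-corrupted evaluation images.

    Returns a table with one row per (kind, level) cell carrying the full
    metric set; a ``report`` column holds the :class:`MetricsReport`.
    """
    import pandas as pd

    y_idx = np.searchsorted(clf.classes_, np.asarray(y))
    rows = []
    for cell, spec in enumerate(grid):
        noisy = np.stack([
            apply_noise(X[i], NoiseSpec(spec.kind, spec.level,
                                        seed=seed * 100003 + cell * 1009 + i))
            for i in range(len(X))
        ])
        probs = clf.predict_proba(noisy)
        report = evaluate_predictions(
            y_idx, probs.argmax(1), probs, k=len(clf.classes_)
        )
        rows.append({"kind": spec.kind, "level": spec.level,
                     **report.as_dict(), "report": report})
    return pd.DataFrame(rows)


# ---- attention --------------------------------------------------------------

def normalize_heatmap(raw: np.ndarray) -> tuple[np.ndarray, bool]:
    """Min-max normalise a rectified map to [0, 1]; flag all-zero maps."""
    raw = np.maximum(raw, 0.0)
    peak = raw.max()
    if peak <= 0:
        return np.zeros_like(raw), True
    out = raw / peak
    return out, False


def attention_map(clf: HybridSNNClassifier, image: np.ndarray,
                  target_class: int, blend: float = 0.5) -> AttentionMap:
    """Gradient-weighted class-activation map from the CNN branch.

    The heatmap is the rectified, channel-summed product of the last conv
    stage's feature maps with the gradient of the target-class score at
    those maps (a first-order attribution), upsampled to image size and
    min-max normalised.  Because the backbone flattens into a dense layer
    rather than global-average pooling, per-location gradients are exact and
    no spatially pooled channel-weight approximation is needed.
    """
    maps, grads = clf.net_.capture_attention(
        np.asarray(image, dtype=np.float32), target_class
    )
    cam = (grads * maps).sum(axis=0)  # (h, w)
    heat, degenerate = normalize_heatmap(cam)
    h, w = image.shape[:2]
    heat = resize(heat, (h, w), order=1, preserve_range=True)
    heat, _ = normalize_heatmap(heat)
    # overlay: red-channel heat blended onto the (grey) input
    color = np.zeros((h, w, 3), dtype=np.float32)
    color[..., 0] = heat
    base = image if image.ndim == 3 else np.repeat(image[..., None], 3, 2)
    overlay = np.clip((1 - blend) * base + blend * color, 0.0, 1.0)
    return AttentionMap(heatmap=heat.astype(np.float32), overlay=overlay,
                        target_class=target_class, degenerate=degenerate)


# ---- ablation ---------------------------------------------------------------

def ablation_compare(
    dataset: Dataset,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    seed: int = 0,
    **estimator_params,
) -> dict:
    """Train the hybrid and CNN-only variants under identical conditions.

    Both models see the same training/validation indices and the same seed;
    the returned dict holds one report, confusion matrix and history each.
    """
    assert np.intersect1d(train_idx, val_idx).size == 0, \
        "train and validation indices overlap"
    out: dict = {"val_idx": np.asarray(val_idx)}
    y_val = dataset.labels[val_idx]
    for kind in ("hybrid", "cnn_only"):
        clf = HybridSNNClassifier(model_kind=kind, random_state=seed,
                                  **estimator_params)
        clf.fit(dataset.images[train_idx], dataset.labels[train_idx],
                dataset.images[val_idx], y_val)
        probs = clf.predict_proba(dataset.images[val_idx])
        y_pred = clf.classes_[probs.argmax(1)]
        y_val_idx = np.searchsorted(clf.classes_, y_val)
        out[kind] = {
            "model": clf,
            "report": evaluate_predictions(
                y_val_idx, np.searchsorted(clf.classes_, y_pred), probs,
                k=len(clf.classes_),
            ),
            "confusion": confusion(
                y_val_idx, np.searchsorted(clf.classes_, y_pred),
                k=len(clf.classes_),
            ),
            "history": clf.history_,
        }
    return out
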
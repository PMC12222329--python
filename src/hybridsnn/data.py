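"""Dataset loading, augmentation, SMOTE oversampling, folds and phantoms.

The three diagnostic classes are encoded as AD=0, CI=1 (mild cognitive
impairment; "MCI" is accepted as an alias on disk), CN=2 throughout.

Because real ADNI slices cannot be redistributed, :func:`synth_phantoms`
draws simple head phantoms whose class-dependent geometry mimics the
structural signatures the classifier is meant to detect: ventricular
enlargement (largest in AD), cortical thinning (thinnest in AD) and
hippocampal atrophy (smallest bright blob in AD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

CLASS_NAMES = ("AD", "CI", "CN")
CLASS_ALIASES = {"AD": 0, "CI": 1, "MCI": 1, "CN": 2}
IMAGE_SIZE = 128

__all__ = [
    "CLASS_NAMES",
    "ImageSample",
    "Dataset",
    "AugmentConfig",
    "FoldAssignment",
    "PhantomParams",
    "load_image_dir",
    "augment",
    "smote_oversample",
    "stratified_kfold",
    "synth_phantoms",
    "save_dataset",
]


@dataclass
class ImageSample:
    """A single labelled image: HxWx3 float array in [0, 1]."""

    pixels: np.ndarray
    label: int
    source_id: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be HxWx3, got {self.pixels.shape}")
        if self.label not in (0, 1, 2):
            raise ValueError(f"label must be in {{0,1,2}}, got {self.label}")
        self.pixels = np.clip(self.pixels, 0.0, 1.0)

    @property
    def class_name(self) -> str:
        return CLASS_NAMES[self.label]


@dataclass
class Dataset:
    """An ordered collection of labelled images stored as dense arrays."""

    images: np.ndarray  # (N, H, W, 3) float32 in [0, 1]
    labels: np.ndarray  # (N,) int
    source_ids: list[str]

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.images) != len(self.labels) or len(self.labels) != len(
            self.source_ids
        ):
            raise ValueError("images, labels and source_ids must align")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def class_counts(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.labels == i))
            for i, name in enumerate(CLASS_NAMES)
        }

    def subset(self, indices: np.ndarray) -> "Dataset":
        indices = np.asarray(indices)
        return Dataset(
            images=self.images[indices],
            labels=self.labels[indices],
            source_ids=[self.source_ids[i] for i in indices],
        )

    def samples(self):
        for i in range(len(self)):
            yield ImageSample(self.images[i], int(self.labels[i]),
                              self.source_ids[i])

    @classmethod
    def from_samples(cls, samples: list[ImageSample]) -> "Dataset":
        return cls(
            images=np.stack([s.pixels for s in samples]),
            labels=np.array([s.label for s in samples]),
            source_ids=[s.source_id for s in samples],
        )

    def concat(self, other: "Dataset") -> "Dataset":
        return Dataset(
            images=np.concatenate([self.images, other.images]),
            labels=np.concatenate([self.labels, other.labels]),
            source_ids=self.source_ids + other.source_ids,
        )


@dataclass(frozen=True)
class AugmentConfig:
    """On-the-fly augmentation: zoom, multiplicative brightness, h-flip.

    Ranges default to mild perturbations containing the identity; the flip is
    applied with probability ``hflip_prob``.
    """

    zoom_range: tuple[float, float] = (0.9, 1.1)
    brightness_range: tuple[float, float] = (0.8, 1.2)
    hflip_prob: float = 0.5

    def __post_init__(self) -> None:
        for lo, hi in (self.zoom_range, self.brightness_range):
            if not (lo <= hi and lo > 0):
                raise ValueError("ranges must be positive with lo <= hi")
        if not 0.0 <= self.hflip_prob <= 1.0:
            raise ValueError("hflip_prob must be in [0, 1]")


@dataclass(frozen=True)
class FoldAssignment:
    """Stratified k-fold assignment: fold index per sample."""

    fold_index: np.ndarray
    k: int
    seed: int

    def split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_indices, validation_indices) for one fold."""
        if not 0 <= fold < self.k:
            raise ValueError(f"fold must be in [0, {self.k})")
        val = np.where(self.fold_index == fold)[0]
        train = np.where(self.fold_index != fold)[0]
        return train, val


# effect-size orderings (pixels at 128x128): AD has the largest ventricles,
# the thinnest cortical ring and the smallest hippocampal blob
_DEFAULT_VENTRICLE = {"AD": 16.0, "CI": 11.5, "CN": 7.0}
_DEFAULT_CORTEX = {"AD": 3.5, "CI": 6.0, "CN": 8.5}
_DEFAULT_HIPPO = {"AD": 3.5, "CI": 5.5, "CN": 7.5}


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and noise of the synthetic 3-class head phantom."""

    image_size: int = IMAGE_SIZE
    ventricle_radius: dict = field(
        default_factory=lambda: dict(_DEFAULT_VENTRICLE))
    cortex_thickness: dict = field(
        default_factory=lambda: dict(_DEFAULT_CORTEX))
    hippocampus_radius: dict = field(
        default_factory=lambda: dict(_DEFAULT_HIPPO))
    pixel_noise_sd: float = 0.05
    jitter: float = 0.1  # relative size/position variability per sample
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        if self.pixel_noise_sd < 0:
            raise ValueError("pixel_noise_sd must be >= 0")
        # ventricle and cortex orderings may tie (e.g. a phantom family whose
        # only discriminating structure is the hippocampal blob), but must
        # never invert; the hippocampus ordering is strict.
        if not (
            self.ventricle_radius["AD"] >= self.ventricle_radius["CI"]
            >= self.ventricle_radius["CN"] > 0
        ):
            raise ValueError("ventricle radii must be ordered AD >= CI >= CN")
        if not (
            0 < self.cortex_thickness["AD"] <= self.cortex_thickness["CI"]
            <= self.cortex_thickness["CN"]
        ):
            raise ValueError("cortex thickness must be ordered AD <= CI <= CN")
        if not (
            0 < self.hippocampus_radius["AD"] < self.hippocampus_radius["CI"]
            < self.hippocampus_radius["CN"]
        ):
            raise ValueError("hippocampus radii must be ordered AD < CI < CN")


# ---- loading ----------------------------------------------------------------

_IMG_SUFFIXES = {".png", ".jpg", ".jpeg"}
_NIFTI_SUFFIXES = {".nii", ".gz"}


def _load_one(path: Path, slice_index: int | None,
              image_size: int = IMAGE_SIZE) -> np.ndarray:
    """Decode one file to an image_size x image_size x 3 float array in
    [0, 1]."""
    suffix = path.suffix.lower()
    if suffix in _IMG_SUFFIXES:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0
    elif suffix in _NIFTI_SUFFIXES or path.name.lower().endswith(".nii.gz"):
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float32)
        if vol.ndim < 3:
            sl = vol if vol.ndim == 2 else vol[..., 0]
        else:
            idx = vol.shape[2] // 2 if slice_index is None else slice_index
            sl = vol[:, :, idx]
        lo, hi = float(sl.min()), float(sl.max())
        sl = (sl - lo) / (hi - lo) if hi > lo else np.zeros_like(sl)
        arr = np.repeat(sl[:, :, None], 3, axis=2)
    else:
        raise IOError(f"unsupported image format: {path}")
    if arr.shape[:2] != (image_size, image_size):
        arr = resize(arr, (image_size, image_size), order=1,
                     preserve_range=True, anti_aliasing=True)
    return np.clip(arr.astype(np.float32), 0.0, 1.0)


def load_image_dir(
    path: str | Path,
    expected_classes: tuple[str, ...] = CLASS_NAMES,
    slice_index: int | None = None,
    image_size: int = IMAGE_SIZE,
) -> Dataset:
    """Load a class-foldered image directory into a :class:`Dataset`.

    Each sub-directory names a class (``AD``, ``CI``/``MCI``, ``CN``); files
    may be PNG/JPEG images or NIfTI volumes, from which a single axial slice
    (middle by default) is extracted.
    """
    root = Path(path)
    if not root.is_dir():
        raise IOError(f"not a directory: {root}")
    samples: list[ImageSample] = []
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        name = sub.name.upper()
        if name not in CLASS_ALIASES:
            raise ValueError(
                f"unknown class directory {sub.name!r}; expected one of "
                f"{sorted(set(CLASS_ALIASES))}"
            )
        label = CLASS_ALIASES[name]
        files = sorted(
            f for f in sub.iterdir()
            if f.is_file() and (
                f.suffix.lower() in _IMG_SUFFIXES
                or f.name.lower().endswith((".nii", ".nii.gz"))
            )
        )
        if not files:
            logger.warning("class directory %s is empty", sub)
        for f in files:
            try:
                arr = _load_one(f, slice_index, image_size)
            except Exception as exc:  # re-raise with the offending path
                raise IOError(f"failed to read {f}: {exc}") from exc
            samples.append(ImageSample(arr, label, f"{name}/{f.name}"))
    if not samples:
        return Dataset(
            images=np.zeros((0, image_size, image_size, 3), dtype=np.float32),
            labels=np.zeros(0, dtype=int), source_ids=[],
        )
    return Dataset.from_samples(samples)


# ---- augmentation -----------------------------------------------------------

def _resize_bilinear(img: np.ndarray, h: int, w: int) -> np.ndarray:
    """Fast float bilinear resize (PIL per channel)."""
    if img.ndim == 2:
        return np.asarray(
            Image.fromarray(img, mode="F").resize((w, h), Image.BILINEAR)
        )
    return np.stack([
        np.asarray(Image.fromarray(np.ascontiguousarray(img[..., c]),
                                   mode="F").resize((w, h), Image.BILINEAR))
        for c in range(img.shape[2])
    ], axis=2)


def _zoom_image(img: np.ndarray, factor: float) -> np.ndarray:
    """Centre zoom: crop-and-resize for factor>1, pad-and-resize for <1."""
    if factor == 1.0:
        return img
    h, w = img.shape[:2]
    if factor > 1.0:
        ch, cw = max(1, round(h / factor)), max(1, round(w / factor))
        top, left = (h - ch) // 2, (w - cw) // 2
        out = _resize_bilinear(img[top:top + ch, left:left + cw], h, w)
    else:
        ph, pw = round(h / factor), round(w / factor)
        pad_t, pad_l = (ph - h) // 2, (pw - w) // 2
        padded = np.zeros((ph, pw) + img.shape[2:], dtype=np.float32)
        padded[pad_t:pad_t + h, pad_l:pad_l + w] = img
        out = _resize_bilinear(padded, h, w)
    return out.astype(np.float32)


def augment(
    sample: ImageSample,
    config: AugmentConfig = AugmentConfig(),
    seed: int | np.random.Generator = 0,
) -> ImageSample:
    """Randomly zoom, rescale brightness and maybe flip one sample.

    Deterministic given the seed; the label is unchanged and pixels stay
    clipped to [0, 1].
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    z = rng.uniform(*config.zoom_range)
    b = rng.uniform(*config.brightness_range)
    flip = rng.random() < config.hflip_prob
    img = _zoom_image(sample.pixels, z)
    img = np.clip(img * b, 0.0, 1.0)
    if flip:
        img = img[:, ::-1, :].copy()
    return ImageSample(img, sample.label, sample.source_id)


def augment_batch(images: np.ndarray, config: AugmentConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Vector form used inside the training loop (labels untouched)."""
    out = np.empty_like(images)
    for i in range(len(images)):
        z = rng.uniform(*config.zoom_range)
        b = rng.uniform(*config.brightness_range)
        flip = rng.random() < config.hflip_prob
        img = _zoom_image(images[i], z)
        img = np.clip(img * b, 0.0, 1.0)
        if flip:
            img = img[:, ::-1, :]
        out[i] = img
    return out


# ---- SMOTE ------------------------------------------------------------------

def smote_oversample(
    dataset: Dataset,
    k_neighbors: int = 5,
    seed: int | np.random.Generator = 0,
) -> Dataset:
    """Equalise class counts by synthetic-minority oversampling.

    Each synthetic image is a convex combination ``x + u (x_nn - x)`` of a
    minority sample and one of its ``k_neighbors`` nearest same-class
    neighbours (Euclidean distance on flattened pixels), ``u ~ U(0, 1)``.
    Must only ever be applied to the training split of a fold.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    counts = np.bincount(dataset.labels, minlength=len(CLASS_NAMES))
    present = np.where(counts > 0)[0]
    majority = counts.max()
    new_samples: list[ImageSample] = []
    for cls in present:
        deficit = majority - counts[cls]
        if deficit == 0:
            continue
        if counts[cls] < k_neighbors + 1:
            raise ValueError(
                f"class {CLASS_NAMES[cls]} has {counts[cls]} samples; "
                f"SMOTE with k={k_neighbors} needs at least {k_neighbors + 1}"
            )
        idx = np.where(dataset.labels == cls)[0]
        flat = dataset.images[idx].reshape(len(idx), -1)
        nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(flat)
        # drop self-matches in column 0
        neigh = nn.kneighbors(flat, return_distance=False)[:, 1:]
        for _ in range(deficit):
            i = rng.integers(len(idx))
            j = neigh[i, rng.integers(k_neighbors)]
            u = rng.uniform()
            synth = flat[i] + u * (flat[j] - flat[i])
            new_samples.append(ImageSample(
                synth.reshape(dataset.images.shape[1:]),
                int(cls),
                f"smote:{dataset.source_ids[idx[i]]}+{dataset.source_ids[idx[j]]}",
            ))
    if not new_samples:
        return dataset
    return dataset.concat(Dataset.from_samples(new_samples))


# ---- folds ------------------------------------------------------------------

def stratified_kfold(dataset: Dataset, k: int = 5,
                     seed: int = 0) -> FoldAssignment:
    """Shuffled, class-stratified k-fold partition, deterministic per seed."""
    counts = np.bincount(dataset.labels, minlength=1)
    small = counts[(counts > 0) & (counts < k)]
    if small.size:
        raise ValueError(f"every class needs >= {k} samples for {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_index = np.empty(len(dataset), dtype=int)
    for fold, (_, val) in enumerate(
        skf.split(np.zeros(len(dataset)), dataset.labels)
    ):
        fold_index[val] = fold
    return FoldAssignment(fold_index=fold_index, k=k, seed=seed)


# ---- phantoms ---------------------------------------------------------------

def _draw_phantom(rng: np.random.Generator, params: PhantomParams,
                  class_name: str) -> np.ndarray:
    """One noiseless-to-noisy head phantom for the given class."""
    n = params.image_size
    scale = n / IMAGE_SIZE
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float32)
    cy = n / 2 + rng.uniform(-3, 3) * scale * (params.jitter / 0.1)
    cx = n / 2 + rng.uniform(-3, 3) * scale * (params.jitter / 0.1)
    j = lambda: rng.uniform(1 - params.jitter, 1 + params.jitter)

    a, b = 0.40 * n * j(), 0.34 * n * j()  # head semi-axes
    rho = np.sqrt(((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2)
    img = np.zeros((n, n), dtype=np.float32)
    img[rho <= 1.0] = 0.55

    tc = params.cortex_thickness[class_name] * scale * j()
    ring_lo = 1.0 - tc / (0.37 * n)
    img[(rho <= 1.0) & (rho >= ring_lo)] = 0.8

    rv = params.ventricle_radius[class_name] * scale * j()
    vent = ((xx - cx) / rv) ** 2 + ((yy - cy) / (0.65 * rv)) ** 2
    img[vent <= 1.0] = 0.08

    rh = params.hippocampus_radius[class_name] * scale * j()
    hy = cy + 0.11 * n + rng.uniform(-2, 2) * scale
    hx = cx + 0.16 * n + rng.uniform(-2, 2) * scale
    hip = (xx - hx) ** 2 + (yy - hy) ** 2
    img[hip <= rh**2] = 0.9

    if params.pixel_noise_sd > 0:
        img = img + rng.normal(0, params.pixel_noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return np.repeat(img[:, :, None], 3, axis=2)


def synth_phantoms(params: PhantomParams = PhantomParams(),
                   n_per_class: int = 50) -> Dataset:
    """Generate a balanced, labelled phantom dataset (deterministic per seed)."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(params.seed)
    samples: list[ImageSample] = []
    for label, name in enumerate(CLASS_NAMES):
        for i in range(n_per_class):
            img = _draw_phantom(rng, params, name)
            samples.append(ImageSample(img, label, f"phantom:{name}:{i}"))
    return Dataset.from_samples(samples)


def save_dataset(dataset: Dataset, out_dir: str | Path) -> Path:
    """Write a dataset as class-foldered PNGs plus a TSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = ["sample_id\tclass\tfile"]
    for i, sample in enumerate(dataset.samples()):
        sub = out / sample.class_name
        sub.mkdir(exist_ok=True)
        fname = f"{i:05d}.png"
        arr = (sample.pixels * 255).round().astype(np.uint8)
        Image.fromarray(arr).save(sub / fname)
        rows.append(f"{sample.source_id}\t{sample.class_name}\t"
                    f"{sample.class_name}/{fname}")
    (out / "manifest.tsv").write_text("\n".join(rows) + "\n")
    return out
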
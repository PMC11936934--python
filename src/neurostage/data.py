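"""Dataset scanning, class balancing, augmentation and phantom generation.

The balancing scheme mirrors common practice for the five-class ADNI-style
dementia problem: over-represented classes are capped by seeded random
selection (default cap 500), and under-represented classes are expanded to an
explicit target count by rotation / scaling / flipping augmentation (e.g. a
144-image class tripled to 432).

Because real ADNI/OASIS images are access-restricted, a synthetic
brain-phantom generator provides class-separable stand-ins: an elliptical
head with textured interior tissue, a central ventricle whose area grows
monotonically with disease grade, a cortical band that thins with grade, and
additive Gaussian noise.  Grades are separable by construction in the
two-feature summary (mean interior intensity, ventricle area).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from PIL import Image
from skimage import transform as sktransform

from .exceptions import DataError, ParameterError

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg"}

#: severity-ordered default class names for the five-grade problem
ADNI_CLASSES = ["CN", "EMCI", "MCI", "LMCI", "AD"]

__all__ = [
    "DatasetManifest",
    "BalancePlan",
    "AugmentationConfig",
    "PhantomConfig",
    "derive_seed",
    "load_image",
    "save_image",
    "scan_dataset",
    "select_utilized",
    "augment_to_target",
    "phantom_image",
    "generate_phantom_dataset",
    "stratified_split",
]


def derive_seed(master: int, *names: str) -> int:
    """Stable sub-seed below 2**31 derived from a master seed and stage names,
    so adding a stage never perturbs another stage's randomness."""
    digest = hashlib.sha256(":".join([str(master), *names]).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class DatasetManifest:
    """Ordered class labels and per-class image path lists."""

    classes: list
    files: dict

    @property
    def counts(self) -> dict:
        return {label: len(paths) for label, paths in self.files.items()}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"path": str(p), "label": label}
            for label in self.classes
            for p in self.files[label]
        ]
        return pd.DataFrame(rows, columns=["path", "label"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DatasetManifest":
        frame = pd.read_csv(path)
        classes = list(dict.fromkeys(frame["label"]))
        files = {
            label: [Path(p) for p in frame.loc[frame["label"] == label, "path"]]
            for label in classes
        }
        return cls(classes=classes, files=files)


@dataclass(frozen=True)
class BalancePlan:
    """Per-class cap plus explicit augmentation targets (label -> count)."""

    per_class_cap: int = 500
    augment_targets: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.per_class_cap < 1:
            raise ParameterError(f"per_class_cap must be >= 1, got {self.per_class_cap}")


@dataclass(frozen=True)
class AugmentationConfig:
    """Operation families used to expand a class: rotation angles (degrees),
    scale ratios (center-cropped/padded back to size) and flips."""

    rotation_angles: tuple = (90.0, 180.0, 270.0, 10.0, -10.0)
    scale_range: tuple = (0.9, 1.1)
    flips: tuple = ("horizontal", "vertical")
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.scale_range):
            raise ParameterError(f"scale ratios must be > 0, got {self.scale_range}")
        for f in self.flips:
            if f not in ("horizontal", "vertical"):
                raise ParameterError(f"unknown flip axis {f!r}")


@dataclass(frozen=True)
class PhantomConfig:
    """Synthetic brain-slice generator settings.

    ``class_geometry`` optionally overrides the per-class severity values in
    ``[0, 1]`` that drive ventricle size and cortical thinning; by default
    severities are evenly spaced across classes.
    """

    n_classes: int = 5
    per_class: int = 100
    image_size: tuple = (64, 64)
    class_geometry: tuple | None = None
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.per_class < 1:
            raise ParameterError(f"per_class must be >= 1, got {self.per_class}")
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_classes < 2:
            raise ParameterError(f"n_classes must be >= 2, got {self.n_classes}")

    def severities(self) -> np.ndarray:
        if self.class_geometry is not None:
            return np.asarray(self.class_geometry, dtype=np.float64)
        return np.linspace(0.0, 1.0, self.n_classes)

    def class_names(self) -> list:
        if self.n_classes == len(ADNI_CLASSES):
            return list(ADNI_CLASSES)
        return [f"grade{i}" for i in range(self.n_classes)]


def load_image(path) -> np.ndarray:
    """Read PNG/JPEG as float64 in [0, 1]; grayscale stays 2-D."""
    with Image.open(path) as img:
        if img.mode not in ("L", "RGB"):
            img = img.convert("RGB")
        arr = np.asarray(img, dtype=np.float64) / 255.0
    return arr


def save_image(array: np.ndarray, path) -> None:
    """Write a [0, 1] float array as an 8-bit PNG/JPEG (round-half-even)."""
    scaled = np.clip(np.asarray(array, dtype=np.float64), 0.0, 1.0) * 255.0
    data = np.rint(scaled).astype(np.uint8)
    Image.fromarray(data).save(path)


def scan_dataset(root) -> DatasetManifest:
    """Build a deterministic manifest from a one-subdirectory-per-class tree.

    Files are lexicographically sorted; non-image files are skipped with a
    warning; an empty class directory is an error naming the class.
    """
    root = Path(root)
    if not root.is_dir():
        raise DataError(f"dataset root {root} is not a directory")
    classes = sorted(p.name for p in root.iterdir() if p.is_dir())
    if not classes:
        raise DataError(f"no class subdirectories under {root}")
    files: dict = {}
    for label in classes:
        paths = []
        for p in sorted((root / label).iterdir()):
            if p.is_dir():
                continue
            if p.suffix.lower() in IMAGE_EXTENSIONS:
                paths.append(p)
            else:
                logger.warning("skipping non-image file %s", p)
        if not paths:
            raise DataError(f"class directory {label!r} contains no images")
        files[label] = paths
    return DatasetManifest(classes=classes, files=files)


def select_utilized(manifest: DatasetManifest, plan: BalancePlan) -> DatasetManifest:
    """Cap each class at ``per_class_cap`` images by seeded uniform sampling
    without replacement; classes at or below the cap pass through untouched."""
    selected: dict = {}
    for label in manifest.classes:
        paths = manifest.files[label]
        if len(paths) <= plan.per_class_cap:
            selected[label] = list(paths)
            continue
        rng = np.random.default_rng(derive_seed(plan.seed, "select", label))
        idx = rng.choice(len(paths), size=plan.per_class_cap, replace=False)
        selected[label] = [paths[i] for i in sorted(idx)]
    return DatasetManifest(classes=list(manifest.classes), files=selected)


def _augment_ops(cfg: AugmentationConfig) -> list:
    ops = [(f"rot{int(a) if float(a).is_integer() else a}", ("rotate", a)) for a in cfg.rotation_angles]
    ops += [(f"scale{s}", ("scale", s)) for s in cfg.scale_range]
    ops += [(f"flip_{f[0]}", ("flip", f)) for f in cfg.flips]
    return ops


def _apply_op(image: np.ndarray, op: tuple) -> np.ndarray:
    kind, arg = op
    if kind == "rotate":
        return sktransform.rotate(image, arg, resize=False, mode="reflect", order=1)
    if kind == "flip":
        return np.flip(image, axis=1 if arg == "horizontal" else 0).copy()
    if kind == "scale":
        h, w = image.shape[:2]
        scaled = sktransform.rescale(
            image, arg, channel_axis=2 if image.ndim == 3 else None,
            mode="reflect", order=1, anti_aliasing=arg < 1,
        )
        sh, sw = scaled.shape[:2]
        if sh >= h:  # center crop
            top, left = (sh - h) // 2, (sw - w) // 2
            return scaled[top : top + h, left : left + w]
        pad_h, pad_w = h - sh, w - sw
        pads = [(pad_h // 2, pad_h - pad_h // 2), (pad_w // 2, pad_w - pad_w // 2)]
        if image.ndim == 3:
            pads.append((0, 0))
        return np.pad(scaled, pads, mode="reflect")
    raise ParameterError(f"unknown augmentation op {kind!r}")


def augment_to_target(files, target: int, cfg: AugmentationConfig, out_dir=None):
    """Expand ``files`` to exactly ``target`` paths by seeded round-robin over
    the source images and the operation set; every augmented file name encodes
    its source and operation.  Originals are never modified or removed."""
    files = [Path(f) for f in files]
    if not files:
        raise DataError("cannot augment an empty source list")
    if target < len(files):
        raise ParameterError(
            f"target ({target}) is below the current count ({len(files)})"
        )
    if target == len(files):
        return list(files)
    if out_dir is None:
        raise ParameterError("out_dir is required when new images must be written")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ops = _augment_ops(cfg)
    rng = np.random.default_rng(derive_seed(cfg.seed, "augment"))
    source_order = [files[i] for i in rng.permutation(len(files))]
    result = list(files)
    for i in range(target - len(files)):
        src = source_order[i % len(source_order)]
        op_name, op = ops[(i // len(source_order)) % len(ops)]
        out_path = out_dir / f"{src.stem}__aug{i:04d}_{op_name}{src.suffix}"
        save_image(_apply_op(load_image(src), op), out_path)
        result.append(out_path)
    return result


def _draw_ellipse_mask(shape, center, axes) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((yy - center[0]) / axes[0]) ** 2 + ((xx - center[1]) / axes[1]) ** 2 <= 1.0


def phantom_image(
    class_index: int,
    cfg: PhantomConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One grayscale brain phantom for the given disease grade.

    Geometry per grade (severity ``s`` in [0, 1]):

    * interior tissue intensity ``0.75 - 0.25 s`` (global atrophy darkening);
    * ventricle semi-axes ``(0.05 + 0.10 s) H`` by ``(0.04 + 0.08 s) W``
      (monotone area growth, the dominant separable feature);
    * cortical band thickness shrinking from 8% to 3% of the head radius.

    Per-image jitter (center shift, +-5% axis scaling, smooth texture) and
    additive Gaussian noise come from ``rng``.
    """
    h, w = cfg.image_size
    severity = float(cfg.severities()[class_index])
    img = np.zeros((h, w), dtype=np.float64)

    center = (h / 2 + rng.normal(0, 0.01 * h), w / 2 + rng.normal(0, 0.01 * w))
    head_axes = (
        0.42 * h * (1 + rng.uniform(-0.03, 0.03)),
        0.36 * w * (1 + rng.uniform(-0.03, 0.03)),
    )
    head = _draw_ellipse_mask((h, w), center, head_axes)

    tissue = 0.75 - 0.25 * severity
    img[head] = tissue

    # smooth tissue texture: low-frequency random field
    texture = ndimage.gaussian_filter(rng.normal(0, 1.0, size=(h, w)), sigma=3.0)
    img[head] += 0.05 * texture[head]

    # cortical band: brighter rim whose thickness thins with severity
    band_frac = 0.08 - 0.05 * severity
    inner = _draw_ellipse_mask(
        (h, w), center, (head_axes[0] * (1 - band_frac), head_axes[1] * (1 - band_frac))
    )
    img[head & ~inner] = np.clip(img[head & ~inner] + 0.15, 0, 1)

    # central ventricle (dark CSF), area monotone in severity
    vent_axes = (
        (0.05 + 0.10 * severity) * h * (1 + rng.uniform(-0.05, 0.05)),
        (0.04 + 0.08 * severity) * w * (1 + rng.uniform(-0.05, 0.05)),
    )
    vent = _draw_ellipse_mask((h, w), center, vent_axes)
    img[vent] = 0.08

    if cfg.noise_sd > 0:
        img = img + rng.normal(0, cfg.noise_sd, size=(h, w))
    return np.clip(img, 0.0, 1.0)


def generate_phantom_dataset(cfg: PhantomConfig, out_dir) -> DatasetManifest:
    """Write ``per_class`` phantoms per grade under ``out_dir/<class>/`` and
    return the manifest.  Fully determined by ``cfg.seed``."""
    out_dir = Path(out_dir)
    names = cfg.class_names()
    files: dict = {}
    for ci, name in enumerate(names):
        class_dir = out_dir / name
        class_dir.mkdir(parents=True, exist_ok=True)
        rng = np.random.default_rng(derive_seed(cfg.seed, "phantom", name))
        paths = []
        for j in range(cfg.per_class):
            path = class_dir / f"{name}_{j:04d}.png"
            save_image(phantom_image(ci, cfg, rng), path)
            paths.append(path)
        files[name] = paths
    return DatasetManifest(classes=names, files=files)


def stratified_split(
    manifest: DatasetManifest, fractions: tuple, seed: int
) -> tuple[DatasetManifest, DatasetManifest]:
    """Seeded per-class train/test split preserving class proportions to
    within one image.  Both fractions must be strictly positive and sum to 1."""
    train_frac, test_frac = fractions
    if train_frac <= 0 or test_frac <= 0:
        raise ParameterError(f"both fractions must be > 0, got {fractions}")
    if abs(train_frac + test_frac - 1.0) > 1e-9:
        raise ParameterError(f"fractions must sum to 1, got {fractions}")
    train_files: dict = {}
    test_files: dict = {}
    for label in manifest.classes:
        paths = manifest.files[label]
        if len(paths) < 2:
            raise DataError(f"class {label!r} has fewer than 2 images; cannot split")
        rng = np.random.default_rng(derive_seed(seed, "split", label))
        order = rng.permutation(len(paths))
        n_train = int(round(train_frac * len(paths)))
        n_train = min(max(n_train, 1), len(paths) - 1)  # both sides non-empty
        train_files[label] = [paths[i] for i in sorted(order[:n_train])]
        test_files[label] = [paths[i] for i in sorted(order[n_train:])]
    classes = list(manifest.classes)
    return (
        DatasetManifest(classes=classes, files=train_files),
        DatasetManifest(classes=classes, files=test_files),
    )
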
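"""Image-folder loading, preprocessing, stratified splitting and synthetic
weed-imagery generation.

Real data enters as a directory of class-labelled subfolders of PNG/JPEG
files (the layout used by the DeepWeeds release: eight weed species plus a
negative class, 256x256 RGB).  Images are decoded to RGB, bilinearly resized
and scaled to [0, 1].  The synthetic generator renders 9-class imagery with
class-dependent foliage hue, leaf-element scale and texture frequency over a
soil-toned background, so the full pipeline — preprocessing, training,
evaluation, robustness — runs with no download.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = [
    "DatasetBundle",
    "load_image_folder",
    "stratified_split",
    "generate_synthetic_dataset",
    "resize_normalize",
    "write_png_tree",
]

IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


@dataclass
class DatasetBundle:
    """Normalized images (N, 3, side, side) in [0, 1] with integer labels."""

    images: np.ndarray
    labels: np.ndarray
    class_names: list[str]
    split_tag: str = "all"

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have equal length")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def num_classes(self) -> int:
        return len(self.class_names)


def resize_normalize(img: Image.Image | np.ndarray, side: int = 224) -> np.ndarray:
    """Decode to RGB, bilinear-resize to ``side`` and scale by 1/255.

    Accepts a PIL image or an 8-bit HWC array; returns float32 (3, side, side).
    """
    if isinstance(img, np.ndarray):
        img = Image.fromarray(img)
    img = img.convert("RGB")
    if img.size != (side, side):
        img = img.resize((side, side), Image.BILINEAR)
    arr = np.asarray(img, dtype=np.float32) / 255.0
    return arr.transpose(2, 0, 1)


def load_image_folder(root: str | Path, side: int = 224) -> DatasetBundle:
    """Load a class-per-subdirectory image tree.

    Class indices follow sorted subdirectory-name order.  Unreadable files
    are skipped (with a logged count); empty class folders produce a warning.
    """
    root = Path(root)
    if not root.is_dir():
        raise NotADirectoryError(f"{root} is not a directory")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories found under {root}")
    images, labels = [], []
    skipped = 0
    for label, class_dir in enumerate(class_dirs):
        files = sorted(
            f for f in class_dir.iterdir() if f.suffix.lower() in IMAGE_SUFFIXES
        )
        if not files:
            logger.warning("class folder %s contains no images", class_dir.name)
        for f in files:
            try:
                with Image.open(f) as img:
                    images.append(resize_normalize(img, side))
            except OSError:
                skipped += 1
                continue
            labels.append(label)
    if skipped:
        logger.warning("skipped %d unreadable image files", skipped)
    return DatasetBundle(
        images=np.stack(images).astype(np.float32),
        labels=np.asarray(labels, dtype=np.int64),
        class_names=[d.name for d in class_dirs],
    )


def stratified_split(
    bundle: DatasetBundle, train_fraction: float = 0.8, seed: int = 42
) -> tuple[DatasetBundle, DatasetBundle]:
    """Per-class split: round(train_fraction * n_c) to train, rest to test.

    Deterministic under ``seed``; the two parts partition the input.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in np.unique(bundle.labels):
        idx = np.flatnonzero(bundle.labels == c)
        if len(idx) < 2:
            raise ValueError(f"class {c} has fewer than 2 items; cannot stratify")
        idx = rng.permutation(idx)
        n_train = round(train_fraction * len(idx))
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    train_idx = np.sort(np.asarray(train_idx))
    test_idx = np.sort(np.asarray(test_idx))

    def take(indices, tag):
        return DatasetBundle(
            images=bundle.images[indices],
            labels=bundle.labels[indices],
            class_names=bundle.class_names,
            split_tag=tag,
        )

    return take(train_idx, "train"), take(test_idx, "test")


# ---------------------------------------------------------------------------
# synthetic imagery
# ---------------------------------------------------------------------------


def _hsv_to_rgb(h, s, v):
    """Vectorized HSV -> RGB on arrays in [0, 1]."""
    i = np.floor(h * 6.0).astype(int) % 6
    f = h * 6.0 - np.floor(h * 6.0)
    p = v * (1.0 - s)
    q = v * (1.0 - s * f)
    t = v * (1.0 - s * (1.0 - f))
    choices = [
        (v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q),
    ]
    r = np.select([i == k for k in range(6)], [c[0] for c in choices])
    g = np.select([i == k for k in range(6)], [c[1] for c in choices])
    b = np.select([i == k for k in range(6)], [c[2] for c in choices])
    return np.stack([r, g, b])


def generate_synthetic_dataset(
    n_per_class: int = 30,
    num_classes: int = 9,
    side: int = 256,
    seed: int = 0,
    hue_separation: float = 1.0,
) -> DatasetBundle:
    """Procedurally render class-separable weed-like imagery.

    Each class has a base foliage hue (evenly spaced around the green-to-red
    portion of the hue wheel), a leaf-element scale and a texture frequency.
    Images are built from a soil-toned noisy background, a few dozen random
    elliptical "leaf" elements at class-dependent scale and hue, sinusoidal
    texture, and a global illumination jitter — emulating the class-dependent
    color/texture/scale statistics and the wide illumination range of field
    imagery.  Fully deterministic under ``seed``.

    ``hue_separation`` in [0, 1] scales inter-class hue spacing (1 = strong,
    easily separable classes; smaller values make classes overlap).
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float32)
    images, labels = [], []
    for c in range(num_classes):
        base_hue = (0.16 + 0.8 * hue_separation * c / num_classes) % 1.0
        leaf_scale = side * (0.04 + 0.05 * (c % 3))
        tex_freq = 2.0 + 3.0 * ((c // 3) % 3)
        n_leaves = 18 + 6 * (c % 4)
        for _ in range(n_per_class):
            # soil-toned noisy background
            soil_v = 0.35 + 0.1 * rng.random()
            img = _hsv_to_rgb(
                np.full((side, side), 0.08, np.float32),
                np.full((side, side), 0.45, np.float32),
                soil_v + 0.08 * rng.random((side, side)).astype(np.float32),
            )
            # leaf elements: ellipses at class-dependent scale and hue
            hue = np.full((side, side), np.nan, np.float32)
            for _leaf in range(n_leaves):
                cx, cy = rng.random(2) * side
                a = leaf_scale * (0.6 + 0.8 * rng.random())
                b = a * (0.3 + 0.4 * rng.random())
                theta = rng.random() * np.pi
                dx, dy = xx - cx, yy - cy
                u = dx * np.cos(theta) + dy * np.sin(theta)
                v = -dx * np.sin(theta) + dy * np.cos(theta)
                mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
                hue[mask] = (base_hue + 0.03 * rng.standard_normal()) % 1.0
            leaf_mask = ~np.isnan(hue)
            tex = 0.5 + 0.5 * np.sin(
                2 * np.pi * tex_freq * (xx + yy) / side + rng.random() * 2 * np.pi
            )
            sat = (0.55 + 0.25 * tex).astype(np.float32)
            val = (0.45 + 0.35 * tex).astype(np.float32)
            leaves = _hsv_to_rgb(np.nan_to_num(hue), sat, val)
            img = np.where(leaf_mask[None], leaves, img)
            # global illumination jitter
            img = img * (0.8 + 0.4 * rng.random())
            images.append(np.clip(img, 0.0, 1.0).astype(np.float32))
            labels.append(c)
    return DatasetBundle(
        images=np.stack(images),
        labels=np.asarray(labels, dtype=np.int64),
        class_names=[f"class_{c}" for c in range(num_classes)],
    )


def write_png_tree(bundle: DatasetBundle, out_dir: str | Path) -> Path:
    """Write a bundle as a class-per-subdirectory PNG tree (fixture layout)."""
    out_dir = Path(out_dir)
    counters = {name: 0 for name in bundle.class_names}
    for img, label in zip(bundle.images, bundle.labels):
        name = bundle.class_names[int(label)]
        class_dir = out_dir / name
        class_dir.mkdir(parents=True, exist_ok=True)
        arr = (img.transpose(1, 2, 0) * 255.0).round().astype(np.uint8)
        Image.fromarray(arr).save(class_dir / f"{name}_{counters[name]:04d}.png")
        counters[name] += 1
    return out_dir


def resize_bundle(bundle: DatasetBundle, side: int) -> DatasetBundle:
    """Bilinear-resize every image of a bundle to a new side length."""
    resized = np.stack(
        [
            resize_normalize(
                (img.transpose(1, 2, 0) * 255.0).round().astype(np.uint8), side
            )
            for img in bundle.images
        ]
    )
    return DatasetBundle(
        images=resized,
        labels=bundle.labels.copy(),
        class_names=list(bundle.class_names),
        split_tag=bundle.split_tag,
    )
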
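"""Controlled domain-shift transforms and the robustness-evaluation harness.

Six corruption families at three severities each model the appearance
changes of field deployment: photometric illumination changes (brightness,
contrast, gamma, white balance), weather-induced Gaussian blur, and a hue
shift standing in for soil/background color variation.  Exactly one
transform is applied at a time, on the preprocessed [0, 1] float image, with
the ground-truth label left unchanged.

Severity parameters:

========  ==============================================
family    severity 1 / 2 / 3
========  ==============================================
brightness  beta   = 0.10 / 0.20 / 0.30   (additive, clipped)
contrast    alpha  = 0.8 / 0.6 / 0.4      (rescale about the scalar mean)
gamma       gamma  = 0.8 / 1.2 / 1.6      (elementwise power)
white_balance  (sR, sG, sB) = (1.1, 1.0, 0.9) / (1.2, 1.0, 0.8) / (1.3, 1.0, 0.7)
gaussian_blur  kernel = 3 / 5 / 7         (sigma = 0.3*((k-1)*0.5 - 1) + 0.8)
hue_shift   |dh|   = 5 / 10 / 15 degrees  (both signs evaluated, F1 averaged)
========  ==============================================
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import convolve
from skimage.color import hsv2rgb, rgb2hsv
from sklearn.metrics import f1_score

from .data import DatasetBundle

__all__ = [
    "Perturbation",
    "RobustnessReport",
    "apply_brightness",
    "apply_contrast",
    "apply_gamma",
    "apply_white_balance",
    "apply_gaussian_blur",
    "apply_hue_shift",
    "apply_perturbation",
    "severity_grid",
    "gaussian_kernel",
    "evaluate_robustness",
]

FAMILIES = (
    "brightness",
    "contrast",
    "gamma",
    "white_balance",
    "gaussian_blur",
    "hue_shift",
)

SEVERITY_PARAMS: dict[str, tuple] = {
    "brightness": (0.10, 0.20, 0.30),
    "contrast": (0.8, 0.6, 0.4),
    "gamma": (0.8, 1.2, 1.6),
    "white_balance": ((1.1, 1.0, 0.9), (1.2, 1.0, 0.8), (1.3, 1.0, 0.7)),
    "gaussian_blur": (3, 5, 7),
    "hue_shift": (5.0, 10.0, 15.0),
}


@dataclass(frozen=True)
class Perturbation:
    """One corruption family at one severity with its parameter(s) theta."""

    family: str
    severity: int
    theta: object

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.severity not in (1, 2, 3):
            raise ValueError(f"severity must be 1..3, got {self.severity}")


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 3 or image.shape[0] != 3:
        raise ValueError(f"expected (3, H, W) image, got shape {image.shape}")
    if image.min() < 0.0 or image.max() > 1.0:
        raise ValueError("image values must lie in [0, 1]")
    return image


def apply_brightness(image: np.ndarray, beta: float) -> np.ndarray:
    """Additive brightness change: clip(I + beta)."""
    image = _check_image(image)
    if beta == 0.0:
        return image
    return np.clip(image + beta, 0.0, 1.0)


def apply_contrast(image: np.ndarray, alpha: float) -> np.ndarray:
    """Contrast rescale about the scalar mean intensity: clip(a(I - mu) + mu).

    ``mu`` is one scalar per image (mean over all pixels and channels).
    """
    image = _check_image(image)
    if alpha == 1.0:
        return image
    mu = image.mean()
    return np.clip(alpha * (image - mu) + mu, 0.0, 1.0)


def apply_gamma(image: np.ndarray, gamma: float) -> np.ndarray:
    """Elementwise power I**gamma; [0, 1] is closed under it, no clipping."""
    image = _check_image(image)
    if gamma == 1.0:
        return image
    return np.power(image, gamma)


def apply_white_balance(image: np.ndarray, scales: Sequence[float]) -> np.ndarray:
    """Per-channel scaling I_c * s_c, clipped to [0, 1]."""
    image = _check_image(image)
    scales = np.asarray(scales, dtype=np.float32)
    if scales.shape != (3,):
        raise ValueError("scales must be an (R, G, B) triple")
    if np.all(scales == 1.0):
        return image
    return np.clip(image * scales[:, None, None], 0.0, 1.0)


def gaussian_kernel(kernel_size: int) -> np.ndarray:
    """Normalized 2-D Gaussian kernel with sigma = 0.3*((k-1)*0.5 - 1) + 0.8."""
    if kernel_size < 3 or kernel_size % 2 == 0:
        raise ValueError(f"kernel_size must be odd and >= 3, got {kernel_size}")
    sigma = 0.3 * ((kernel_size - 1) * 0.5 - 1.0) + 0.8
    half = kernel_size // 2
    coords = np.arange(-half, half + 1, dtype=np.float64)
    g = np.exp(-(coords**2) / (2.0 * sigma**2))
    kernel = np.outer(g, g)
    return (kernel / kernel.sum()).astype(np.float32)


def apply_gaussian_blur(image: np.ndarray, kernel_size: int) -> np.ndarray:
    """Per-channel convolution with a unit-sum Gaussian, reflective borders."""
    image = _check_image(image)
    kernel = gaussian_kernel(kernel_size)
    out = np.stack([convolve(ch, kernel, mode="reflect") for ch in image])
    return np.clip(out, 0.0, 1.0)


def apply_hue_shift(image: np.ndarray, delta_degrees: float) -> np.ndarray:
    """Rotate hue by delta degrees in HSV space; S and V untouched."""
    image = _check_image(image)
    hsv = rgb2hsv(image.transpose(1, 2, 0))
    hsv[..., 0] = (hsv[..., 0] + delta_degrees / 360.0) % 1.0
    out = hsv2rgb(hsv).transpose(2, 0, 1).astype(np.float32)
    return np.clip(out, 0.0, 1.0)


_APPLY: dict[str, Callable] = {
    "brightness": apply_brightness,
    "contrast": apply_contrast,
    "gamma": apply_gamma,
    "white_balance": apply_white_balance,
    "gaussian_blur": apply_gaussian_blur,
    "hue_shift": apply_hue_shift,
}


def apply_perturbation(image: np.ndarray, p: Perturbation) -> np.ndarray:
    """Apply a single transform T(.; theta) to one image."""
    return _APPLY[p.family](image, p.theta)


def severity_grid() -> list[Perturbation]:
    """The full 6-family x 3-severity corruption grid (18 perturbations)."""
    return [
        Perturbation(family, severity, SEVERITY_PARAMS[family][severity - 1])
        for family in FAMILIES
        for severity in (1, 2, 3)
    ]


@dataclass
class RobustnessReport:
    """Macro-F1 under each corruption, with the drop relative to clean."""

    table: pd.DataFrame
    clean_f1: float


def _macro_f1_pct(model, images: np.ndarray, labels: np.ndarray, batch: int) -> float:
    preds = []
    for start in range(0, len(images), batch):
        logits = model(images[start : start + batch])
        preds.append(np.argmax(logits, axis=1))
    preds = np.concatenate(preds)
    return 100.0 * f1_score(labels, preds, average="macro", zero_division=0)


def evaluate_robustness(
    model: Callable[[np.ndarray], np.ndarray],
    dataset: DatasetBundle,
    grid: list[Perturbation] | None = None,
    batch_size: int = 32,
) -> RobustnessReport:
    """Macro-F1 on the clean set and under every corruption of the grid.

    ``model`` maps an image batch (N, 3, H, W) to logits.  Labels are never
    modified.  Hue-shift rows evaluate the +dh and -dh rotations separately
    and report the mean of the two F1 scores (the symmetric reading of a
    signed shift).
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    if grid is None:
        grid = severity_grid()
    clean_f1 = _macro_f1_pct(model, dataset.images, dataset.labels, batch_size)
    rows = [
        {"family": "clean", "severity": 0, "f1_pct": clean_f1, "delta_f1_pct": 0.0}
    ]
    for p in sorted(grid, key=lambda q: (FAMILIES.index(q.family), q.severity)):
        if p.family == "hue_shift":
            f1s = []
            for sign in (+1.0, -1.0):
                shifted = np.stack(
                    [apply_hue_shift(img, sign * p.theta) for img in dataset.images]
                )
                f1s.append(_macro_f1_pct(model, shifted, dataset.labels, batch_size))
            f1 = float(np.mean(f1s))
        else:
            corrupted = np.stack(
                [apply_perturbation(img, p) for img in dataset.images]
            )
            f1 = _macro_f1_pct(model, corrupted, dataset.labels, batch_size)
        rows.append(
            {
                "family": p.family,
                "severity": p.severity,
                "f1_pct": f1,
                "delta_f1_pct": f1 - clean_f1,
            }
        )
    return RobustnessReport(table=pd.DataFrame(rows), clean_f1=clean_f1)
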
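"""Deterministic image conditioning: gamma correction, median filtering, resize.

Pipeline order is fixed: gamma -> median -> resize.  Stochastic
augmentation (see :mod:`histonet.augment`) operates on the original image
before the final resize.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "PreprocessConfig",
    "adaptive_gamma",
    "apply_gamma",
    "median_filter",
    "resize_to_input",
    "preprocess_image",
]


@dataclass
class PreprocessConfig:
    gamma_mode: str = "adaptive"  # or "fixed"
    gamma_fixed: float = 1.0
    gamma_clip: Tuple[float, float] = (0.5, 2.0)
    median_kernel: int = 3
    target_size: int = 224

    def __post_init__(self):
        if self.gamma_mode not in ("adaptive", "fixed"):
            raise ValueError("gamma_mode must be 'adaptive' or 'fixed'")
        if self.gamma_fixed <= 0:
            raise ValueError("gamma_fixed must be positive")
        if self.median_kernel % 2 == 0 or self.median_kernel < 1:
            raise ValueError("median_kernel must be odd and positive")
        lo, hi = self.gamma_clip
        if lo > hi:
            raise ValueError("gamma_clip must be (low, high) with low <= high")
        if self.target_size < 8:
            raise ValueError("target_size must be >= 8")


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3 or img.dtype != np.uint8:
        raise ValueError("expected an H x W x 3 uint8 RGB array")
    return img


def adaptive_gamma(img: np.ndarray, clip: Tuple[float, float] = (0.5, 2.0)) -> float:
    """Gamma from the intensity distribution: ``log(0.5)/log(mean/255)``.

    The normalized mean luminance is clamped to [0.01, 0.99] before the log,
    and the result is clipped to ``clip`` so mid-gray images map to gamma 1
    while extreme images cannot collapse contrast.
    """
    img = _check_image(img)
    m = float(img.mean()) / 255.0
    m = min(max(m, 0.01), 0.99)
    gamma = np.log(0.5) / np.log(m)
    return float(np.clip(gamma, clip[0], clip[1]))


def apply_gamma(img: np.ndarray, gamma: float) -> np.ndarray:
    """``out = round(255 * (in/255) ** gamma)`` per channel (monotone)."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    img = _check_image(img)
    lut = np.round(255.0 * (np.arange(256) / 255.0) ** gamma).astype(np.uint8)
    return lut[img]


def median_filter(img: np.ndarray, k: int = 3) -> np.ndarray:
    """Per-channel k x k median with edge-replication padding."""
    if k % 2 == 0 or k < 1:
        raise ValueError("median kernel must be odd and positive")
    img = _check_image(img)
    if k > min(img.shape[0], img.shape[1]):
        raise ValueError("kernel larger than image")
    out = np.empty_like(img)
    for c in range(3):
        out[:, :, c] = ndimage.median_filter(img[:, :, c], size=k, mode="nearest")
    return out


def resize_to_input(img: np.ndarray, size: int = 224) -> np.ndarray:
    """Plain bilinear rescale to size x size (aspect ratio not preserved)."""
    if size < 8:
        raise ValueError("size must be >= 8")
    img = _check_image(img)
    if img.shape[0] == size and img.shape[1] == size:
        return img.copy()
    return np.asarray(Image.fromarray(img).resize((size, size), Image.BILINEAR))


def preprocess_image(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    cfg = cfg or PreprocessConfig()
    gamma = (
        adaptive_gamma(img, cfg.gamma_clip)
        if cfg.gamma_mode == "adaptive"
        else cfg.gamma_fixed
    )
    out = apply_gamma(img, gamma)
    out = median_filter(out, cfg.median_kernel)
    return resize_to_input(out, cfg.target_size)
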
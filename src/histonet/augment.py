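"""Stochastic training-time augmentation with seeded reproducibility.

Transforms: elastic deformation, horizontal/vertical flips, and random
crop-and-resize.  Augmentation is applied to training folds only; the same
generator state reproduces the same augmented stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

from .preprocess import resize_to_input

__all__ = [
    "AugmentConfig",
    "elastic_transform",
    "flip",
    "random_crop_resize",
    "augment_pipeline",
    "sample_rng",
]


@dataclass
class AugmentConfig:
    elastic_alpha: float = 30.0
    elastic_sigma: float = 8.0
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    crop_scale: Tuple[float, float] = (0.7, 1.0)
    out_size: int = 224
    seed: int = 0

    def __post_init__(self):
        if self.elastic_alpha < 0:
            raise ValueError("elastic_alpha must be >= 0")
        if self.elastic_sigma <= 0:
            raise ValueError("elastic_sigma must be positive")
        for p in (self.p_hflip, self.p_vflip):
            if not (0.0 <= p <= 1.0):
                raise ValueError("flip probabilities must lie in [0, 1]")
        lo, hi = self.crop_scale
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("crop_scale must satisfy 0 < low <= high <= 1")


def sample_rng(global_seed: int, image_index: int, epoch: int) -> np.random.Generator:
    """Per-sample generator stream so parallel loading stays reproducible."""
    return np.random.default_rng(np.random.SeedSequence((global_seed, image_index, epoch)))


def elastic_transform(img: np.ndarray, alpha: float, sigma: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Gaussian-smoothed random displacement field, bilinear warp.

    Two independent uniform(-1, 1) fields are smoothed at scale ``sigma``,
    scaled by ``alpha`` pixels, and applied with edge replication.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    img = np.asarray(img)
    if alpha == 0:
        return img.copy()
    h, w = img.shape[:2]
    dx = ndimage.gaussian_filter(rng.uniform(-1, 1, (h, w)), sigma) * alpha
    dy = ndimage.gaussian_filter(rng.uniform(-1, 1, (h, w)), sigma) * alpha
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = (yy + dy, xx + dx)
    out = np.empty_like(img)
    for c in range(img.shape[2]):
        warped = ndimage.map_coordinates(
            img[:, :, c].astype(np.float64), coords, order=1, mode="nearest"
        )
        out[:, :, c] = np.clip(np.round(warped), 0, 255).astype(img.dtype)
    return out


def flip(img: np.ndarray, axis: str) -> np.ndarray:
    """Mirror about the named axis ('horizontal' reverses columns)."""
    if axis == "horizontal":
        return np.asarray(img)[:, ::-1].copy()
    if axis == "vertical":
        return np.asarray(img)[::-1].copy()
    raise ValueError("axis must be 'horizontal' or 'vertical'")


def random_crop_resize(img: np.ndarray, scale: Tuple[float, float], out_size: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Crop a random window with area fraction uniform in ``scale``, resize."""
    lo, hi = scale
    if not (0.0 < lo <= hi <= 1.0):
        raise ValueError("scale must satisfy 0 < low <= high <= 1")
    img = np.asarray(img)
    h, w = img.shape[:2]
    for attempt in range(10):
        frac = rng.uniform(lo, hi)
        side = np.sqrt(frac)
        ch, cw = max(int(round(h * side)), 1), max(int(round(w * side)), 1)
        if ch >= 2 and cw >= 2:
            top = rng.integers(0, h - ch + 1)
            left = rng.integers(0, w - cw + 1)
            return resize_to_input(img[top:top + ch, left:left + cw], out_size)
        lo = min(1.0, lo * 2)  # retry with a larger fraction
        hi = max(hi, lo)
    raise ValueError("crop window smaller than 2x2 after 10 attempts")


def augment_pipeline(img: np.ndarray, cfg: AugmentConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """elastic -> maybe-hflip -> maybe-vflip -> random crop-and-resize."""
    out = np.asarray(img)
    if cfg.elastic_alpha > 0:
        out = elastic_transform(out, cfg.elastic_alpha, cfg.elastic_sigma, rng)
    if cfg.p_hflip and rng.random() < cfg.p_hflip:
        out = flip(out, "horizontal")
    if cfg.p_vflip and rng.random() < cfg.p_vflip:
        out = flip(out, "vertical")
    return random_crop_resize(out, cfg.crop_scale, cfg.out_size, rng)
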
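"""Gradient-weighted class-activation saliency over the final stage, with
blue-to-red overlays."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image
from scipy import ndimage

from .arch import HistoNet
from .nn import Tensor

__all__ = ["SaliencyMap", "gradcam", "overlay", "side_by_side"]


@dataclass
class SaliencyMap:
    weights: np.ndarray  # (H, W) in [0, 1], aligned to the input grid
    target_class: int
    source_layer: str = "stage4"


def _upsample_bilinear(arr: np.ndarray, size: int) -> np.ndarray:
    zoom = (size / arr.shape[0], size / arr.shape[1])
    return ndimage.zoom(arr, zoom, order=1, mode="nearest", grid_mode=True)


def gradcam(model: HistoNet, image_chw: np.ndarray, target_class: int,
            input_size: Optional[int] = None) -> SaliencyMap:
    """Saliency = rectified, gradient-weighted sum of final-stage feature maps.

    Channel weights are the global-average-pooled gradients of the target
    logit with respect to the last bottleneck stage's output (taken after any
    attention gating), min-max normalized to [0, 1] and bilinearly upsampled
    to the input grid.  One class per call.
    """
    x = np.asarray(image_chw, dtype=np.float32)
    if x.ndim != 3 or x.shape[0] != 3:
        raise ValueError("expected a (3, H, W) image")
    if not (0 <= target_class < model.cfg.num_classes):
        raise ValueError(f"invalid class index {target_class}")
    size = input_size or x.shape[1]
    model.eval()
    logits = model(x[None], capture_features=True)
    feats = model.last_features
    logits[0, target_class].backward()
    grads = feats.grad[0]          # (C, h, w)
    acts = feats.data[0]
    channel_w = grads.mean(axis=(1, 2))
    raw = np.maximum((channel_w[:, None, None] * acts).sum(axis=0), 0.0)
    if raw.max() <= 0:
        warnings.warn("no positive class evidence; returning a uniform zero map")
        return SaliencyMap(np.zeros((size, size)), target_class)
    norm = (raw - raw.min()) / (raw.max() - raw.min())
    return SaliencyMap(
        np.clip(_upsample_bilinear(norm, size), 0.0, 1.0), target_class
    )


def _colorize(map2d: np.ndarray) -> np.ndarray:
    """Blue (low) -> red (high) rendering via the jet colormap."""
    import matplotlib

    cmap = matplotlib.colormaps["jet"]
    return (cmap(np.clip(map2d, 0, 1))[:, :, :3] * 255).astype(np.uint8)


def overlay(img: np.ndarray, sal: SaliencyMap, opacity: float = 0.5) -> np.ndarray:
    """Alpha-blend the colorized saliency over the image."""
    if not (0.0 <= opacity <= 1.0):
        raise ValueError("opacity must lie in [0, 1]")
    img = np.asarray(img)
    if img.shape[:2] != sal.weights.shape:
        raise ValueError("saliency map does not match the image grid")
    heat = _colorize(sal.weights)
    blend = (1 - opacity) * img.astype(np.float64) + opacity * heat
    return np.clip(np.round(blend), 0, 255).astype(np.uint8)


def side_by_side(img: np.ndarray, sal: SaliencyMap, path,
                 opacity: float = 0.5) -> Path:
    """Write an original|overlay panel PNG."""
    panel = np.concatenate([img, overlay(img, sal, opacity)], axis=1)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(panel).save(path)
    return path
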
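"""Seeded generator of three texture-distinct H&E-palette image classes.

The three archetypes stand in for a directory-per-class histopathology
dataset so the full pipeline is exercisable offline:

* class A ("cca_like")  — pale background with ring/duct ellipse structures;
* class B ("hcc_like")  — dense dark-purple nuclei-like blobs;
* class C ("norm_like") — regular low-frequency pink texture.

They claim no biological fidelity, only learnable class structure.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from PIL import Image

CLASS_NAMES = ("cca_like", "hcc_like", "norm_like")

# training-cohort class sizes the imbalance preset emulates (proportions only)
_IMBALANCE_COUNTS = (180, 3380, 1536)


@dataclass
class SyntheticConfig:
    n_per_class: Tuple[int, int, int] = (50, 50, 50)
    image_size: int = 224
    seed: int = 0
    noise_sd: float = 8.0
    imbalance_preset: bool = False
    imbalance_scale: float = 0.1

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if any(n < 0 for n in self.n_per_class):
            raise ValueError("class counts must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.imbalance_preset:
            self.n_per_class = tuple(
                int(round(n * self.imbalance_scale)) for n in _IMBALANCE_COUNTS
            )


@dataclass
class SyntheticDataset:
    images: np.ndarray  # (N, H, W, 3) uint8
    labels: np.ndarray  # (N,) int
    paths: List[str] = field(default_factory=list)
    class_names: Tuple[str, ...] = CLASS_NAMES


# ------------------------------------------------------------------ rendering
def _smooth_noise(rng, size, scale, lo, hi):
    small = rng.uniform(lo, hi, (max(size // scale, 1),) * 2)
    img = np.asarray(
        Image.fromarray((small * 255).astype(np.uint8)).resize((size, size), Image.BILINEAR),
        dtype=np.float64,
    ) / 255.0
    return lo + img * (hi - lo)


def _render_cca(rng: np.random.Generator, s: int) -> np.ndarray:
    """Pale eosin background with dark elliptical duct rings."""
    img = np.empty((s, s, 3))
    img[..., 0] = 235 + _smooth_noise(rng, s, 8, -10, 10)
    img[..., 1] = 215 + _smooth_noise(rng, s, 8, -10, 10)
    img[..., 2] = 225 + _smooth_noise(rng, s, 8, -10, 10)
    yy, xx = np.mgrid[0:s, 0:s]
    for _ in range(max(3, s // 28)):
        cy, cx = rng.uniform(0.15 * s, 0.85 * s, 2)
        a, b = rng.uniform(0.06 * s, 0.16 * s, 2)
        th = rng.uniform(0, np.pi)
        u = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
        v = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
        rad = np.sqrt((u / a) ** 2 + (v / b) ** 2)
        ring = np.abs(rad - 1.0) < 0.22
        lumen = rad < 0.78
        img[ring] = [120, 70, 140]
        img[lumen] = [245, 240, 245]
    return img


def _render_hcc(rng: np.random.Generator, s: int) -> np.ndarray:
    """Dense dark-purple blob field on a mid-pink background."""
    img = np.empty((s, s, 3))
    img[..., 0] = 190 + _smooth_noise(rng, s, 16, -15, 15)
    img[..., 1] = 120 + _smooth_noise(rng, s, 16, -15, 15)
    img[..., 2] = 170 + _smooth_noise(rng, s, 16, -15, 15)
    yy, xx = np.mgrid[0:s, 0:s]
    n_blobs = max(30, (s * s) // 140)
    cys = rng.uniform(0, s, n_blobs)
    cxs = rng.uniform(0, s, n_blobs)
    rads = rng.uniform(0.012 * s, 0.03 * s, n_blobs)
    for cy, cx, r in zip(cys, cxs, rads):
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 < r * r
        img[mask] = [95, 50, 125]
    return img


def _render_norm(rng: np.random.Generator, s: int) -> np.ndarray:
    """Regular low-frequency pink sinusoidal texture."""
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    period = s / rng.uniform(6, 9)
    phase = rng.uniform(0, 2 * np.pi, 2)
    wave = 0.5 * (np.sin(2 * np.pi * xx / period + phase[0])
                  + np.sin(2 * np.pi * yy / period + phase[1]))
    img = np.empty((s, s, 3))
    img[..., 0] = 240 + 10 * wave
    img[..., 1] = 170 + 35 * wave
    img[..., 2] = 190 + 25 * wave
    return img


_RENDERERS = (_render_cca, _render_hcc, _render_norm)


def render_image(class_index: int, size: int, noise_sd: float,
                 rng: np.random.Generator) -> np.ndarray:
    img = _RENDERERS[class_index](rng, size)
    if noise_sd > 0:
        img = img + rng.normal(0, noise_sd, img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


# ------------------------------------------------------------------- dataset
def generate_arrays(cfg: SyntheticConfig) -> SyntheticDataset:
    """In-memory dataset, deterministic given ``cfg.seed``."""
    images, labels = [], []
    for ci, n in enumerate(cfg.n_per_class):
        for i in range(n):
            rng = np.random.default_rng(
                np.random.SeedSequence((cfg.seed, ci, i))
            )
            images.append(render_image(ci, cfg.image_size, cfg.noise_sd, rng))
            labels.append(ci)
    images = (np.stack(images) if images
              else np.zeros((0, cfg.image_size, cfg.image_size, 3), np.uint8))
    return SyntheticDataset(images=images, labels=np.asarray(labels, dtype=int))


def generate_dataset(cfg: SyntheticConfig, out_dir) -> Path:
    """Write a directory-per-class PNG tree plus a manifest CSV; returns the
    manifest path."""
    out_dir = Path(out_dir)
    ds = generate_arrays(cfg)
    manifest = out_dir / "manifest.csv"
    out_dir.mkdir(parents=True, exist_ok=True)
    counters = [0, 0, 0]
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "class", "seed"])
        for img, lab in zip(ds.images, ds.labels):
            cname = CLASS_NAMES[lab]
            cdir = out_dir / cname
            cdir.mkdir(exist_ok=True)
            path = cdir / f"{cname}_{counters[lab]:05d}.png"
            Image.fromarray(img).save(path)
            writer.writerow([str(path.relative_to(out_dir)), cname, cfg.seed])
            counters[lab] += 1
    return manifest


def load_image_folder(root) -> SyntheticDataset:
    """Read a directory-per-class tree of PNG/JPEG images."""
    root = Path(root)
    classes = sorted(p.name for p in root.iterdir() if p.is_dir())
    if not classes:
        raise ValueError(f"no class subdirectories under {root}")
    images, labels, paths = [], [], []
    for ci, cname in enumerate(classes):
        for p in sorted((root / cname).iterdir()):
            if p.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            images.append(np.asarray(Image.open(p).convert("RGB")))
            labels.append(ci)
            paths.append(str(p))
    return SyntheticDataset(
        images=np.stack(images), labels=np.asarray(labels, dtype=int),
        paths=paths, class_names=tuple(classes),
    )


# --------------------------------------------------------- separability guard
def separability_check(ds: SyntheticDataset, seed: int = 0,
                       min_per_class: int = 50,
                       holdout_fraction: float = 0.3) -> float:
    """Held-out accuracy of a fixed small reference classifier.

    A frozen random-convolution feature bank (3 -> 12 channels of 5x5
    filters, ReLU, 4x4 average pooling) feeds a ridge-regularized linear
    classifier solved in closed form.  Independent of the package's
    trainable networks; guards that the generator's signal is learnable.
    """
    labels = np.asarray(ds.labels)
    classes = np.unique(labels)
    counts = [(labels == c).sum() for c in classes]
    if len(classes) < 2 or min(counts) < min_per_class:
        raise ValueError(f"need >= {min_per_class} images in each of >= 2 classes")
    rng = np.random.default_rng(seed)
    filt = np.random.default_rng(1234).normal(0, 0.2, (12, 3, 5, 5))

    def features(imgs):
        x = imgs.astype(np.float64) / 255.0
        # downsample to 32x32 by block mean for speed and scale invariance
        s = x.shape[1]
        k = max(s // 32, 1)
        x = x[:, : 32 * k, : 32 * k].reshape(x.shape[0], 32, k, 32, k, 3).mean((2, 4))
        x = x.transpose(0, 3, 1, 2)
        from numpy.lib.stride_tricks import sliding_window_view

        win = sliding_window_view(x, (5, 5), axis=(2, 3))[:, :, ::2, ::2]
        conv = np.maximum(np.tensordot(win, filt, axes=([1, 4, 5], [1, 2, 3])), 0)
        conv = conv.transpose(0, 3, 1, 2)
        n, c, h, w = conv.shape
        hp, wp = h // 4, w // 4
        pooled = conv[:, :, : 4 * hp, : 4 * wp].reshape(n, c, 4, hp, 4, wp).mean((3, 5))
        return pooled.reshape(n, -1)

    idx = rng.permutation(len(labels))
    n_hold = max(int(round(holdout_fraction * len(labels))), len(classes))
    test_idx, train_idx = idx[:n_hold], idx[n_hold:]
    if len(np.unique(labels[train_idx])) < len(classes):
        raise ValueError("degenerate split: a class is missing from training")
    ftr = features(ds.images[train_idx])
    fte = features(ds.images[test_idx])
    mu, sd = ftr.mean(0), ftr.std(0) + 1e-8
    ftr, fte = (ftr - mu) / sd, (fte - mu) / sd
    onehot = np.eye(len(classes))[np.searchsorted(classes, labels[train_idx])]
    a = ftr.T @ ftr + 1e-2 * len(train_idx) * np.eye(ftr.shape[1])
    w = np.linalg.solve(a, ftr.T @ onehot)
    pred = classes[np.argmax(fte @ w, axis=1)]
    return float((pred == labels[test_idx]).mean())
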
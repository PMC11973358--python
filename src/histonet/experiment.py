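"""Training protocol: stratified k-fold cross-validation, early-stopped
training, random+grid hyperparameter search, and leakage-guarded external
testing."""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .arch import ArchConfig, HistoNet, build_network
from .augment import AugmentConfig, augment_pipeline, sample_rng
from .metrics import MetricsReport, confusion, evaluate
from .nn import Adam, Tensor, cross_entropy
from .preprocess import PreprocessConfig, preprocess_image

__all__ = [
    "TrainConfig",
    "SearchSpace",
    "FoldSplit",
    "stratified_kfold",
    "train_model",
    "cross_validate",
    "hyperparameter_search",
    "external_test",
    "save_checkpoint",
    "load_checkpoint",
]

_NORM_MEAN, _NORM_STD = 0.5, 0.25


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 16
    weight_decay: float = 0.0
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    target_val_accuracy: Optional[float] = None  # optional early exit once met

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if not (0 < self.patience < self.max_epochs):
            raise ValueError("patience must satisfy 0 < patience < max_epochs")


@dataclass
class SearchSpace:
    grids: Dict[str, List] = field(default_factory=dict)
    random_ranges: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    log_scale: Tuple[str, ...] = ("learning_rate", "weight_decay")
    budget: int = 4

    def __post_init__(self):
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        if not self.grids and not self.random_ranges:
            raise ValueError("search space is empty")


@dataclass
class FoldSplit:
    k: int
    assignments: np.ndarray  # per-sample fold index in [0, k)

    def fold_indices(self, fold: int) -> Tuple[np.ndarray, np.ndarray]:
        val = np.where(self.assignments == fold)[0]
        train = np.where(self.assignments != fold)[0]
        return train, val


# ------------------------------------------------------------------- folding
def stratified_kfold(labels: Sequence[int], k: int = 5, seed: int = 0) -> FoldSplit:
    """Deterministic stratified partition; per-class fold sizes differ by <=1."""
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assignments = np.full(len(labels), -1, dtype=int)
    for c in np.unique(labels):
        idx = np.where(labels == c)[0]
        if len(idx) < k:
            raise ValueError(
                f"class {c} has only {len(idx)} samples but k={k} folds were requested"
            )
        idx = rng.permutation(idx)
        assignments[idx] = np.arange(len(idx)) % k
    return FoldSplit(k=k, assignments=assignments)


# ------------------------------------------------------------------- training
def _to_batch(images: np.ndarray) -> np.ndarray:
    x = images.astype(np.float32) / 255.0
    x = (x - _NORM_MEAN) / _NORM_STD
    return x.transpose(0, 3, 1, 2)


def _predict_scores(model: HistoNet, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
    model.eval()
    outs = []
    for i in range(0, len(images), batch_size):
        logits = model(_to_batch(images[i:i + batch_size])).data
        shift = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shift)
        outs.append(e / e.sum(axis=1, keepdims=True))
    return np.concatenate(outs, axis=0)


def train_model(
    cfg: ArchConfig,
    tcfg: TrainConfig,
    train_set: Tuple[np.ndarray, np.ndarray],
    val_set: Tuple[np.ndarray, np.ndarray],
    augment: Optional[AugmentConfig] = None,
    verbose: bool = False,
) -> Tuple[HistoNet, List[dict]]:
    """Minimize categorical cross-entropy; record per-epoch train/val loss and
    the full validation metric suite; early-stop on validation loss; return
    the best-validation-loss weights.
    """
    x_train, y_train = np.asarray(train_set[0]), np.asarray(train_set[1], dtype=int)
    x_val, y_val = np.asarray(val_set[0]), np.asarray(val_set[1], dtype=int)
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    if not set(np.unique(y_val)) <= set(np.unique(y_train)):
        raise ValueError("validation contains classes absent from training")

    model = build_network(cfg, seed=tcfg.seed)
    opt = Adam(model.parameters(), lr=tcfg.learning_rate,
               weight_decay=tcfg.weight_decay)
    rng = np.random.default_rng(tcfg.seed)
    history: List[dict] = []
    best_val, best_state, since_best = np.inf, None, 0

    for epoch in range(tcfg.max_epochs):
        model.train()
        order = rng.permutation(len(x_train))
        losses = []
        for start in range(0, len(order), tcfg.batch_size):
            idx = order[start:start + tcfg.batch_size]
            if augment is not None:
                imgs = np.stack([
                    augment_pipeline(x_train[i], augment,
                                     sample_rng(augment.seed, int(i), epoch))
                    for i in idx
                ])
            else:
                imgs = x_train[idx]
            loss = cross_entropy(model(_to_batch(imgs)), y_train[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={float(loss.data)}"
                )
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))

        scores = _predict_scores(model, x_val)
        pred = scores.argmax(axis=1)
        val_loss = float(-np.log(
            np.clip(scores[np.arange(len(y_val)), y_val], 1e-12, None)
        ).mean())
        report = evaluate(y_val, pred, scores=None, k=cfg.num_classes)
        cm = confusion(y_val, pred, cfg.num_classes)
        row = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "val_loss": val_loss,
            "val_accuracy": report.accuracy,
            "val_f1_macro": report.f1_macro,
            "val_mcc": report.mcc,
            "confusion": cm.counts.tolist(),
        }
        history.append(row)
        if verbose:
            print(f"epoch {epoch}: train {row['train_loss']:.4f} "
                  f"val {val_loss:.4f} acc {report.accuracy:.3f}")
        if val_loss < best_val - 1e-6:
            best_val, since_best = val_loss, 0
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
        else:
            since_best += 1
            if since_best >= tcfg.patience:
                break
        if (tcfg.target_val_accuracy is not None
                and report.accuracy >= tcfg.target_val_accuracy):
            if val_loss <= best_val:
                best_state = {k: v.copy() for k, v in model.state_dict().items()}
            break

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


# ------------------------------------------------------------ cross-validation
def cross_validate(
    cfg: ArchConfig,
    tcfg: TrainConfig,
    dataset,
    k: int = 5,
    seed: int = 0,
    augment: Optional[AugmentConfig] = None,
) -> dict:
    """k models, each trained on k-1 folds; augmentation on training folds
    only.  Returns per-fold best-epoch reports, per-epoch trajectories, and
    mean/std summaries."""
    images, labels = dataset.images, dataset.labels
    split = stratified_kfold(labels, k=k, seed=seed)
    fold_reports: List[MetricsReport] = []
    fold_histories: List[List[dict]] = []
    for fold in range(k):
        tr, va = split.fold_indices(fold)
        model, history = train_model(
            cfg, tcfg, (images[tr], labels[tr]), (images[va], labels[va]),
            augment=augment,
        )
        scores = _predict_scores(model, images[va])
        fold_reports.append(
            evaluate(labels[va], scores.argmax(axis=1), scores=scores,
                     k=cfg.num_classes)
        )
        fold_histories.append(history)
    accs = [r.accuracy for r in fold_reports]
    epoch_accs = [row["val_accuracy"] for h in fold_histories for row in h]
    return {
        "fold_reports": fold_reports,
        "fold_histories": fold_histories,
        "split": split,
        "mean_accuracy": float(np.mean(accs)),
        "std_accuracy": float(np.std(accs)),
        "all_epoch_accuracies": epoch_accs,
    }


# --------------------------------------------------------------------- search
def hyperparameter_search(
    space: SearchSpace,
    objective: Callable[[TrainConfig], float],
    base: Optional[TrainConfig] = None,
    seed: int = 0,
) -> Tuple[TrainConfig, List[dict]]:
    """Grid points first, then random draws, up to ``space.budget`` trials;
    ranks by the objective (mean validation accuracy by convention)."""
    base = base or TrainConfig()
    rng = np.random.default_rng(seed)
    candidates: List[Dict] = []
    if space.grids:
        keys = sorted(space.grids)
        for combo in itertools.product(*(space.grids[k] for k in keys)):
            candidates.append(dict(zip(keys, combo)))
    while len(candidates) < space.budget:
        draw = {}
        for key in sorted(space.random_ranges):
            lo, hi = space.random_ranges[key]
            if key in space.log_scale:
                draw[key] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                draw[key] = float(rng.uniform(lo, hi))
            if key == "batch_size":
                draw[key] = int(round(draw[key]))
        if not draw:
            break
        candidates.append(draw)
    candidates = candidates[: space.budget] if len(candidates) > space.budget else candidates
    trials = []
    best_cfg, best_val = None, -np.inf
    for i, overrides in enumerate(candidates):
        params = {**base.__dict__, **overrides}
        tcfg = TrainConfig(**params)
        value = float(objective(tcfg))
        trials.append({"trial": i, "params": overrides, "objective": value})
        if value > best_val:
            best_val, best_cfg = value, tcfg
    return best_cfg, trials


# ------------------------------------------------------------- external test
def external_test(
    model: HistoNet,
    cfg: ArchConfig,
    test_set,
    train_paths: Optional[Sequence[str]] = None,
    preprocess: Optional[PreprocessConfig] = None,
) -> MetricsReport:
    """No augmentation; preprocessing identical to training; refuses any
    file-path overlap with the training data (leakage guard)."""
    test_paths = getattr(test_set, "paths", None)
    if train_paths and test_paths:
        overlap = set(map(str, train_paths)) & set(map(str, test_paths))
        if overlap:
            raise ValueError(
                f"data leakage: {len(overlap)} test paths appear in training "
                f"data (e.g. {sorted(overlap)[0]})"
            )
    images = test_set.images
    if preprocess is not None:
        images = np.stack([preprocess_image(im, preprocess) for im in images])
    scores = _predict_scores(model, images)
    return evaluate(test_set.labels, scores.argmax(axis=1), scores=scores,
                    k=cfg.num_classes,
                    class_names=list(getattr(test_set, "class_names", []) or []) or None)


# ---------------------------------------------------------------- checkpoints
def save_checkpoint(model: HistoNet, path) -> None:
    """NumPy ``.npz`` archive of all parameters/buffers plus the config JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    cfg_json = json.dumps(model.cfg.__dict__, default=list)
    np.savez(path, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> HistoNet:
    with np.load(path) as data:
        cfg_raw = bytes(data["__config__"]).decode()
        cfg_dict = json.loads(cfg_raw)
        cfg_dict["stage_depths"] = tuple(cfg_dict["stage_depths"])
        cfg = ArchConfig(**cfg_dict)
        model = build_network(cfg)
        state = {k: data[k] for k in data.files if k != "__config__"}
    model.load_state_dict(state)
    return model
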
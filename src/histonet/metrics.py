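"""Multi-class evaluation: confusion matrix, accuracy, micro/macro
precision/recall, F1, Matthews correlation, and one-vs-rest ROC / PR curves
with micro and macro averaged AUCs.

Zero-denominator rates are defined as 0 (with a warning), matching common
reference-library behavior; this matters for macro averages on tiny folds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "ScoreSet",
    "MetricsReport",
    "confusion",
    "accuracy",
    "precision_recall_micro",
    "precision_recall_macro",
    "f1",
    "mcc",
    "binary_mcc",
    "roc_curve",
    "pr_curve",
    "roc_pr_curves",
    "evaluate",
]


# ----------------------------------------------------------------- structures
@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (K, K) ints; rows = true class, cols = predicted
    class_names: Optional[List[str]] = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def per_class(self) -> Dict[str, np.ndarray]:
        tp = np.diag(self.counts).astype(float)
        fp = self.counts.sum(axis=0) - tp
        fn = self.counts.sum(axis=1) - tp
        tn = self.total - tp - fp - fn
        return {"tp": tp, "fp": fp, "fn": fn, "tn": tn}

    def to_csv(self) -> str:
        names = self.class_names or [f"class{i}" for i in range(self.k)]
        lines = ["true\\pred," + ",".join(names)]
        for i, row in enumerate(self.counts):
            lines.append(names[i] + "," + ",".join(str(v) for v in row))
        return "\n".join(lines) + "\n"


@dataclass
class ScoreSet:
    true_labels: np.ndarray
    scores: np.ndarray  # (N, K) post-softmax class scores

    def __post_init__(self):
        self.true_labels = np.asarray(self.true_labels, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or len(self.true_labels) != len(self.scores):
            raise ValueError("scores must be (N, K) aligned with true_labels")
        sums = self.scores.sum(axis=1)
        if len(sums) and not np.allclose(sums, 1.0, atol=1e-5):
            raise ValueError("score vectors must sum to 1")


@dataclass
class MetricsReport:
    accuracy: float
    precision_micro: float
    recall_micro: float
    precision_macro: float
    recall_macro: float
    f1_micro: float
    f1_macro: float
    mcc: float
    mcc_ovr_mean: float = float("nan")
    roc_auc_per_class: Dict[int, float] = field(default_factory=dict)
    pr_auc_per_class: Dict[int, float] = field(default_factory=dict)
    roc_auc_micro: float = float("nan")
    roc_auc_macro: float = float("nan")
    pr_auc_micro: float = float("nan")
    pr_auc_macro: float = float("nan")
    per_class_precision: List[float] = field(default_factory=list)
    per_class_recall: List[float] = field(default_factory=list)
    per_class_f1: List[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            k: (dict(v) if isinstance(v, dict) else v)
            for k, v in self.__dict__.items()
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, default=float)


# -------------------------------------------------------------------- tallies
def confusion(true: Sequence[int], pred: Sequence[int], k: int,
              class_names: Optional[List[str]] = None) -> ConfusionMatrix:
    true = np.asarray(true, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if true.shape != pred.shape:
        raise ValueError("label sequences must have equal length")
    if len(true) and (true.min() < 0 or true.max() >= k or pred.min() < 0 or pred.max() >= k):
        raise ValueError(f"labels must lie in [0, {k})")
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (true, pred), 1)
    return ConfusionMatrix(counts=counts, class_names=class_names)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {what}; defining the rate as 0")
        return 0.0
    return num / den


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("accuracy is undefined for an empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def precision_recall_micro(cm: ConfusionMatrix) -> Tuple[float, float]:
    s = cm.per_class()
    tp, fp, fn = s["tp"].sum(), s["fp"].sum(), s["fn"].sum()
    return (_safe_div(tp, tp + fp, "micro precision"),
            _safe_div(tp, tp + fn, "micro recall"))


def precision_recall_macro(cm: ConfusionMatrix) -> Tuple[float, float]:
    s = cm.per_class()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        precs = [_safe_div(tp, tp + fp, "") for tp, fp in zip(s["tp"], s["fp"])]
        recs = [_safe_div(tp, tp + fn, "") for tp, fn in zip(s["tp"], s["fn"])]
    return float(np.mean(precs)), float(np.mean(recs))


def f1(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def binary_mcc(tp: float, tn: float, fp: float, fn: float) -> float:
    den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if den == 0:
        return 0.0
    return float((tp * tn - fp * fn) / den)


def mcc(cm: ConfusionMatrix) -> float:
    """Multiclass Matthews correlation (covariance form over the matrix);
    reduces to the familiar binary formula at K=2."""
    c = cm.counts.astype(float)
    t = c.sum()
    if t == 0:
        raise ValueError("MCC is undefined for an empty confusion matrix")
    correct = np.trace(c)
    truth = c.sum(axis=1)   # per-class actual counts
    pred = c.sum(axis=0)    # per-class predicted counts
    cov_xy = correct * t - truth @ pred
    cov_xx = t * t - pred @ pred
    cov_yy = t * t - truth @ truth
    den = np.sqrt(cov_xx) * np.sqrt(cov_yy)
    if den == 0:
        return 0.0
    return float(cov_xy / den)


def mcc_one_vs_rest(cm: ConfusionMatrix) -> float:
    """Mean of per-class binary MCCs (the alternative reading of a single
    reported multiclass MCC value)."""
    s = cm.per_class()
    vals = [binary_mcc(tp, tn, fp, fn)
            for tp, tn, fp, fn in zip(s["tp"], s["tn"], s["fp"], s["fn"])]
    return float(np.mean(vals))


# --------------------------------------------------------------------- curves
def roc_curve(y_true: np.ndarray, score: np.ndarray):
    """One-vs-rest ROC: (fpr, tpr, thresholds), trapezoid AUC."""
    y_true = np.asarray(y_true, dtype=bool)
    score = np.asarray(score, dtype=float)
    pos, neg = y_true.sum(), (~y_true).sum()
    if pos == 0 or neg == 0:
        raise ValueError("ROC requires at least one positive and one negative")
    order = np.argsort(-score, kind="stable")
    score, y_true = score[order], y_true[order]
    distinct = np.where(np.diff(score))[0]
    idx = np.r_[distinct, len(score) - 1]
    tps = np.cumsum(y_true)[idx].astype(float)
    fps = (idx + 1) - tps
    tpr = np.r_[0.0, tps / pos]
    fpr = np.r_[0.0, fps / neg]
    thresholds = np.r_[np.inf, score[idx]]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, thresholds, auc


def pr_curve(y_true: np.ndarray, score: np.ndarray):
    """One-vs-rest precision-recall; AUC by the step-wise sum
    (no linear interpolation between operating points)."""
    y_true = np.asarray(y_true, dtype=bool)
    score = np.asarray(score, dtype=float)
    pos = y_true.sum()
    if pos == 0:
        raise ValueError("PR curve requires at least one positive")
    order = np.argsort(-score, kind="stable")
    score, y_true = score[order], y_true[order]
    distinct = np.where(np.diff(score))[0]
    idx = np.r_[distinct, len(score) - 1]
    tps = np.cumsum(y_true)[idx].astype(float)
    fps = (idx + 1) - tps
    precision = tps / (tps + fps)
    recall = tps / pos
    auc = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    precision = np.r_[1.0, precision]
    recall = np.r_[0.0, recall]
    thresholds = np.r_[np.inf, score[idx]]
    return precision, recall, thresholds, auc


def roc_pr_curves(scores: ScoreSet) -> dict:
    """Per-class one-vs-rest curves plus micro (pooled decisions) and macro
    (mean of per-class AUCs) averages.  Classes without positives are skipped
    with a warning and excluded from the macro mean."""
    y = scores.true_labels
    s = scores.scores
    k = s.shape[1]
    out = {"roc": {}, "pr": {}, "roc_auc": {}, "pr_auc": {}}
    kept = []
    for c in range(k):
        mask = y == c
        if mask.sum() == 0 or mask.sum() == len(y):
            warnings.warn(f"class {c} lacks positives or negatives; curve skipped")
            continue
        fpr, tpr, th, auc_r = roc_curve(mask, s[:, c])
        prec, rec, thp, auc_p = pr_curve(mask, s[:, c])
        out["roc"][c] = (fpr, tpr, th)
        out["pr"][c] = (prec, rec, thp)
        out["roc_auc"][c] = auc_r
        out["pr_auc"][c] = auc_p
        kept.append(c)
    onehot = np.zeros_like(s, dtype=bool)
    onehot[np.arange(len(y)), y] = True
    _, _, _, roc_micro = roc_curve(onehot.ravel(), s.ravel())
    _, _, _, pr_micro = pr_curve(onehot.ravel(), s.ravel())
    out["roc_auc_micro"] = roc_micro
    out["pr_auc_micro"] = pr_micro
    out["roc_auc_macro"] = float(np.mean([out["roc_auc"][c] for c in kept])) if kept else float("nan")
    out["pr_auc_macro"] = float(np.mean([out["pr_auc"][c] for c in kept])) if kept else float("nan")
    return out


# ------------------------------------------------------------------ reporting
def evaluate(true: Sequence[int], pred: Sequence[int],
             scores: Optional[np.ndarray] = None, k: Optional[int] = None,
             class_names: Optional[List[str]] = None) -> MetricsReport:
    """Full report from labels, predictions and (optionally) class scores."""
    true = np.asarray(true, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if k is None:
        k = int(max(true.max(), pred.max())) + 1
    cm = confusion(true, pred, k, class_names)
    p_mi, r_mi = precision_recall_micro(cm)
    p_ma, r_ma = precision_recall_macro(cm)
    s = cm.per_class()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pcp = [_safe_div(tp, tp + fp, "") for tp, fp in zip(s["tp"], s["fp"])]
        pcr = [_safe_div(tp, tp + fn, "") for tp, fn in zip(s["tp"], s["fn"])]
    pcf = [f1(p, r) for p, r in zip(pcp, pcr)]
    report = MetricsReport(
        accuracy=accuracy(cm),
        precision_micro=p_mi, recall_micro=r_mi,
        precision_macro=p_ma, recall_macro=r_ma,
        f1_micro=f1(p_mi, r_mi), f1_macro=float(np.mean(pcf)),
        mcc=mcc(cm), mcc_ovr_mean=mcc_one_vs_rest(cm),
        per_class_precision=pcp, per_class_recall=pcr, per_class_f1=pcf,
    )
    if scores is not None:
        curves = roc_pr_curves(ScoreSet(true_labels=true, scores=scores))
        report.roc_auc_per_class = curves["roc_auc"]
        report.pr_auc_per_class = curves["pr_auc"]
        report.roc_auc_micro = curves["roc_auc_micro"]
        report.roc_auc_macro = curves["roc_auc_macro"]
        report.pr_auc_micro = curves["pr_auc_micro"]
        report.pr_auc_macro = curves["pr_auc_macro"]
    return report
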
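"""Evaluation metrics for segmentation masks and multi-class predictions.

Segmentation is scored at pixel level (white/true = abnormal skin):
sensitivity TP/(TP+FN), specificity TN/(TN+FP), Dice 2TP/((TP+FP)+(TP+FN)),
and the symmetric Hausdorff distance H(X,Y) = max(h(X,Y), h(Y,X)) with
h(X,Y) = max_x min_y ||x-y|| over foreground coordinate sets.

Classification is scored one-vs-rest per class — sensitivity, specificity,
F1 = 2TP/(2TP+FP+FN) (algebraically the Dice coefficient), trapezoidal ROC
AUC — then weighted by per-class sample counts; Top-n accuracy counts a
sample correct when its true class is among the n most probable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def pixel_confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Per-pixel confusion counts; true/white is the positive class."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass
class Rates:
    sensitivity: float
    specificity: float
    dice: float
    f1: float
    vacuous: tuple[str, ...] = ()  # metrics whose denominator was zero


def rates(counts: ConfusionCounts) -> Rates:
    """Exact formula evaluation; a zero denominator yields 1.0 and the
    metric's name in ``vacuous`` (no units to get wrong means no error)."""
    flags = []

    def _ratio(num, den, name):
        if den == 0:
            flags.append(name)
            return 1.0
        return num / den

    sens = _ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    spec = _ratio(counts.tn, counts.tn + counts.fp, "specificity")
    dice = _ratio(2 * counts.tp, (counts.tp + counts.fp) + (counts.tp + counts.fn), "dice")
    f1 = _ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn, "f1")
    return Rates(sensitivity=sens, specificity=spec, dice=dice, f1=f1,
                 vacuous=tuple(flags))


def hausdorff(pred: np.ndarray, truth: np.ndarray) -> float:
    """Symmetric Hausdorff distance (pixels) between foreground point sets."""
    X = np.argwhere(np.asarray(pred).astype(bool))
    Y = np.argwhere(np.asarray(truth).astype(bool))
    if len(X) == 0 or len(Y) == 0:
        raise ValueError("Hausdorff distance is undefined for an empty mask")
    d_xy = cKDTree(Y).query(X, k=1)[0].max()
    d_yx = cKDTree(X).query(Y, k=1)[0].max()
    return float(max(d_xy, d_yx))


def weighted_class_metrics(per_class: dict, counts: dict) -> float:
    """Count-weighted average of a per-class metric; zero-count classes are
    excluded."""
    if set(per_class) != set(counts):
        raise ValueError("per_class and counts must share the same keys")
    keys = [k for k in per_class if counts[k] > 0]
    total = sum(counts[k] for k in keys)
    if total == 0:
        raise ValueError("all class counts are zero")
    return float(sum(per_class[k] * counts[k] for k in keys) / total)


def topn_accuracy(distributions, labels, n_values=(1, 2, 3)) -> dict:
    """Top-n accuracy for each n; ties are broken toward the lowest class
    index (stable sort on descending probability)."""
    P = np.asarray(distributions, dtype=float)
    labels = np.asarray(labels)
    n_classes = P.shape[1]
    out = {}
    order = np.argsort(-P, axis=1, kind="stable")
    for n in n_values:
        if not 1 <= n <= n_classes:
            raise ValueError(f"n must be in [1, {n_classes}], got {n}")
        out[int(n)] = float(np.mean([
            labels[i] in order[i, :n] for i in range(len(labels))
        ]))
    return out


def roc_auc_ovr(scores: np.ndarray, positives: np.ndarray) -> float:
    """Trapezoidal one-vs-rest ROC AUC from ranked scores."""
    scores = np.asarray(scores, dtype=float)
    positives = np.asarray(positives).astype(bool)
    n_pos = positives.sum()
    n_neg = len(positives) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined without both classes")
    order = np.argsort(-scores, kind="stable")
    y = positives[order]
    s = scores[order]
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    # keep the last point of each tied-score run
    distinct = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return float(np.trapezoid(tpr, fpr))


@dataclass
class MetricReport:
    per_class: dict = field(default_factory=dict)
    weights: dict = field(default_factory=dict)
    weighted: dict = field(default_factory=dict)
    topn: dict = field(default_factory=dict)
    accuracy: float | None = None
    warnings: list = field(default_factory=list)

    def to_dict(self):
        return {
            "per_class": {int(k): dict(v) for k, v in self.per_class.items()},
            "weights": {int(k): int(v) for k, v in self.weights.items()},
            "weighted": dict(self.weighted),
            "topn": {int(k): float(v) for k, v in self.topn.items()},
            "accuracy": self.accuracy,
            "warnings": list(self.warnings),
        }


def classification_report(distributions, labels, n_classes=None,
                          n_values=None) -> MetricReport:
    """Per-class one-vs-rest metrics + count-weighted averages + Top-n."""
    P = np.asarray(distributions, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if P.ndim != 2 or len(P) != len(labels):
        raise ValueError("distributions and labels must align")
    if n_classes is None:
        n_classes = P.shape[1]
    preds = np.argmin(-P, axis=1)  # argmax with lowest-index tie-break
    report = MetricReport()
    present = set(np.unique(labels).tolist())
    for c in range(n_classes):
        n_c = int(np.sum(labels == c))
        if n_c == 0:
            report.warnings.append(f"class {c} absent from labels; excluded")
            continue
        counts = pixel_confusion(preds == c, labels == c)
        r = rates(counts)
        entry = {"sensitivity": r.sensitivity, "specificity": r.specificity,
                 "f1": r.f1}
        try:
            entry["auc"] = roc_auc_ovr(P[:, c], labels == c)
        except ValueError:
            entry["auc"] = 1.0
            report.warnings.append(f"class {c}: AUC vacuous (single class)")
        report.per_class[c] = entry
        report.weights[c] = n_c
    if not report.per_class:
        raise ValueError("no class present in labels")
    for m in ("sensitivity", "specificity", "f1", "auc"):
        report.weighted[m] = weighted_class_metrics(
            {c: report.per_class[c][m] for c in report.per_class}, report.weights)
    if n_values is None:
        n_values = tuple(range(1, min(n_classes, 5) + 1))
    report.topn = topn_accuracy(P, labels, n_values)
    report.accuracy = float(np.mean(preds == labels))
    return report
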
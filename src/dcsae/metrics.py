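"""Classification metrics, ROC/AUC, and the cross-validation harness.

Per-class metrics are one-vs-rest (sensitivity, specificity, precision,
F-score, MCC) summarized by an unweighted macro mean; accuracy is the overall
fraction correct.  Ratios with zero denominators are reported as 0 and
flagged rather than raising, so batch evaluations stay total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "binary_metrics",
    "multiclass_metrics",
    "roc_curve",
    "kfold_evaluate",
]


@dataclass
class ConfusionMatrix:
    """k x k count matrix, rows = actual class, columns = predicted class."""

    counts: np.ndarray
    class_labels: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.class_labels = np.asarray(self.class_labels)
        k = len(self.class_labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be k x k for k class labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if not np.array_equal(self.class_labels, other.class_labels):
            raise ValueError("cannot add confusion matrices over different classes")
        return ConfusionMatrix(self.counts + other.counts, self.class_labels)


@dataclass
class MetricsReport:
    """Per-class and macro-averaged metric summary."""

    class_labels: np.ndarray
    per_class: dict[str, np.ndarray]
    averaged: dict[str, float]
    accuracy: float
    auc: float | None = None
    undefined_flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "class_labels": [int(c) for c in self.class_labels],
            "per_class": {k: [float(x) for x in v] for k, v in self.per_class.items()},
            "averaged": {k: float(v) for k, v in self.averaged.items()},
            "accuracy": float(self.accuracy),
            "auc": None if self.auc is None else float(self.auc),
            "undefined_flags": list(self.undefined_flags),
        }


def confusion(
    actual: np.ndarray, predicted: np.ndarray, class_labels: Sequence | None = None
) -> ConfusionMatrix:
    """Count matrix counts[a][p] = #{i : actual_i = a, predicted_i = p}."""
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if actual.shape != predicted.shape or actual.ndim != 1:
        raise ValueError("actual and predicted must be equal-length vectors")
    if actual.shape[0] == 0:
        raise ValueError("empty label vectors")
    if class_labels is None:
        class_labels = np.unique(np.concatenate([actual, predicted]))
    class_labels = np.asarray(class_labels)
    seen = set(np.unique(np.concatenate([actual, predicted])))
    if not seen <= set(class_labels.tolist()):
        raise ValueError(f"labels {sorted(seen - set(class_labels.tolist()))} outside class_labels")
    counts = _sk_confusion(actual, predicted, labels=class_labels)
    return ConfusionMatrix(counts, class_labels)


def _safe_div(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def binary_metrics(tp: int, tn: int, fp: int, fn: int) -> dict:
    """Standard binary metrics from the four confusion counts.

    Zero-denominator ratios return 0 and are listed under ``undefined``.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("at least one count must be positive")
    flags: list[str] = []
    sens = _safe_div(tp, tp + fn, "sensitivity", flags)
    spec = _safe_div(tn, tn + fp, "specificity", flags)
    prec = _safe_div(tp, tp + fp, "precision", flags)
    acc = (tp + tn) / total
    f_score = _safe_div(2 * prec * sens, prec + sens, "f_score", flags)
    mcc_den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _safe_div(float(tp) * tn - float(fp) * fn, mcc_den, "mcc", flags)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "accuracy": acc,
        "f_score": f_score,
        "mcc": mcc,
        "undefined": flags,
    }


_METRIC_NAMES = ("sensitivity", "specificity", "precision", "f_score", "mcc")


def multiclass_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest per-class metrics with unweighted macro averages."""
    k = len(cm.class_labels)
    if k < 2:
        raise ValueError("need at least 2 classes")
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    per_class: dict[str, list[float]] = {m: [] for m in _METRIC_NAMES}
    flags: list[str] = []
    for i in range(k):
        tp = int(cm.counts[i, i])
        fn = int(cm.counts[i].sum() - tp)
        fp = int(cm.counts[:, i].sum() - tp)
        tn = total - tp - fn - fp
        entry = binary_metrics(tp, tn, fp, fn)
        for m in _METRIC_NAMES:
            per_class[m].append(entry[m])
        flags.extend(f"class {cm.class_labels[i]}: {f}" for f in entry["undefined"])
    averaged = {m: float(np.mean(per_class[m])) for m in _METRIC_NAMES}
    accuracy = float(np.trace(cm.counts)) / total
    return MetricsReport(
        class_labels=cm.class_labels,
        per_class={m: np.array(v) for m, v in per_class.items()},
        averaged=averaged,
        accuracy=accuracy,
        undefined_flags=flags,
    )


def roc_curve(
    scores: np.ndarray, actual: np.ndarray, class_labels: Sequence | None = None
) -> tuple[dict, float]:
    """One-vs-rest ROC per class by threshold sweep; macro trapezoid AUC.

    ``scores`` is an (n, k) matrix of per-class scores (higher = more
    confident).  Returns ({class: (fpr, tpr, thresholds, auc)}, macro_auc).
    """
    scores = np.asarray(scores, dtype=float)
    actual = np.asarray(actual)
    if scores.ndim != 2 or scores.shape[0] != actual.shape[0]:
        raise ValueError("scores rows must match the label count")
    if class_labels is None:
        class_labels = np.unique(actual)
    class_labels = np.asarray(class_labels)
    if len(class_labels) < 2:
        raise ValueError("ROC needs at least 2 classes")
    if scores.shape[1] != len(class_labels):
        raise ValueError("scores must have one column per class")
    curves: dict = {}
    aucs = []
    for i, c in enumerate(class_labels):
        y = (actual == c).astype(int)
        if y.min() == y.max():
            raise ValueError(f"class {c} is absent or covers all samples")
        fpr, tpr, thr = _sk_roc_curve(y, scores[:, i])
        a = float(_trapezoid_auc(fpr, tpr))
        curves[c] = (fpr, tpr, thr, a)
        aucs.append(a)
    return curves, float(np.mean(aucs))


def kfold_evaluate(
    values: np.ndarray,
    labels: np.ndarray,
    fit_predict: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray],
    k: int = 10,
    seed: int = 0,
) -> tuple[list[MetricsReport], MetricsReport, ConfusionMatrix]:
    """Stratified k-fold evaluation of a train/predict pipeline.

    ``fit_predict(train_X, train_y, test_X)`` must fit every data-dependent
    step (normalization, feature selection, the classifier) on the training
    fold only and return predictions for the test fold.  Returns per-fold
    reports, the pooled report from the summed confusion matrix, and the
    pooled confusion matrix itself.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small} has only {counts.min()} members, fewer than k={k}; "
            "reduce k or provide more samples per class"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_reports: list[MetricsReport] = []
    pooled_cm: ConfusionMatrix | None = None
    for train_idx, test_idx in skf.split(values, labels):
        pred = fit_predict(values[train_idx], labels[train_idx], values[test_idx])
        cm = confusion(labels[test_idx], np.asarray(pred), classes)
        fold_reports.append(multiclass_metrics(cm))
        pooled_cm = cm if pooled_cm is None else pooled_cm + cm
    return fold_reports, multiclass_metrics(pooled_cm), pooled_cm
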
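"""Per-class confusion metrics, balanced accuracy (BACC) and ROC AUC.

BACC is the unweighted mean of per-class sensitivities (recalls), the key
metric for imbalanced multiclass screening tasks: a classifier that always
predicts the majority class scores near 1/C, not near the raw accuracy.

All metrics are one-vs-rest on a fixed sample set.  Ratios with a zero
denominator (e.g. a class absent from a small fold) are reported as NaN
("missing") and excluded from macro averages with a warning, rather than
silently coerced to 0.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "per_class_metrics",
    "bacc",
    "roc_auc",
    "average_auc",
    "evaluate_predictions",
]


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts per class (arrays of length C)."""

    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    def __post_init__(self):
        arrs = (self.tp, self.fp, self.tn, self.fn)
        if len({a.shape for a in arrs}) != 1:
            raise ValueError("tp/fp/tn/fn must share length")
        if any(np.any(a < 0) for a in arrs):
            raise ValueError("confusion counts must be nonnegative")
        totals = self.tp + self.fp + self.tn + self.fn
        if len(set(totals.tolist())) > 1:
            raise ValueError("per-class totals must agree (one-vs-rest on one sample set)")

    @property
    def num_classes(self) -> int:
        return len(self.tp)


def confusion_counts(y_true, y_pred, num_classes: int | None = None) -> ConfusionCounts:
    """One-vs-rest counts from integer label vectors."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if num_classes is None:
        num_classes = int(max(y_true.max(), y_pred.max())) + 1
    tp = np.zeros(num_classes, dtype=np.int64)
    fp = np.zeros(num_classes, dtype=np.int64)
    fn = np.zeros(num_classes, dtype=np.int64)
    for c in range(num_classes):
        tp[c] = np.sum((y_true == c) & (y_pred == c))
        fp[c] = np.sum((y_true != c) & (y_pred == c))
        fn[c] = np.sum((y_true == c) & (y_pred != c))
    tn = len(y_true) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(len(num), np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


@dataclasses.dataclass
class MetricsReport:
    """Per-class ratios plus macro aggregates; NaN marks an undefined ratio."""

    precision: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    accuracy: np.ndarray
    bacc: float
    average_auc: float | None = None
    per_class_auc: np.ndarray | None = None

    @property
    def average_precision(self) -> float:
        return float(np.nanmean(self.precision))

    @property
    def average_specificity(self) -> float:
        return float(np.nanmean(self.specificity))

    @property
    def average_accuracy(self) -> float:
        return float(np.nanmean(self.accuracy))

    def to_frame(self) -> pd.DataFrame:
        rows = pd.DataFrame(
            {
                "precision": self.precision,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "accuracy": self.accuracy,
            }
        )
        if self.per_class_auc is not None:
            rows["auc"] = self.per_class_auc
        agg = {
            "precision": self.average_precision,
            "sensitivity": self.bacc,
            "specificity": self.average_specificity,
            "accuracy": self.average_accuracy,
        }
        if self.per_class_auc is not None:
            agg["auc"] = self.average_auc
        rows.loc["macro"] = agg
        return rows

    def to_json(self) -> str:
        def _clean(x):
            return [None if np.isnan(v) else float(v) for v in x]

        doc = {
            "per_class": {
                "precision": _clean(self.precision),
                "sensitivity": _clean(self.sensitivity),
                "specificity": _clean(self.specificity),
                "accuracy": _clean(self.accuracy),
            },
            "bacc": self.bacc,
            "average_precision": self.average_precision,
            "average_specificity": self.average_specificity,
            "average_accuracy": self.average_accuracy,
        }
        if self.per_class_auc is not None:
            doc["per_class"]["auc"] = _clean(self.per_class_auc)
            doc["average_auc"] = self.average_auc
        return json.dumps(doc, indent=2)


def per_class_metrics(confusion: ConfusionCounts) -> MetricsReport:
    """Precision, sensitivity, specificity and accuracy per class.

    precision_i = TP/(TP+FP), sensitivity_i = TP/(TP+FN),
    specificity_i = TN/(TN+FP), accuracy_i = (TP+TN)/(TP+FP+TN+FN).
    """
    c = confusion
    precision = _safe_ratio(c.tp, c.tp + c.fp)
    sensitivity = _safe_ratio(c.tp, c.tp + c.fn)
    specificity = _safe_ratio(c.tn, c.tn + c.fp)
    accuracy = _safe_ratio(c.tp + c.tn, c.tp + c.fp + c.tn + c.fn)
    for name, arr in (("precision", precision), ("sensitivity", sensitivity)):
        if np.any(np.isnan(arr)):
            warnings.warn(
                f"{name} undefined (0/0) for classes {np.flatnonzero(np.isnan(arr)).tolist()}; "
                "excluded from macro averages",
                stacklevel=2,
            )
    return MetricsReport(
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=accuracy,
        bacc=bacc(confusion, allow_missing=True),
    )


def bacc(confusion: ConfusionCounts, allow_missing: bool = False) -> float:
    """Balanced accuracy: mean of per-class sensitivities TP/(TP+FN)."""
    sens = _safe_ratio(confusion.tp, confusion.tp + confusion.fn)
    if np.any(np.isnan(sens)):
        if not allow_missing:
            raise ValueError(
                f"classes {np.flatnonzero(np.isnan(sens)).tolist()} absent from ground truth"
            )
        return float(np.nanmean(sens))
    return float(sens.mean())


def roc_auc(scores, binary_labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney U) statistic.

    Equals P(score+ > score-) + 0.5 P(tie) over all positive-negative pairs.
    Invariant under strictly monotone transforms of the scores.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(binary_labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both label values must be present to compute AUC")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def average_auc(probabilities, y_true) -> tuple[float, np.ndarray]:
    """Macro one-vs-rest AUC: unweighted mean over classes present in y_true.

    Returns (macro AUC, per-class AUC vector with NaN for absent classes).
    """
    probabilities = np.asarray(probabilities, dtype=np.float64)
    y_true = np.asarray(y_true)
    n_classes = probabilities.shape[1]
    aucs = np.full(n_classes, np.nan)
    for c in range(n_classes):
        pos = y_true == c
        if 0 < pos.sum() < len(y_true):
            aucs[c] = roc_auc(probabilities[:, c], pos)
    if np.any(np.isnan(aucs)):
        warnings.warn(
            f"AUC undefined for classes {np.flatnonzero(np.isnan(aucs)).tolist()}; "
            "excluded from the macro average",
            stacklevel=2,
        )
    return float(np.nanmean(aucs)), aucs


def evaluate_predictions(probabilities, y_true, num_classes: int | None = None) -> MetricsReport:
    """Full report (confusion ratios, BACC, macro AUC) from probabilities."""
    probabilities = np.asarray(probabilities, dtype=np.float64)
    y_true = np.asarray(y_true)
    if num_classes is None:
        num_classes = probabilities.shape[1]
    y_pred = probabilities.argmax(axis=1)
    report = per_class_metrics(confusion_counts(y_true, y_pred, num_classes))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report.average_auc, report.per_class_auc = average_auc(probabilities, y_true)
    return report
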
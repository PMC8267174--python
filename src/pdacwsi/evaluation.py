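"""Binary-classification evaluation: confusion matrices, accuracy /
precision / recall / F1 per class, ROC and AUC. The positive class is
"cancerous" throughout; metrics with a zero denominator are reported as
missing (None), never coerced to 0."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 integer counts; positive class = cancerous."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count the four outcomes; labels must be binary 0/1 with 1 =
    cancerous."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def _f1(p: float | None, r: float | None) -> float | None:
    if p is None or r is None or p + r == 0:
        return None
    return 2 * p * r / (p + r)


@dataclass
class MetricsReport:
    accuracy: float
    precision: dict[str, float | None]
    recall: dict[str, float | None]
    f1: dict[str, float | None]
    confusion: ConfusionMatrix
    roc: pd.DataFrame | None = field(default=None, repr=False)
    auc: float | None = None

    def to_dict(self, decimals: int = 4) -> dict:
        def r(v):
            return None if v is None else round(v, decimals)
        return {
            "accuracy": r(self.accuracy),
            "accuracy_pct": None if self.accuracy is None else round(100 * self.accuracy, 1),
            "precision": {k: r(v) for k, v in self.precision.items()},
            "recall": {k: r(v) for k, v in self.recall.items()},
            "f1": {k: r(v) for k, v in self.f1.items()},
            "auc": r(self.auc),
            "confusion": {"tp": self.confusion.tp, "fp": self.confusion.fp,
                          "tn": self.confusion.tn, "fn": self.confusion.fn},
        }

    def to_json(self, path: str | Path, decimals: int = 4) -> None:
        Path(path).write_text(json.dumps(self.to_dict(decimals), indent=2))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in ("normal", "cancerous"):
            rows.append({"class": cls, "accuracy": self.accuracy,
                         "precision": self.precision[cls],
                         "recall": self.recall[cls], "f1": self.f1[cls]})
        return pd.DataFrame(rows)


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy plus per-class precision/recall/F1 by the standard
    formulas. The normal class treats "predicted normal" as its positive
    call, so precision_normal = tn / (tn + fn) etc."""
    precision = {"cancerous": _ratio(cm.tp, cm.tp + cm.fp),
                 "normal": _ratio(cm.tn, cm.tn + cm.fn)}
    recall = {"cancerous": _ratio(cm.tp, cm.tp + cm.fn),
              "normal": _ratio(cm.tn, cm.tn + cm.fp)}
    f1 = {cls: _f1(precision[cls], recall[cls]) for cls in precision}
    return MetricsReport(accuracy=(cm.tp + cm.tn) / cm.total,
                         precision=precision, recall=recall, f1=f1,
                         confusion=cm)


def confusion_from_recalls(n_normal: int, n_cancerous: int,
                           recall_normal: float, recall_cancerous: float
                           ) -> ConfusionMatrix:
    """Reconstruct integer counts from class sizes and per-class recalls
    (rounding recall x class size to the nearest integer) — the published
    form of a confusion matrix."""
    tn = round(recall_normal * n_normal)
    tp = round(recall_cancerous * n_cancerous)
    return ConfusionMatrix(tp=tp, fp=n_normal - tn, tn=tn, fn=n_cancerous - tp)


def roc_auc(scores, y_true) -> tuple[pd.DataFrame, float]:
    """ROC by threshold sweep over the unique scores and trapezoid AUC
    (equal to the Mann-Whitney pair statistic). Requires both classes."""
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thresholds = _roc_curve(y_true, scores)
    points = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return points, float(_trapezoid_auc(fpr, tpr))


def slide_accuracy(n_total: int, n_misclassified: int) -> float:
    """Percentage of correctly classified slides."""
    if n_total <= 0 or not 0 <= n_misclassified <= n_total:
        raise ValueError("need 0 <= n_misclassified <= n_total, n_total > 0")
    return 100.0 * (n_total - n_misclassified) / n_total
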
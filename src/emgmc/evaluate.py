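"""Classification metrics from a confusion matrix.

Accuracy, precision, recall, F1 and the Matthews correlation coefficient
(MCC), with an explicit multiclass extension: accuracy is trace/total,
precision/recall/F1 are computed per class one-vs-rest and macro-averaged,
and MCC uses the multiclass (Gorodkin) confusion-matrix form, which
reduces exactly to the familiar binary
(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)) when K = 2.
Degenerate 0/0 ratios (a class never predicted, or absent from the truth)
are reported as 0 and flagged instead of propagating NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ConfusionMatrix:
    """K x K count matrix; rows = true class, columns = predicted class."""

    counts: np.ndarray
    labels: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K with K = len(labels)")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


@dataclass
class MetricsReport:
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    precision_macro: float
    recall_macro: float
    f1_macro: float
    mcc: float
    averaging: str
    labels: list = field(default_factory=list)
    degenerate_classes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision_macro,
            "recall": self.recall_macro,
            "f1": self.f1_macro,
            "mcc": self.mcc,
            "averaging": self.averaging,
            "per_class": {
                str(lab): {
                    "precision": float(p),
                    "recall": float(r),
                    "f1": float(f),
                }
                for lab, p, r, f in zip(
                    self.labels, self.precision, self.recall, self.f1
                )
            },
            "degenerate_classes": [str(c) for c in self.degenerate_classes],
        }


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Count matrix over the sorted union of observed labels."""
    t = list(true_labels)
    p = list(predicted_labels)
    if len(t) != len(p):
        raise ValueError("label vectors must have equal length")
    if len(t) == 0:
        raise ValueError("need at least one sample")
    labels = sorted(set(t) | set(p))
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for ti, pi in zip(t, p):
        counts[index[ti], index[pi]] += 1
    return ConfusionMatrix(counts, labels)


def _multiclass_mcc(counts: np.ndarray) -> float:
    """Gorodkin's confusion-matrix MCC; 0 when a denominator vanishes."""
    c = counts.astype(float)
    s = c.sum()
    trace = np.trace(c)
    t_k = c.sum(axis=1)  # true per class
    p_k = c.sum(axis=0)  # predicted per class
    num = trace * s - float(t_k @ p_k)
    den = math.sqrt(max(s**2 - float(p_k @ p_k), 0.0)) * math.sqrt(
        max(s**2 - float(t_k @ t_k), 0.0)
    )
    return num / den if den > 0 else 0.0


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, per-class and macro P/R/F1, and MCC from a confusion matrix."""
    counts = cm.counts.astype(float)
    total = counts.sum()
    if total < 1:
        raise ValueError("empty confusion matrix")
    k = len(cm.labels)
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp

    degenerate = []
    precision = np.zeros(k)
    recall = np.zeros(k)
    f1 = np.zeros(k)
    for i in range(k):
        p_den = tp[i] + fp[i]
        r_den = tp[i] + fn[i]
        if p_den == 0 or r_den == 0:
            degenerate.append(cm.labels[i])
        precision[i] = tp[i] / p_den if p_den > 0 else 0.0
        recall[i] = tp[i] / r_den if r_den > 0 else 0.0
        f_den = precision[i] + recall[i]
        f1[i] = 2 * precision[i] * recall[i] / f_den if f_den > 0 else 0.0

    return MetricsReport(
        accuracy=float(np.trace(counts) / total),
        precision=precision,
        recall=recall,
        f1=f1,
        precision_macro=float(precision.mean()),
        recall_macro=float(recall.mean()),
        f1_macro=float(f1.mean()),
        mcc=_multiclass_mcc(cm.counts),
        averaging="binary" if k == 2 else "macro",
        labels=list(cm.labels),
        degenerate_classes=degenerate,
    )


def binary_metrics(tp: int, fn: int, fp: int, tn: int) -> dict:
    """Two-class metrics straight from the four cell counts.

    Positive-class precision/recall/F1 and the binary MCC; the confusion
    matrix is [[tn, fp], [fn, tp]] with the positive class second.
    """
    cm = ConfusionMatrix(np.array([[tn, fp], [fn, tp]]), ["neg", "pos"])
    rep = metrics(cm)
    return {
        "accuracy": rep.accuracy,
        "precision": float(rep.precision[1]),
        "recall": float(rep.recall[1]),
        "f1": float(rep.f1[1]),
        "mcc": rep.mcc,
    }
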
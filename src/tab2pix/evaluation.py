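"""Confusion matrices and diagnostic metrics for binary diagnosis.

Convention: malignant is class 0 (the negative row of the confusion
matrix) and benign is class 1 (positive), so TN counts correctly
identified malignant cases. Sensitivity is the proportion of positives
correctly identified, specificity the proportion of negatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "UndefinedMetricError",
    "confusion",
    "metrics",
    "summarize",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero for this confusion matrix."""


@dataclass(frozen=True)
class ConfusionMatrix:
    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must hold at least one case")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp


@dataclass(frozen=True)
class EvalReport:
    """Proportions in [0, 1] plus the matrix they came from."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    matrix: ConfusionMatrix


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionMatrix:
    """Count TN/FP/FN/TP with benign (1) as the positive class."""
    yt = np.asarray(y_true, dtype=int).ravel()
    yp = np.asarray(y_pred, dtype=int).ravel()
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if yt.size < 1:
        raise ValueError("need at least one case")
    for arr, name in ((yt, "y_true"), (yp, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must contain only 0/1 labels")
    return ConfusionMatrix(
        tn=int(((yt == 0) & (yp == 0)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
        tp=int(((yt == 1) & (yp == 1)).sum()),
    )


def metrics(cm: ConfusionMatrix) -> EvalReport:
    """Accuracy, sensitivity, specificity, precision and F1 from counts.

    Raises :class:`UndefinedMetricError` rather than silently reporting 0
    when a denominator is empty.
    """
    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            raise UndefinedMetricError(f"{name} is undefined (empty denominator)")
        return num / den

    sens = ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    spec = ratio(cm.tn, cm.tn + cm.fp, "specificity")
    prec = ratio(cm.tp, cm.tp + cm.fp, "precision")
    if prec + sens == 0:
        raise UndefinedMetricError("f1 is undefined (precision + sensitivity = 0)")
    f1 = 2 * prec * sens / (prec + sens)
    acc = (cm.tp + cm.tn) / cm.total
    return EvalReport(acc, sens, spec, prec, f1, cm)


def summarize(reports: Sequence[EvalReport]) -> dict[str, dict[str, float]]:
    """Best (max per metric, over attempts) and arithmetic-mean summaries."""
    if not reports:
        raise ValueError("need at least one report")
    out: dict[str, dict[str, float]] = {"best": {}, "average": {}}
    for name in ("accuracy", "sensitivity", "specificity", "precision", "f1"):
        vals = [getattr(r, name) for r in reports]
        out["best"][name] = max(vals)
        out["average"][name] = mean(vals)
    return out


def as_percent(value: float) -> float:
    """Render a proportion the way the summary tables print it."""
    return round(100.0 * value, 2)
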
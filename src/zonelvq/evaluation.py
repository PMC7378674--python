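"""Contingency-table construction and diagnostic metrics.

The screening task is binary: "suspected" (lesion present, the
positive class) versus "normal".  Given truth/prediction label lists
the confusion matrix counts TP, FP, FN, TN, and the standard screening
metrics follow, each reported as a percentage:

    accuracy    = (TP + TN) / (P + N) * 100
    sensitivity = TP / (TP + FN) * 100     (= recall = TPR)
    specificity = TN / (TN + FP) * 100
    precision   = TP / (TP + FP) * 100
    FPR         = FP / (FP + TN) * 100

A metric whose denominator is zero is reported as ``None`` ("n/a"),
never as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyEvaluationError, LabelingError
from .lvq import LVQModel, predict
from .zoning import ZoneGridSpec, locate_tumor

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "build_confusion",
    "compute_metrics",
    "evaluate_run",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts with the positive-class label they refer to."""

    tp: int
    fp: int
    fn: int
    tn: int
    positive: str = "suspected"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def p(self) -> int:
        """Number of truth-positive samples."""
        return self.tp + self.fn

    @property
    def n(self) -> int:
        """Number of truth-negative samples."""
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.p + self.n


@dataclass(frozen=True)
class MetricsReport:
    """Diagnostic metrics as percentages; ``None`` marks an undefined metric."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    fpr: float | None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "fpr": self.fpr,
        }


def build_confusion(
    truths: list[str],
    predictions: list[str],
    positive: str = "suspected",
    negative: str = "normal",
) -> ConfusionMatrix:
    """Count TP/FP/FN/TN over paired truth and prediction labels.

    Raises
    ------
    LabelingError
        If any label is neither the positive nor the negative class.
    """
    if len(truths) != len(predictions):
        raise ValueError(f"{len(truths)} truths but {len(predictions)} predictions")
    classes = {positive, negative}
    tp = fp = fn = tn = 0
    for t, pr in zip(truths, predictions):
        if t not in classes:
            raise LabelingError(f"unknown truth label {t!r}")
        if pr not in classes:
            raise LabelingError(f"unknown prediction label {pr!r}")
        if t == positive:
            if pr == positive:
                tp += 1
            else:
                fn += 1
        else:
            if pr == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn, positive=positive)


def _pct(num: int, den: int) -> float | None:
    return None if den == 0 else num / den * 100.0


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Diagnostic metrics from a confusion matrix, as percentages.

    Sensitivity is TP/(TP+FN) and specificity TN/(TN+FP), the standard
    epidemiological definitions.

    Raises
    ------
    EmptyEvaluationError
        If the matrix contains no samples at all.
    """
    if cm.total == 0:
        raise EmptyEvaluationError("confusion matrix is empty; no samples evaluated")
    return MetricsReport(
        accuracy=_pct(cm.tp + cm.tn, cm.total),
        sensitivity=_pct(cm.tp, cm.tp + cm.fn),
        specificity=_pct(cm.tn, cm.tn + cm.fp),
        precision=_pct(cm.tp, cm.tp + cm.fp),
        fpr=_pct(cm.fp, cm.fp + cm.tn),
    )


def _note(truth: str, pred: str, positive: str) -> str:
    if truth == positive:
        return "TP" if pred == positive else "FN"
    return "FP" if pred == positive else "TN"


def evaluate_run(
    model: LVQModel,
    features: np.ndarray,
    truths: list[str],
    filenames: list[str] | None = None,
    zone_counts: list[np.ndarray] | None = None,
    grid: ZoneGridSpec | None = None,
    positive: str = "suspected",
    negative: str = "normal",
) -> tuple[pd.DataFrame, ConfusionMatrix, MetricsReport]:
    """Score a labeled test set: per-image table, confusion matrix, metrics.

    The table has one row per image with the distance to each class
    prototype, truth, prediction, the TP/TN/FP/FN note, and — when
    per-image ``zone_counts`` are supplied — the localized side of any
    suspected finding.
    """
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    n = features.shape[0]
    if n == 0:
        raise EmptyEvaluationError("no test images to evaluate")
    if len(truths) != n:
        raise ValueError(f"{n} feature rows but {len(truths)} labels")
    if filenames is None:
        filenames = [f"image-{i + 1}" for i in range(n)]
    if grid is None:
        grid = ZoneGridSpec()

    rows = []
    predictions = []
    for i in range(n):
        label, dists = predict(model, features[i])
        predictions.append(label)
        row = {"file": filenames[i]}
        for lab in model.class_labels:
            row[f"dist_{lab}"] = dists[lab]
        row["truth"] = truths[i]
        row["predicted"] = label
        row["note"] = _note(truths[i], label, positive)
        if zone_counts is not None:
            loc = locate_tumor(zone_counts[i], label, grid, normal_label=negative)
            row["position"] = loc.side
            row["zone"] = loc.zone_index
        rows.append(row)
    table = pd.DataFrame(rows)
    cm = build_confusion(truths, predictions, positive=positive, negative=negative)
    return table, cm, compute_metrics(cm)
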
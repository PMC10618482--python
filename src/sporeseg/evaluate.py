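"""Confusion matrices and the classification metrics used to judge segmentations.

All metrics derive from one-vs-rest counts TP/FP/FN/TN read off an 8x8
confusion matrix (rows = truth, columns = prediction):

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)
    F1          = 2 TP / (2 TP + FP + FN)

Zero denominators yield 0 by convention, which keeps classes absent from
both truth and prediction from inflating macro averages.  Support is the
number of ground-truth samples per class (the row sum).  Scoring happens
at the 1/16 grid against blockwise-majority masks; grid cells whose
downsampled label is 0 are excluded everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .labels import DEFAULT_SCHEME, N_CLASSES, LabelScheme

__all__ = [
    "ConfusionMatrix",
    "PerClassCounts",
    "MetricsReport",
    "confusion_matrix",
    "per_class_counts",
    "accuracy",
    "precision",
    "sensitivity",
    "f1",
    "metrics_report",
    "per_image_accuracy",
    "mean_accuracy",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray
    scheme: LabelScheme = field(default_factory=lambda: DEFAULT_SCHEME)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"confusion matrix must be 8x8, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        names = self.scheme.names
        return pd.DataFrame(self.counts, index=names, columns=names)


@dataclass(frozen=True)
class PerClassCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_matrix(true_labels, pred_labels) -> ConfusionMatrix:
    """Count (true, predicted) pairs; labels must already be in 1..8."""
    t = np.asarray(true_labels).ravel()
    p = np.asarray(pred_labels).ravel()
    if t.shape != p.shape:
        raise ValueError(f"label vectors differ in length: {t.size} vs {p.size}")
    for name, v in (("true", t), ("pred", p)):
        if v.size and (v.min() < 1 or v.max() > N_CLASSES):
            raise ValueError(f"{name} labels outside 1..8 (filter 0 before scoring)")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(counts, (t.astype(int) - 1, p.astype(int) - 1), 1)
    return ConfusionMatrix(counts=counts)


def per_class_counts(cm: ConfusionMatrix, c: int) -> PerClassCounts:
    """One-vs-rest reduction of the matrix for class ``c`` (1..8)."""
    if not 1 <= c <= N_CLASSES:
        raise ValueError(f"class index must be in 1..8, got {c}")
    i = c - 1
    tp = int(cm.counts[i, i])
    fp = int(cm.counts[:, i].sum()) - tp
    fn = int(cm.counts[i, :].sum()) - tp
    tn = cm.total - tp - fp - fn
    return PerClassCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def accuracy(arg) -> float:
    """Overall accuracy: trace/total for a matrix, (TP+TN)/all for counts."""
    if isinstance(arg, ConfusionMatrix):
        return _safe_div(float(np.trace(arg.counts)), float(arg.total))
    c: PerClassCounts = arg
    return _safe_div(c.tp + c.tn, c.total)


def precision(counts: PerClassCounts) -> float:
    return _safe_div(counts.tp, counts.tp + counts.fp)


def sensitivity(counts: PerClassCounts) -> float:
    return _safe_div(counts.tp, counts.tp + counts.fn)


def f1(counts: PerClassCounts) -> float:
    return _safe_div(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn)


@dataclass
class MetricsReport:
    """Per-class precision/sensitivity/F1/support plus overall and macro scores."""

    cm: ConfusionMatrix
    per_class: pd.DataFrame
    overall_accuracy: float
    macro_precision: float
    macro_sensitivity: float
    macro_f1: float

    @property
    def total_support(self) -> int:
        return int(self.per_class["support"].sum())

    def to_json_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "macro_precision": self.macro_precision,
            "macro_sensitivity": self.macro_sensitivity,
            "macro_f1": self.macro_f1,
            "per_class": self.per_class.to_dict(orient="index"),
        }


def metrics_report(cm: ConfusionMatrix) -> MetricsReport:
    """Full per-class and macro-averaged report from one confusion matrix."""
    rows = {}
    for c in range(1, N_CLASSES + 1):
        counts = per_class_counts(cm, c)
        rows[cm.scheme.name_of(c)] = {
            "precision": precision(counts),
            "sensitivity": sensitivity(counts),
            "f1": f1(counts),
            "support": int(cm.supports[c - 1]),
        }
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    return MetricsReport(
        cm=cm,
        per_class=per_class,
        overall_accuracy=accuracy(cm),
        macro_precision=float(per_class["precision"].mean()),
        macro_sensitivity=float(per_class["sensitivity"].mean()),
        macro_f1=float(per_class["f1"].mean()),
    )


def per_image_accuracy(model_outputs, masks) -> np.ndarray:
    """Fraction of correctly labeled scored cells, one value per image.

    ``model_outputs`` are predicted label grids; ``masks`` the matching
    downsampled ground-truth grids.  Cells with true label 0 are not
    scored; an image with no scored cells is excluded with a warning.
    """
    if len(model_outputs) != len(masks):
        raise ValueError("need one mask per model output")
    out = []
    for i, (pred, mask) in enumerate(zip(model_outputs, masks)):
        pred = np.asarray(pred)
        mask = np.asarray(mask)
        if pred.shape != mask.shape:
            raise ValueError(f"image {i}: prediction grid {pred.shape} != mask {mask.shape}")
        scored = mask > 0
        n = int(scored.sum())
        if n == 0:
            warnings.warn(f"image {i} has no scored cells; excluded", stacklevel=2)
            continue
        out.append(float((pred[scored] == mask[scored]).sum() / n))
    return np.asarray(out)


def mean_accuracy(values) -> float:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no per-image accuracies to average")
    return float(values.mean())
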
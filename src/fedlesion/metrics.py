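"""Multiclass diagnostic metrics and communication accounting.

Per-class metrics follow the one-vs-rest reduction of the confusion
matrix: for class c, TP is the diagonal entry, FN the rest of row c,
FP the rest of column c, and TN everything else.  Reported metrics are

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    recall      = TP / (TP + FN)          (identically sensitivity)
    precision   = TP / (TP + FP)
    specificity = TN / (TN + FP)
    F1          = 2 * precision * recall / (precision + recall)

A metric whose denominator is zero (e.g. precision for a class never
predicted) is reported as 0 with an ``undefined`` flag set; macro
averages are unweighted means over classes.

Communication accounting counts transmitted parameter scalars per
round (uplink and downlink), with a byte conversion at 4 bytes per
scalar (float32 on the wire).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "CommunicationLedger",
    "confusion_matrix",
    "binary_counts",
    "accuracy",
    "recall",
    "precision",
    "specificity",
    "f1",
    "macro_report",
    "communication_cost",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "specificity", "f1")


@dataclass
class ConfusionMatrix:
    """L x L counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    class_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise InputError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise InputError("confusion matrix counts must be nonnegative")
        if self.class_names is not None and len(self.class_names) != len(self.counts):
            raise InputError("one class name per class required")

    @property
    def L(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        names = list(self.class_names or range(self.L))
        return pd.DataFrame(self.counts, index=names, columns=names)


def confusion_matrix(
    true_labels, predicted_labels, L: int, class_names: tuple[str, ...] | None = None
) -> ConfusionMatrix:
    """Tally (true, predicted) label pairs into an L x L matrix."""
    y, p = np.asarray(true_labels, dtype=np.int64), np.asarray(predicted_labels, dtype=np.int64)
    if y.shape != p.shape or y.ndim != 1:
        raise InputError("label vectors must be 1-D and of equal length")
    if len(y) and (y.min() < 0 or y.max() >= L or p.min() < 0 or p.max() >= L):
        raise InputError(f"labels must lie in [0, {L})")
    counts = np.bincount(y * L + p, minlength=L * L).reshape(L, L)
    return ConfusionMatrix(counts, class_names)


def binary_counts(cm: ConfusionMatrix, c: int) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, FP, TN, FN) for class ``c``."""
    if not (0 <= c < cm.L):
        raise InputError(f"class index {c} out of range")
    tp = int(cm.counts[c, c])
    fn = int(cm.counts[c].sum()) - tp
    fp = int(cm.counts[:, c].sum()) - tp
    tn = cm.total - tp - fn - fp
    return tp, fp, tn, fn


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """(TP + TN) / all."""
    return _ratio(tp + tn, tp + tn + fp + fn)


def recall(tp: int, fn: int) -> float:
    """TP / (TP + FN); identically the sensitivity."""
    return _ratio(tp, tp + fn)


def precision(tp: int, fp: int) -> float:
    """TP / (TP + FP)."""
    return _ratio(tp, tp + fp)


def specificity(tn: int, fp: int) -> float:
    """TN / (TN + FP)."""
    return _ratio(tn, tn + fp)


def f1(precision_value: float, recall_value: float) -> float:
    """Harmonic mean of precision and recall."""
    return _ratio(2.0 * precision_value * recall_value, precision_value + recall_value)


@dataclass
class MetricsReport:
    """Per-class and macro-averaged one-vs-rest metrics.

    ``per_class`` has one row per class with the five metrics plus an
    ``undefined`` flag marking classes where any denominator was zero;
    ``macro`` holds the unweighted means; ``overall_accuracy`` is
    trace / total of the confusion matrix.
    """

    per_class: pd.DataFrame
    macro: dict[str, float]
    overall_accuracy: float
    cm: ConfusionMatrix = field(repr=False)

    def to_summary_row(self, scale: float = 1.0) -> dict[str, float]:
        """Flat summary (optionally on the x100 percent scale)."""
        out = {k: v * scale for k, v in self.macro.items()}
        out["overall_accuracy"] = self.overall_accuracy * scale
        return out


def macro_report(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class one-vs-rest metrics with unweighted macro averages."""
    rows = []
    for c in range(cm.L):
        tp, fp, tn, fn = binary_counts(cm, c)
        prec = precision(tp, fp)
        rec = recall(tp, fn)
        rows.append(
            {
                "accuracy": accuracy(tp, tn, fp, fn),
                "precision": prec,
                "recall": rec,
                "specificity": specificity(tn, fp),
                "f1": f1(prec, rec),
                "undefined": (tp + fn == 0) or (tp + fp == 0) or (tn + fp == 0),
            }
        )
    names = list(cm.class_names or range(cm.L))
    per_class = pd.DataFrame(rows, index=names).rename_axis("class")
    macro = {name: float(per_class[name].mean()) for name in METRIC_NAMES}
    overall = _ratio(float(np.trace(cm.counts)), cm.total)
    return MetricsReport(per_class, macro, overall, cm)


@dataclass
class CommunicationLedger:
    """Per-round and cumulative transmitted-scalar counts."""

    uplink: np.ndarray
    downlink: np.ndarray
    scalar_bytes: int = 4

    def __post_init__(self) -> None:
        self.uplink = np.asarray(self.uplink, dtype=np.int64)
        self.downlink = np.asarray(self.downlink, dtype=np.int64)
        if (self.uplink < 0).any() or (self.downlink < 0).any():
            raise InputError("scalar counts must be nonnegative")

    @property
    def cumulative_uplink(self) -> np.ndarray:
        return np.cumsum(self.uplink)

    @property
    def total_uplink(self) -> int:
        return int(self.uplink.sum())

    @property
    def total_downlink(self) -> int:
        return int(self.downlink.sum())

    @property
    def total_bytes(self) -> int:
        return (self.total_uplink + self.total_downlink) * self.scalar_bytes

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "round": np.arange(1, len(self.uplink) + 1),
                "uplink_scalars": self.uplink,
                "downlink_scalars": self.downlink,
                "cumulative_uplink": self.cumulative_uplink,
                "uplink_bytes": self.uplink * self.scalar_bytes,
            }
        )


def communication_cost(history, scalar_bytes: int = 4) -> CommunicationLedger:
    """Ledger of the per-round scalar traffic logged in a history."""
    uplink = [r.uplink_scalars for r in history.records]
    downlink = [r.downlink_scalars for r in history.records]
    return CommunicationLedger(np.array(uplink), np.array(downlink), scalar_bytes)
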
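"""Binary-classification performance assessment.

Per-class accuracy Q_i = 100 * c_i / n_i, overall accuracy as the
f_i-weighted sum of the class accuracies (identically 100*(TP+TN)/N),
AFP precision, and the Matthews correlation coefficient.  A zero factor
in the MCC denominator yields 0 by convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .seqio import AFP, NONAFP


class UndefinedMetricError(ZeroDivisionError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion counts must describe >= 1 item")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


def confusion_from_labels(
    y_true: Sequence[str], y_pred: Sequence[str]
) -> ConfusionCounts:
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors differ in length")
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == AFP:
            tp += p == AFP
            fn += p != AFP
        else:
            tn += p != AFP
            fp += p == AFP
    return ConfusionCounts(tp, tn, fp, fn)


def class_accuracy(counts: ConfusionCounts, cls: str) -> float:
    """Q_i as a percentage; *cls* is AFP or NONAFP."""
    if cls == AFP:
        n = counts.tp + counts.fn
        c = counts.tp
    elif cls == NONAFP:
        n = counts.tn + counts.fp
        c = counts.tn
    else:
        raise ValueError(f"class must be {AFP} or {NONAFP}, got {cls!r}")
    if n == 0:
        raise UndefinedMetricError(f"no items of class {cls}")
    return 100.0 * c / n


def overall_accuracy(counts: ConfusionCounts) -> float:
    return 100.0 * (counts.tp + counts.tn) / counts.total


def precision(counts: ConfusionCounts) -> float:
    if counts.tp + counts.fp == 0:
        raise UndefinedMetricError("no positive predictions")
    return 100.0 * counts.tp / (counts.tp + counts.fp)


def mcc(counts: ConfusionCounts) -> float:
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def summary_table(counts: ConfusionCounts) -> str:
    """Human-readable evaluation block (percentages at one decimal)."""
    lines = [
        f"AFP accuracy\t{class_accuracy(counts, AFP):.1f}%",
        f"AFP precision\t{precision(counts):.1f}%"
        if counts.tp + counts.fp
        else "AFP precision\tundefined",
        f"Overall accuracy\t{overall_accuracy(counts):.1f}%",
        f"MCC\t{mcc(counts):.3f}",
        f"TP\t{counts.tp}",
        f"TN\t{counts.tn}",
        f"FP\t{counts.fp}",
        f"FN\t{counts.fn}",
    ]
    return "\n".join(lines)
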
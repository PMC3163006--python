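"""Confusion matrix and the three diagnostic metrics.

Positive class (+1, syndrome present) is "positive" throughout:

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / (TP + FN + FP + TN)

Percentages are rendered at one decimal, rounding half up (89.74 -> 89.7,
83.87 -> 83.9). A ratio whose denominator is empty is reported as NA, never
as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .exceptions import DataError

__all__ = ["ConfusionMatrix", "MetricSet", "confusion", "metrics", "percent"]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise DataError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fn + other.fn,
            self.fp + other.fp, self.tn + other.tn,
        )


@dataclass(frozen=True)
class MetricSet:
    """Sensitivity, specificity, accuracy as fractions in [0, 1].

    A metric is None when its denominator is empty (no positives for
    sensitivity, no negatives for specificity).
    """

    sensitivity: float | None
    specificity: float | None
    accuracy: float

    @property
    def sensitivity_pct(self) -> float | None:
        return None if self.sensitivity is None else percent(self.sensitivity)

    @property
    def specificity_pct(self) -> float | None:
        return None if self.specificity is None else percent(self.specificity)

    @property
    def accuracy_pct(self) -> float:
        return percent(self.accuracy)

    def format_row(self) -> str:
        def fmt(x: float | None) -> str:
            return "NA" if x is None else f"{x:.1f}"

        return "\t".join(
            fmt(v) for v in (self.sensitivity_pct, self.specificity_pct, self.accuracy_pct)
        )


def percent(fraction: float) -> float:
    """Render a fraction as a percentage at 1 decimal, rounding half up."""
    d = Decimal(repr(fraction * 100)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return float(d)


def confusion(labels, predictions) -> ConfusionMatrix:
    """Count (label, prediction) pairs; +1 is the positive class."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape or y.ndim != 1:
        raise DataError(
            f"labels and predictions must be equal-length 1-D, got shapes "
            f"{y.shape} and {p.shape}"
        )
    if y.size == 0:
        raise DataError("empty label/prediction lists")
    for arr, what in ((y, "labels"), (p, "predictions")):
        bad = set(np.unique(arr)) - {-1, 1}
        if bad:
            raise DataError(f"{what} must be +1/-1, found {sorted(bad)}")
    return ConfusionMatrix(
        tp=int(((y == 1) & (p == 1)).sum()),
        fn=int(((y == 1) & (p == -1)).sum()),
        fp=int(((y == -1) & (p == 1)).sum()),
        tn=int(((y == -1) & (p == -1)).sum()),
    )


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """The three diagnostic ratios of a confusion matrix."""
    if cm.total == 0:
        raise DataError("cannot compute metrics of an empty confusion matrix")
    sens = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else None
    spec = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) > 0 else None
    acc = (cm.tp + cm.tn) / cm.total
    return MetricSet(sensitivity=sens, specificity=spec, accuracy=acc)
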
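"""Detection/classification metrics.

Se = TP/(TP+FN), +P = TP/(TP+FP), and Acc = TP/(TP+FP+FN).  Note this
Acc deliberately has no TN term (it is a detection-style accuracy, not
the conventional classification accuracy); ``conventional_accuracy``
reports the usual (TP+TN)/total separately to avoid confusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EvalCounts", "evaluate", "counts_to_metrics", "conventional_accuracy", "mean_abs_error"]


@dataclass(frozen=True)
class EvalCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def positive_predictivity(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def accuracy(self) -> float:
        d = self.tp + self.fp + self.fn
        return self.tp / d if d else float("nan")


def counts_to_metrics(tp: int, fp: int, fn: int) -> EvalCounts:
    return EvalCounts(tp=tp, fp=fp, fn=fn)


def evaluate(predictions: np.ndarray, labels: np.ndarray, positive: int = 1) -> EvalCounts:
    """Counts for binary state predictions against reference labels."""
    p = np.asarray(predictions)
    y = np.asarray(labels)
    if p.size == 0 or p.shape != y.shape:
        raise ValueError("predictions and labels must be non-empty and aligned")
    tp = int(np.sum((p == positive) & (y == positive)))
    fp = int(np.sum((p == positive) & (y != positive)))
    fn = int(np.sum((p != positive) & (y == positive)))
    return EvalCounts(tp=tp, fp=fp, fn=fn)


def conventional_accuracy(predictions: np.ndarray, labels: np.ndarray) -> float:
    p = np.asarray(predictions)
    y = np.asarray(labels)
    if p.size == 0 or p.shape != y.shape:
        raise ValueError("predictions and labels must be non-empty and aligned")
    return float(np.mean(p == y))


def mean_abs_error(dd: np.ndarray, rr: np.ndarray) -> float:
    """Mean absolute difference between detected and reference intervals (s)."""
    a = np.asarray(dd, dtype=float)
    b = np.asarray(rr, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty interval sequences")
    return float(np.mean(np.abs(a - b)))
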
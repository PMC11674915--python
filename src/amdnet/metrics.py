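"""Confusion-matrix construction and macro-averaged multiclass metrics.

Accuracy is trace over grand total.  Precision and recall are computed
one-vs-rest per class and averaged without class weighting (macro averaging);
the F1 score is the harmonic mean of the *macro* precision and *macro* recall,
not the mean of per-class F1 values.  This aggregation convention is the one
that reproduces the published evaluation figures exactly, and it is the only
simple convention that does (mean-of-per-class-F1 disagrees in the second
decimal on the reference matrix).

Zero-division convention: a class that is never predicted gets precision 0 and
a class with zero support gets recall 0; both are reported with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "accuracy",
    "macro_precision",
    "macro_recall",
    "f1_from_macros",
    "report",
    "percent",
]


class EmptyMatrixError(ValueError):
    """Raised when a metric is requested from an empty confusion matrix."""


@dataclass
class ConfusionMatrix:
    """K x K integer counts; rows are true classes, columns predictions."""

    counts: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be nonnegative")
        if not self.class_names:
            self.class_names = [f"class_{i}" for i in range(self.counts.shape[0])]
        if len(self.class_names) != self.counts.shape[0]:
            raise ValueError("class_names length must match matrix order")

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def one_vs_rest(self, i: int) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) readout of the grid for class ``i``."""
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum() - tp)
        fn = int(self.counts[i, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, tn, fn

    def to_csv(self, path) -> None:
        pd.DataFrame(self.counts, index=self.class_names, columns=self.class_names).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(), class_names=[str(c) for c in df.columns])


def confusion(true_labels, predicted_labels, k: int, class_names=None) -> ConfusionMatrix:
    """Count (true, predicted) pairs into a K x K grid."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("label lists must have equal length")
    for name, arr in (("true", t), ("predicted", p)):
        bad = arr[(arr < 0) | (arr >= k)]
        if bad.size:
            raise ValueError(f"{name} label {int(bad[0])} outside 0..{k - 1}")
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts, class_names=list(class_names or []))


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise EmptyMatrixError("accuracy undefined for an empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def _per_class(cm: ConfusionMatrix, kind: str) -> np.ndarray:
    if cm.total == 0:
        raise EmptyMatrixError(f"{kind} undefined for an empty confusion matrix")
    tp = np.diag(cm.counts).astype(float)
    denom = cm.counts.sum(axis=0 if kind == "precision" else 1).astype(float)
    out = np.zeros(cm.k)
    zero = denom == 0
    if zero.any():
        which = [cm.class_names[i] for i in np.flatnonzero(zero)]
        noun = "never predicted" if kind == "precision" else "with zero support"
        warnings.warn(f"{kind} set to 0 for class(es) {which} ({noun})", stacklevel=3)
    out[~zero] = tp[~zero] / denom[~zero]
    return out


def per_class_precision(cm: ConfusionMatrix) -> np.ndarray:
    return _per_class(cm, "precision")


def per_class_recall(cm: ConfusionMatrix) -> np.ndarray:
    return _per_class(cm, "recall")


def macro_precision(cm: ConfusionMatrix) -> float:
    return float(per_class_precision(cm).mean())


def macro_recall(cm: ConfusionMatrix) -> float:
    return float(per_class_recall(cm).mean())


def f1_from_macros(macro_pr: float, macro_re: float) -> float:
    """Harmonic mean of the macro-averaged precision and recall."""
    if macro_pr + macro_re == 0:
        return 0.0
    return 2.0 * macro_pr * macro_re / (macro_pr + macro_re)


@dataclass
class MetricsReport:
    accuracy: float
    per_class_precision: list[float]
    per_class_recall: list[float]
    per_class_f1: list[float]
    macro_precision: float
    macro_recall: float
    f1: float
    class_names: list[str] = field(default_factory=list)

    def as_percentages(self, decimals: int = 2) -> dict[str, float]:
        """Headline metrics as half-up-rounded percentages."""
        return {
            "accuracy": percent(self.accuracy, decimals),
            "precision": percent(self.macro_precision, decimals),
            "recall": percent(self.macro_recall, decimals),
            "f1": percent(self.f1, decimals),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def percent(fraction: float, decimals: int = 2) -> float:
    """Fraction -> percentage rounded half-up to ``decimals`` places."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(fraction * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


def report(cm: ConfusionMatrix) -> MetricsReport:
    """Bundle accuracy, macro precision/recall and the harmonic F1."""
    pr = per_class_precision(cm)
    re = per_class_recall(cm)
    with np.errstate(invalid="ignore"):
        f1c = np.where(pr + re > 0, 2 * pr * re / np.where(pr + re > 0, pr + re, 1.0), 0.0)
    mp, mr = float(pr.mean()), float(re.mean())
    return MetricsReport(
        accuracy=accuracy(cm),
        per_class_precision=[float(v) for v in pr],
        per_class_recall=[float(v) for v in re],
        per_class_f1=[float(v) for v in f1c],
        macro_precision=mp,
        macro_recall=mr,
        f1=f1_from_macros(mp, mr),
        class_names=list(cm.class_names),
    )
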
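"""Multi-class evaluation: confusion matrices, recall/precision/Fβ/G, accuracy.

For each class c the 4x4 confusion matrix (rows = true, columns = predicted,
fixed order CNV, DME, DRUSEN, NORMAL) is reduced one-vs-rest to (TP, FP, FN,
TN) and scored with

    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    Fβ        = (1 + β²)·recall·precision / (β²·recall + precision)
    G         = sqrt(precision · recall)            (geometric mean)

F1 is Fβ at β = 1. Overall accuracy is trace / total — the multi-class
reading of "correctly predicted over total observations". Macro metrics are
unweighted means over the four classes. A zero denominator makes a metric
*undefined*: it is reported as NaN with a flag, never silently zeroed.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .constants import CLASS_ORDER, class_index

__all__ = [
    "ConfusionMatrix",
    "BinaryCounts",
    "ClassMetrics",
    "MetricsReport",
    "confusion",
    "one_vs_rest",
    "class_metrics",
    "f_beta_score",
    "g_measure",
    "overall_accuracy",
    "macro",
    "evaluate",
]


def f_beta_score(recall: float, precision: float, beta: float = 1.0) -> float:
    """Fβ = (1+β²)·R·P / (β²·R + P); β=1 gives the F1 score."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    denom = beta**2 * recall + precision
    if denom == 0:
        return 0.0
    return (1 + beta**2) * recall * precision / denom


def g_measure(recall: float, precision: float) -> float:
    """Geometric mean of precision and recall, sqrt(P·R)."""
    return math.sqrt(precision * recall)


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    """Counts[i, j] = number of samples with true class i predicted as j."""

    counts: np.ndarray  # (4, 4) int
    labels: tuple[str, ...] = CLASS_ORDER

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def percentages(self) -> np.ndarray:
        """The matrix as fractions of the total sample count."""
        return self.counts / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


@dataclasses.dataclass(frozen=True)
class BinaryCounts:
    """One-vs-rest reduction for a single class."""

    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclasses.dataclass(frozen=True)
class ClassMetrics:
    """Recall, precision, Fβ and G for one class; NaN + flag when undefined."""

    recall: float
    precision: float
    f_beta: float
    g_measure: float
    beta: float = 1.0
    defined: bool = True


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    """Full evaluation: confusion matrix, per-class and macro metrics, accuracy."""

    cm: ConfusionMatrix
    per_class: dict[str, ClassMetrics]
    macro_recall: float
    macro_precision: float
    macro_f: float
    macro_g: float
    accuracy: float
    beta: float = 1.0
    defined: bool = True

    def to_frame(self) -> pd.DataFrame:
        """Per-class rows plus a macro row, rounded to 4 dp for printing."""
        rows = []
        for label in self.cm.labels:
            m = self.per_class[label]
            rows.append(
                {
                    "Class": label,
                    "Recall": round(m.recall, 4),
                    "Precision": round(m.precision, 4),
                    "F1-Score" if self.beta == 1.0 else f"F{self.beta}": round(m.f_beta, 4),
                    "G-Measure": round(m.g_measure, 4),
                }
            )
        rows.append(
            {
                "Class": "macro",
                "Recall": round(self.macro_recall, 4),
                "Precision": round(self.macro_precision, 4),
                "F1-Score" if self.beta == 1.0 else f"F{self.beta}": round(self.macro_f, 4),
                "G-Measure": round(self.macro_g, 4),
            }
        )
        return pd.DataFrame(rows)


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Tally a confusion matrix from two equal-length label sequences.

    Labels may be class names or indices into the fixed class order.
    """
    t = list(true_labels)
    p = list(predicted_labels)
    if len(t) == 0:
        raise ValueError("cannot build a confusion matrix from empty inputs")
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} true vs {len(p)} predicted")

    def to_idx(label):
        if isinstance(label, (int, np.integer)):
            if not 0 <= int(label) < len(CLASS_ORDER):
                raise ValueError(f"unknown class index {label}")
            return int(label)
        return class_index(str(label))

    counts = np.zeros((len(CLASS_ORDER), len(CLASS_ORDER)), dtype=int)
    for ti, pi in zip(t, p):
        counts[to_idx(ti), to_idx(pi)] += 1
    return ConfusionMatrix(counts=counts)


def one_vs_rest(cm: ConfusionMatrix, cls: str) -> BinaryCounts:
    """Reduce the matrix to (TP, FP, FN, TN) for one class."""
    c = class_index(cls)
    counts = cm.counts
    tp = int(counts[c, c])
    fn = int(counts[c].sum() - tp)
    fp = int(counts[:, c].sum() - tp)
    tn = int(counts.sum() - tp - fn - fp)
    return BinaryCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def class_metrics(bc: BinaryCounts, beta: float = 1.0) -> ClassMetrics:
    """Recall, precision, Fβ and G-measure from one-vs-rest counts.

    If TP+FN or TP+FP is zero the affected metrics are undefined: NaN with
    ``defined=False``.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if bc.TP + bc.FN == 0 or bc.TP + bc.FP == 0:
        nan = float("nan")
        return ClassMetrics(nan, nan, nan, nan, beta=beta, defined=False)
    recall = bc.TP / (bc.TP + bc.FN)
    precision = bc.TP / (bc.TP + bc.FP)
    return ClassMetrics(
        recall,
        precision,
        f_beta_score(recall, precision, beta),
        g_measure(recall, precision),
        beta=beta,
    )


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Correctly predicted over total observations: trace / total."""
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / total


def macro(per_class: dict[str, ClassMetrics] | list[ClassMetrics]) -> ClassMetrics:
    """Unweighted mean of per-class metrics; undefined if any input is."""
    values = list(per_class.values()) if isinstance(per_class, dict) else list(per_class)
    if not values:
        raise ValueError("no per-class metrics to average")
    beta = values[0].beta
    if any(not m.defined for m in values):
        nan = float("nan")
        return ClassMetrics(nan, nan, nan, nan, beta=beta, defined=False)
    n = len(values)
    return ClassMetrics(
        recall=sum(m.recall for m in values) / n,
        precision=sum(m.precision for m in values) / n,
        f_beta=sum(m.f_beta for m in values) / n,
        g_measure=sum(m.g_measure for m in values) / n,
        beta=beta,
    )


def evaluate(true_labels, predicted_labels, beta: float = 1.0) -> MetricsReport:
    """Full evaluation of a labelled prediction run."""
    cm = confusion(true_labels, predicted_labels)
    per_class = {
        label: class_metrics(one_vs_rest(cm, label), beta=beta) for label in cm.labels
    }
    mac = macro(per_class)
    return MetricsReport(
        cm=cm,
        per_class=per_class,
        macro_recall=mac.recall,
        macro_precision=mac.precision,
        macro_f=mac.f_beta,
        macro_g=mac.g_measure,
        accuracy=overall_accuracy(cm),
        beta=beta,
        defined=mac.defined,
    )
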
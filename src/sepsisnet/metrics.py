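"""Confusion counts, the percent-scale metric suite, and rank-based AUC.

All ratio metrics are reported in percent (full precision retained; display
rounding is the caller's concern).  Identities that hold on every report:
specificity + FPR = 100, recall + FNR = 100, and F1 is the exact harmonic
mean of precision and recall.  Undefined ratios (zero denominator) are
reported as NaN with a warning, never silently as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "compute_metrics",
    "normalized_confusion",
    "roc_auc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The standard binary-classification panel, percent scale (AUC in [0,1])."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float
    fpr: float
    fnr: float
    auc: float
    counts: ConfusionCounts

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "specificity": self.specificity,
            "fpr": self.fpr,
            "fnr": self.fnr,
            "auc": self.auc,
        }

    def __str__(self) -> str:
        rows = [f"{k:>12}: {v:6.1f}%" for k, v in self.as_dict().items() if k != "auc"]
        rows.append(f"{'auc':>12}: {self.auc:6.3f}")
        return "\n".join(rows)


def confusion_counts(probabilities, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Tally TP/FP/TN/FN at the decision threshold."""
    p = np.asarray(probabilities, dtype=float).reshape(-1)
    y = np.asarray(labels, dtype=int).reshape(-1)
    if p.shape != y.shape:
        raise ValueError(f"{p.shape} probabilities vs {y.shape} labels")
    pred = p >= threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _ratio(numerator: int, denominator: int, name: str) -> float:
    if denominator == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN",
                      stacklevel=3)
        return float("nan")
    return 100.0 * numerator / denominator


def compute_metrics(counts: ConfusionCounts, auc: float = float("nan")) -> MetricsReport:
    """Derive the full metric panel from counts (+ externally computed AUC)."""
    accuracy = _ratio(counts.tp + counts.tn, counts.total, "accuracy")
    precision = _ratio(counts.tp, counts.tp + counts.fp, "precision")
    recall = _ratio(counts.tp, counts.tp + counts.fn, "recall")
    specificity = _ratio(counts.tn, counts.tn + counts.fp, "specificity")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
        if precision + recall == 0 and not (np.isnan(precision) or np.isnan(recall)):
            warnings.warn("F1 undefined (precision + recall = 0); reported as NaN",
                          stacklevel=2)
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        specificity=specificity,
        fpr=100.0 - specificity,
        fnr=100.0 - recall,
        auc=float(auc),
        counts=counts,
    )


def normalized_confusion(counts: ConfusionCounts) -> np.ndarray:
    """Row-normalized 2x2 matrix in percent; rows = true class (neg, pos),
    columns = predicted class (neg, pos); each row sums to 100."""
    rows = np.array(
        [[counts.tn, counts.fp], [counts.fn, counts.tp]], dtype=float
    )
    sums = rows.sum(axis=1, keepdims=True)
    if (sums == 0).any():
        warnings.warn("empty true class; its row reported as NaN", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        return 100.0 * rows / sums


def roc_auc(probabilities, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic:
    P(score_pos > score_neg) + 0.5 P(tie)."""
    p = np.asarray(probabilities, dtype=float).reshape(-1)
    y = np.asarray(labels, dtype=int).reshape(-1)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUC undefined with a single class; reported as NaN",
                      stacklevel=2)
        return float("nan")
    ranks = rankdata(p)  # average ranks handle ties as half-wins
    pos_rank_sum = ranks[y == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))
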
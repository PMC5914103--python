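"""Confusion-matrix metrics for imbalanced two-class problems.

The confusion layout follows the abnormal-as-positive orientation:

====================  =====================  ===================
..                    predicted abnormal     predicted normal
====================  =====================  ===================
actually abnormal     TA (true abnormal)     FN (false normal)
actually normal       FA (false abnormal)    TN (true normal)
====================  =====================  ===================

Accuracy is a poor yardstick under heavy imbalance — predicting "normal"
for everyone on a 260/10,923 cohort already scores 97.68% — so the module
provides recall, f-measure, g-mean, and a balanced-accuracy AUC estimate
computed from hard labels.  Degenerate cases (no predicted abnormal, no
true abnormal) return 0 rather than raising, so downstream ranking never
crashes; g-mean and the AUC estimate do require both classes to be present
in the truth, since they are undefined otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import NamedTuple

import numpy as np
from sklearn.metrics import roc_auc_score

from .io_data import ABNORMAL, NORMAL


class ConfusionCounts(NamedTuple):
    """The four confusion cells, abnormal = positive."""

    TA: int
    FN: int
    FA: int
    TN: int

    @property
    def total(self) -> int:
        return self.TA + self.FN + self.FA + self.TN


@dataclass(frozen=True)
class MetricConfig:
    """delta weights recall against precision in the f-measure (default 1)."""

    delta: float = 1.0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Count the four confusion cells from 1/0 (abnormal/normal) label vectors."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        bad = set(np.unique(arr)) - {ABNORMAL, NORMAL}
        if bad:
            raise ValueError(f"{name} contains non-binary labels {sorted(bad)}")
    return ConfusionCounts(
        TA=int(np.sum((y_true == ABNORMAL) & (y_pred == ABNORMAL))),
        FN=int(np.sum((y_true == ABNORMAL) & (y_pred == NORMAL))),
        FA=int(np.sum((y_true == NORMAL) & (y_pred == ABNORMAL))),
        TN=int(np.sum((y_true == NORMAL) & (y_pred == NORMAL))),
    )


def accuracy(c: ConfusionCounts) -> float:
    """(TA + TN) / total."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    return (c.TA + c.TN) / c.total


def precision_recall(c: ConfusionCounts) -> tuple[float, float]:
    """Abnormal-class precision TA/(TA+FA) and recall TA/(TA+FN); 0 on empty denominators."""
    precision = c.TA / (c.TA + c.FA) if (c.TA + c.FA) > 0 else 0.0
    recall = c.TA / (c.TA + c.FN) if (c.TA + c.FN) > 0 else 0.0
    return precision, recall


def f_measure(c: ConfusionCounts, cfg: MetricConfig = MetricConfig()) -> float:
    """Weighted harmonic mean of precision and recall; 0 when both vanish."""
    precision, recall = precision_recall(c)
    d2 = cfg.delta**2
    denom = d2 * recall + precision
    if denom == 0:
        return 0.0
    return (1 + d2) * recall * precision / denom


def g_mean(c: ConfusionCounts) -> float:
    """Geometric mean of the abnormal-class and normal-class recalls."""
    if c.TA + c.FN == 0 or c.TN + c.FA == 0:
        raise ValueError("g-mean is undefined when a true class is absent")
    recall_abnormal = c.TA / (c.TA + c.FN)
    recall_normal = c.TN / (c.TN + c.FA)
    return sqrt(recall_abnormal * recall_normal)


def auc_estimate(c: ConfusionCounts) -> float:
    """Balanced-accuracy AUC estimate from hard labels: mean of the two class recalls.

    This is the estimator used for all reported comparisons; a score-based
    ROC AUC is available separately as :func:`auc_from_scores` but never
    substitutes for this one.
    """
    if c.TA + c.FN == 0 or c.TN + c.FA == 0:
        raise ValueError("AUC estimate is undefined when a true class is absent")
    recall_abnormal = c.TA / (c.TA + c.FN)
    recall_normal = c.TN / (c.TN + c.FA)
    return (recall_abnormal + recall_normal) / 2


def auc_from_scores(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Score-based (trapezoidal ROC) AUC, for diagnostics only."""
    return float(roc_auc_score(np.asarray(y_true, dtype=int), np.asarray(scores, dtype=float)))


def compute_all(
    y_true: np.ndarray, y_pred: np.ndarray, cfg: MetricConfig = MetricConfig()
) -> dict[str, float]:
    """All standard metrics from hard predictions, keyed by short name."""
    c = confusion(y_true, y_pred)
    precision, recall = precision_recall(c)
    out = {
        "accuracy": accuracy(c),
        "precision": precision,
        "recall": recall,
        "f_measure": f_measure(c, cfg),
    }
    if c.TA + c.FN > 0 and c.TN + c.FA > 0:
        out["g_mean"] = g_mean(c)
        out["auc"] = auc_estimate(c)
    else:
        out["g_mean"] = float("nan")
        out["auc"] = float("nan")
    return out
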
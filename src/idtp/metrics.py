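"""Confusion counts and PU evaluation metrics.

Scoring follows the PU convention throughout: the labeled positives
(known drug targets) are the +1 class and every unlabeled record is
scored as -1, so "errors" against unlabeled rows may in truth be
correctly recovered hidden positives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .feature_table import POSITIVE


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with the drug-target (positive) class as +1."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise MetricError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    @classmethod
    def from_predictions(cls, y_true_pm: Sequence[int], y_pred_pm: Sequence[int]) -> "ConfusionCounts":
        t = np.asarray(y_true_pm)
        p = np.asarray(y_pred_pm)
        if t.shape != p.shape:
            raise MetricError(f"length mismatch: {t.shape} vs {p.shape}")
        return cls(
            TP=int(np.sum((t == 1) & (p == 1))),
            FP=int(np.sum((t == -1) & (p == 1))),
            FN=int(np.sum((t == 1) & (p == -1))),
            TN=int(np.sum((t == -1) & (p == -1))),
        )


def fbeta(counts: ConfusionCounts, beta: float = 1.0) -> float:
    """F-beta of the positive class.

    F_beta = (1 + beta^2) * P * R / (beta^2 * P + R) with
    P = TP/(TP+FP), R = TP/(TP+FN).  Returns 0 when the positive class
    is entirely missed (TP = 0 with FP or FN positive); the fully
    degenerate all-zero case returns 0 with a warning.
    """
    if beta <= 0:
        raise MetricError(f"beta must be positive, got {beta}")
    TP, FP, FN = counts.TP, counts.FP, counts.FN
    if TP == 0:
        if FP == 0 and FN == 0:
            warnings.warn("F-beta undefined: no positive predictions or labels", stacklevel=2)
        return 0.0
    precision = TP / (TP + FP)
    recall = TP / (TP + FN)
    b2 = beta * beta
    return (1.0 + b2) * precision * recall / (b2 * precision + recall)


def evaluate(y_observed: Sequence[str], y_pred_pm: Sequence[int]) -> dict[str, float]:
    """PU metrics of one prediction against observed labels.

    ``y_observed`` carries "positive"/"unlabeled" strings; predictions
    are +/-1.  Returns the F1 and recall of the positive (drug-target)
    class and the precision of the negative (non-target) class, along
    with the underlying counts.
    """
    obs = np.asarray(y_observed)
    pred = np.asarray(y_pred_pm)
    if obs.shape != pred.shape:
        raise MetricError(f"length mismatch: {obs.shape} vs {pred.shape}")
    y_true = np.where(obs == POSITIVE, 1, -1)
    counts = ConfusionCounts.from_predictions(y_true, pred)
    recall_dtp = counts.TP / (counts.TP + counts.FN) if (counts.TP + counts.FN) else 0.0
    precision_ndtp = counts.TN / (counts.TN + counts.FN) if (counts.TN + counts.FN) else 0.0
    return {
        "f1_dtp": fbeta(counts, beta=1.0),
        "recall_dtp": recall_dtp,
        "precision_ndtp": precision_ndtp,
        "counts": counts,
    }


def f1_positive(y_true_pm: Sequence[int], y_pred_pm: Sequence[int]) -> float:
    """F1 of the +1 class from +/-1 label vectors."""
    return fbeta(ConfusionCounts.from_predictions(y_true_pm, y_pred_pm), beta=1.0)
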
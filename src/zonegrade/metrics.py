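"""ROC AUC and operating-point metrics, plus cross-validation aggregation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "EvaluationResult",
    "roc_auc",
    "confusion_metrics",
    "mean_over_folds",
]


@dataclass(frozen=True)
class EvaluationResult:
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic.

    Equals the probability that a random positive outscores a random
    negative, with ties credited 1/2. Computed from midranks, which is
    algebraically identical to the all-pairs count.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores, method="average")
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def confusion_metrics(preds, labels) -> EvaluationResult:
    """Accuracy, sensitivity and specificity from binary predictions.

    A metric whose denominator is empty (e.g. sensitivity with no
    positives) is reported as NaN rather than silently 0; stratified folds
    normally prevent this. AUC is not computable from hard predictions and
    is NaN here.
    """
    preds = np.asarray(preds).astype(int)
    labels = np.asarray(labels).astype(int)
    if preds.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    tp = int(np.sum((preds == 1) & (labels == 1)))
    fp = int(np.sum((preds == 1) & (labels == 0)))
    tn = int(np.sum((preds == 0) & (labels == 0)))
    fn = int(np.sum((preds == 0) & (labels == 1)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / preds.size
    return EvaluationResult(auc=float("nan"), accuracy=acc, sensitivity=sens,
                            specificity=spec, tp=tp, fp=fp, tn=tn, fn=fn)


def mean_over_folds(per_fold: list[EvaluationResult]) -> EvaluationResult:
    """Arithmetic mean of each metric over cross-validation folds."""
    if not per_fold:
        raise ValueError("no fold results to aggregate")
    return EvaluationResult(
        auc=float(np.mean([r.auc for r in per_fold])),
        accuracy=float(np.mean([r.accuracy for r in per_fold])),
        sensitivity=float(np.mean([r.sensitivity for r in per_fold])),
        specificity=float(np.mean([r.specificity for r in per_fold])),
        tp=sum(r.tp for r in per_fold), fp=sum(r.fp for r in per_fold),
        tn=sum(r.tn for r in per_fold), fn=sum(r.fn for r in per_fold),
    )
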
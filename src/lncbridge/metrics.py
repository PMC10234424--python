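"""Binary-classification metrics for link-prediction evaluation.

Threshold metrics (accuracy, sensitivity, specificity, precision, F1, MCC)
are computed from an explicit confusion count; a metric whose denominator is
zero is reported as NaN with a warning rather than silently coerced to 0.
Specificity is TN/(TN+FP), the standard definition.  Ranking metrics (ROC
AUC, precision-recall AUC) are threshold-free; ROC AUC equals the normalized
Mann-Whitney U statistic with ties counted one half.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ["acc", "sen", "spec", "prec", "f1", "mcc", "auc", "aupr"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Tally a confusion table; a score equal to the threshold predicts 1."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != scores.shape:
        raise ValueError("labels and scores differ in length")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("metric %s undefined (zero denominator)", name)
        return math.nan
    return num / den


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, precision, F1 and MCC from counts."""
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    acc = _ratio(tp + tn, c.total, "acc")
    sen = _ratio(tp, tp + fn, "sen")
    spec = _ratio(tn, tn + fp, "spec")
    prec = _ratio(tp, tp + fp, "prec")
    if math.isnan(prec) or math.isnan(sen) or prec + sen == 0:
        logger.warning("metric f1 undefined")
        f1 = math.nan
    else:
        f1 = 2 * prec * sen / (prec + sen)
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, denom, "mcc")
    return {"acc": acc, "sen": sen, "spec": spec, "prec": prec, "f1": f1, "mcc": mcc}


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("ranking metrics need both classes present")


def roc_auc(labels, scores) -> float:
    """Area under the ROC curve (Mann-Whitney normalization, ties as 1/2)."""
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pr_auc(labels, scores) -> float:
    """Area under the precision-recall curve by monotone step summation."""
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def evaluate(labels, scores, threshold: float = 0.5) -> dict[str, float]:
    """All eight metrics of one evaluation fold."""
    out = classification_metrics(confusion(labels, scores, threshold))
    out["auc"] = roc_auc(labels, scores)
    out["aupr"] = pr_auc(labels, scores)
    return out
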
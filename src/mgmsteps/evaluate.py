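"""Edge-recovery evaluation: confusion counts and the usual binary metrics.

Predicted and true graphs are compared over the universe of unordered node
pairs, overall or restricted to one edge type (cc, cd, dd).  Metrics with a
degenerate zero denominator are reported as 0 and flagged so that averages
over many datasets stay defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import edge_type_masks

__all__ = ["EdgeConfusion", "edge_confusion", "recovery_metrics"]


@dataclass
class EdgeConfusion:
    tp: int
    fp: int
    fn: int
    tn: int
    edge_type: str = "all"

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def edge_confusion(predicted: np.ndarray, truth: np.ndarray, p: int, q: int,
                   edge_type: str = "all") -> EdgeConfusion:
    """Count TP/FP/FN/TN over unordered node pairs of the given edge type.

    ``predicted`` and ``truth`` are symmetric boolean ``(p+q, p+q)``
    adjacency matrices with continuous nodes first.
    """
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    P = p + q
    if predicted.shape != (P, P) or truth.shape != (P, P):
        raise ValueError("adjacency shape does not match p + q")
    mask = edge_type_masks(p, q)[edge_type]
    pred = predicted[mask]
    true = truth[mask]
    tp = int(np.sum(pred & true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    tn = int(np.sum(~pred & ~true))
    return EdgeConfusion(tp, fp, fn, tn, edge_type)


def recovery_metrics(conf: EdgeConfusion) -> dict:
    """Precision, recall, F1, accuracy and Matthews correlation.

    ``MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``.  Any
    metric whose denominator is 0 is reported as 0 with the ``degenerate``
    flag listing the affected metrics.
    """
    tp, fp, fn, tn = conf.tp, conf.fp, conf.fn, conf.tn
    degenerate = []

    def ratio(num, den, name):
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    f1 = ratio(2 * precision * recall, precision + recall, "f1") \
        if (precision + recall) > 0 else (degenerate.append("f1") or 0.0)
    accuracy = ratio(tp + tn, conf.total, "accuracy")
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den == 0:
        degenerate.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(den)
    return {"precision": precision, "recall": recall, "f1": f1,
            "accuracy": accuracy, "mcc": mcc, "degenerate": degenerate}
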
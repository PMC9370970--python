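"""Confusion-matrix bookkeeping and binary-classification metrics.

The irregular class is the positive class: TP counts irregular objects
correctly flagged, FP regular objects wrongly flagged, FN irregular objects
missed, TN regular objects passed.

Accuracy = (TP+TN)/total, Precision = TP/(TP+FP), Recall = TP/(TP+FN),
F1 = 2PR/(P+R).  Graded sets are typically imbalanced (far more regular
produce than irregular), so precision/recall/F1 are the primary metrics and
accuracy is reported as secondary.  Zero-denominator cases yield ``None``
rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .classify import Label


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be nonnegative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Metrics:
    accuracy: Optional[float]
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1}


def confusion(pred: Sequence[Label | str], truth: Sequence[Label | str]) -> ConfusionMatrix:
    """Count TP/FP/FN/TN with irregular as the positive class."""
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(truth)} truths")
    if len(pred) == 0:
        raise ValueError("need at least one sample")
    tp = fp = fn = tn = 0
    for p, t in zip(pred, truth):
        p_pos = Label(p) is Label.IRREGULAR
        t_pos = Label(t) is Label.IRREGULAR
        if p_pos and t_pos:
            tp += 1
        elif p_pos:
            fp += 1
        elif t_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics(cm: ConfusionMatrix) -> Metrics:
    """Accuracy, precision, recall and F1 from a confusion matrix."""
    accuracy = (cm.tp + cm.tn) / cm.total
    precision = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp > 0 else None
    recall = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return Metrics(accuracy=accuracy, precision=precision, recall=recall, f1=f1)
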
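"""Binary-classification fitness measures.

Four measures drive the GA wrapper selection: accuracy, Matthews
correlation coefficient (MCC), F1 and a "hybrid" score defined as
sensitivity + delta * specificity where delta is the positive/negative
class ratio.  All are pure functions of a confusion table.

Degenerate margins (a zero row or column of the confusion table, which
one-class predictions produce) follow the usual conventions: MCC -> 0,
F1 -> 0, and undefined sensitivity/specificity terms contribute 0.  This
keeps every chromosome's fitness finite and totally ordered.
"""

from __future__ import annotations

import math

from .datatypes import ClassBalance, ConfusionCounts

__all__ = ["accuracy", "mcc", "f1", "hybrid", "sensitivity", "specificity", "precision"]


def accuracy(cc: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    return (cc.tp + cc.tn) / cc.total


def sensitivity(cc: ConfusionCounts) -> float:
    """TP / (TP + FN); 0 when there are no positives."""
    return cc.tp / (cc.tp + cc.fn) if cc.tp + cc.fn else 0.0


def specificity(cc: ConfusionCounts) -> float:
    """TN / (TN + FP); 0 when there are no negatives."""
    return cc.tn / (cc.tn + cc.fp) if cc.tn + cc.fp else 0.0


def precision(cc: ConfusionCounts) -> float:
    """TP / (TP + FP); 0 when nothing is predicted positive."""
    return cc.tp / (cc.tp + cc.fp) if cc.tp + cc.fp else 0.0


def mcc(cc: ConfusionCounts) -> float:
    """Matthews correlation coefficient.

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), which equals the
    Pearson correlation of the binary truth and prediction vectors.
    Returns 0 when any marginal factor is zero.
    """
    denom = (
        (cc.tp + cc.fp) * (cc.tp + cc.fn) * (cc.tn + cc.fp) * (cc.tn + cc.fn)
    )
    if denom == 0:
        return 0.0
    return (cc.tp * cc.tn - cc.fp * cc.fn) / math.sqrt(denom)


def f1(cc: ConfusionCounts) -> float:
    """Harmonic mean of precision and sensitivity; 0 when undefined."""
    p, s = precision(cc), sensitivity(cc)
    if p + s == 0:
        return 0.0
    return 2.0 * p * s / (p + s)


def hybrid(cc: ConfusionCounts, balance: ClassBalance) -> float:
    """Sensitivity + delta * specificity, delta = n_pos / n_neg.

    Ranges over [0, 1 + delta]; rewards sensitivity on the (larger)
    positive class while weighting specificity by the class imbalance.
    """
    return sensitivity(cc) + balance.delta * specificity(cc)
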
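"""Confusion-matrix metrics and the weighted-accuracy fitness.

The positive class is hypoglycemia throughout.  The training fitness is
``1 - WA`` with ``WA = 0.5*Accuracy + 0.5*F1``, a standard way to score
rule classifiers on imbalanced data without a continuous output: accuracy
rewards both classes while F1 keeps the minority (hypoglycemia) class from
being ignored.  TPR and TNR are the per-class recalls used for reporting.

Undefined ratios (a denominator class that is empty) are reported as NaN,
except F1 which is defined as 0 when precision + recall is 0 so that the
fitness of degenerate individuals stays finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["MetricsReport", "confusion", "weighted_accuracy"]


@dataclass
class MetricsReport:
    truePositives: int
    falsePositives: int
    trueNegatives: int
    falseNegatives: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    wa: float
    fitness: float
    tpr: float
    tnr: float

    @property
    def n(self) -> int:
        return (
            self.truePositives
            + self.falsePositives
            + self.trueNegatives
            + self.falseNegatives
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _ratio(num: int, den: int) -> float:
    return num / den if den else math.nan


def confusion(labels, predictions) -> MetricsReport:
    """Full metrics report from binary labels and predictions.

    ``labels`` and ``predictions`` are equal-length boolean sequences with
    True meaning hypoglycemia.
    """
    y = np.asarray(labels, dtype=bool)
    p = np.asarray(predictions, dtype=bool)
    if y.shape != p.shape:
        raise ValueError(
            f"length mismatch: {y.shape[0]} labels vs {p.shape[0]} predictions"
        )
    if y.size == 0:
        raise ValueError("empty input")
    tp = int(np.count_nonzero(y & p))
    fp = int(np.count_nonzero(~y & p))
    tn = int(np.count_nonzero(~y & ~p))
    fn = int(np.count_nonzero(y & ~p))

    accuracy = (tp + tn) / y.size
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    # F1 with the degenerate-classifier convention: no true positives -> 0.
    if tp == 0:
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    wa = weighted_accuracy(accuracy, f1)
    return MetricsReport(
        truePositives=tp,
        falsePositives=fp,
        trueNegatives=tn,
        falseNegatives=fn,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        wa=wa,
        fitness=1.0 - wa,
        tpr=_ratio(tp, tp + fn),
        tnr=_ratio(tn, tn + fp),
    )


def weighted_accuracy(acc: float, f1: float) -> float:
    """WA = 0.5*Accuracy + 0.5*F1, the quantity the fitness maximises."""
    if not (0.0 <= acc <= 1.0) or not (0.0 <= f1 <= 1.0):
        raise ValueError(f"accuracy and F1 must be in [0,1], got {acc}, {f1}")
    return 0.5 * acc + 0.5 * f1
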
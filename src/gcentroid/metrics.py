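"""Evaluation measures over binary predictions versus references.

Counts run componentwise over the full base index set of the space — for
alignments every cell of the |x| x |y| grid, for structures every i < j
pair — so TP + TN + FP + FN always equals the space dimension.  All
zero-denominator score terms are defined as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .spaces import BinaryPrediction

__all__ = ["ConfusionCounts", "confusion", "scores"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def dimension(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(pred: BinaryPrediction, ref: BinaryPrediction) -> ConfusionCounts:
    """Componentwise TP/TN/FP/FN of a prediction against a reference."""
    if pred.dimension != ref.dimension:
        raise ValueError(
            f"dimension mismatch: prediction {pred.dimension}, "
            f"reference {ref.dimension}"
        )
    tp = len(pred.on_indices & ref.on_indices)
    fp = len(pred.on_indices) - tp
    fn = len(ref.on_indices) - tp
    tn = pred.dimension - tp - fp - fn
    return ConfusionCounts(tp, tn, fp, fn)


def scores(c: ConfusionCounts) -> dict:
    """SEN, PPV, MCC and F-score with 0/0 terms defined as 0."""
    sen = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    ppv = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    f = 2 * sen * ppv / (sen + ppv) if sen + ppv else 0.0
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = (
        (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom else 0.0
    )
    return {"SEN": sen, "PPV": ppv, "MCC": mcc, "F": f}
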
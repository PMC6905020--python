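"""Confusion counts and the Sn / Sp / Acc / MCC performance measures.

Sn = TP/(TP+FN) x 100, Sp = TN/(TN+FP) x 100, Acc = (TP+TN)/total x 100,
MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

When any MCC denominator factor is zero the MCC is reported as 0 (common
convention for degenerate confusion tables); an Sn or Sp whose denominator
is zero is reported as missing (None).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ParameterError("confusion counts must be nonnegative")

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        """Labels are +1/-1 (positive = binding residue)."""
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos = y_true > 0
        return cls(
            tp=int(np.sum(pos & (y_pred > 0))),
            fn=int(np.sum(pos & (y_pred <= 0))),
            tn=int(np.sum(~pos & (y_pred <= 0))),
            fp=int(np.sum(~pos & (y_pred > 0))),
        )

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fn + other.fn, self.tn + other.tn, self.fp + other.fp
        )

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class Metrics:
    sn: float | None
    sp: float | None
    acc: float
    mcc: float

    def to_dict(self) -> dict:
        return {"sn": self.sn, "sp": self.sp, "acc": self.acc, "mcc": self.mcc}


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    tp, fn, tn, fp = counts.tp, counts.fn, counts.tn, counts.fp
    if counts.total == 0:
        raise ParameterError("empty confusion table")
    sn = 100.0 * tp / (tp + fn) if tp + fn > 0 else None
    sp = 100.0 * tn / (tn + fp) if tn + fp > 0 else None
    acc = 100.0 * (tp + tn) / counts.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        logger.warning("MCC denominator factor is zero; MCC reported as 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return Metrics(sn=sn, sp=sp, acc=acc, mcc=mcc)


def mean_metrics(entries: list[Metrics]) -> Metrics:
    """Arithmetic mean of a list of metric sets (missing values propagate as None)."""
    if not entries:
        raise ParameterError("nothing to average")

    def avg(vals):
        vals = [v for v in vals]
        return None if any(v is None for v in vals) else float(np.mean(vals))

    return Metrics(
        sn=avg([m.sn for m in entries]),
        sp=avg([m.sp for m in entries]),
        acc=float(np.mean([m.acc for m in entries])),
        mcc=float(np.mean([m.mcc for m in entries])),
    )
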
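"""Binary PVC classification metrics.

The positive class is PVC (V).  Metrics: accuracy, positive predictive
value, sensitivity, specificity, and Youden's index
gamma = Se + Sp - 1, a prevalence-robust summary.  A metric whose
denominator is zero is reported as NaN (with a warning) rather than 0, so
averages are never silently inflated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "MetricSet", "confusion", "metrics"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    acc: float
    ppv: float
    se: float
    sp: float
    gamma: float

    def as_dict(self) -> dict[str, float]:
        return {"Acc": self.acc, "PPV": self.ppv, "Se": self.se,
                "Sp": self.sp, "gamma": self.gamma}


def confusion(true_labels: np.ndarray, predicted_labels: np.ndarray) -> ConfusionCounts:
    """Tally the 2x2 confusion matrix (positive = PVC = truthy label)."""
    t = np.asarray(true_labels).astype(bool)
    p = np.asarray(predicted_labels).astype(bool)
    if t.shape != p.shape:
        raise ValueError(f"label length mismatch: {t.shape} vs {p.shape}")
    if t.size == 0:
        raise ValueError("empty label sequences")
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return float("nan")
    return num / den


def metrics(c: ConfusionCounts) -> MetricSet:
    """Acc, PPV, Se, Sp and gamma = Se + Sp - 1 from confusion counts."""
    if c.total == 0:
        raise ValueError("confusion counts are all zero")
    acc = (c.tp + c.tn) / c.total
    ppv = _ratio(c.tp, c.tp + c.fp, "PPV")
    se = _ratio(c.tp, c.tp + c.fn, "Se")
    sp = _ratio(c.tn, c.tn + c.fp, "Sp")
    return MetricSet(acc=acc, ppv=ppv, se=se, sp=sp, gamma=se + sp - 1.0)
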
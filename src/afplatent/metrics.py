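"""Threshold-dependent evaluation suite for imbalanced binary classification.

Sensitivity, specificity, accuracy, precision, MCC, balanced accuracy,
Youden's index and F1 score, all derived from the TP/FP/TN/FN tallies with
the antifreeze-protein (positive) class as reference.  Balanced accuracy,
Youden's index and MCC are emphasized because the natural AFP test sets are
heavily skewed toward non-AFPs.

Zero-denominator conventions (logged whenever they fire): MCC -> 0 when any
factor under the square root is 0; precision -> 0 when TP + FP = 0;
F1 -> 0 when precision + recall = 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict
from typing import Dict, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN tallies; AFP is the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    balanced_accuracy: float
    youden: float
    mcc: float
    f1: float

    def as_dict(self) -> Dict[str, float]:
        return asdict(self)

    def formatted(self) -> Dict[str, str]:
        """Display rounding: percentages to 1 d.p., indices to 2 d.p."""
        pct = ("sensitivity", "specificity", "accuracy", "precision", "balanced_accuracy")
        return {
            k: (f"{100 * v:.1f}%" if k in pct else f"{v:.2f}")
            for k, v in self.as_dict().items()
        }


def confusion(
    y_true: Sequence, y_pred: Sequence, pos_label=1, neg_label=0
) -> ConfusionCounts:
    """Tally TP/FP/TN/FN with *pos_label* the AFP class.

    Raises on length mismatch or any label outside {pos_label, neg_label}.
    """
    yt, yp = np.asarray(y_true), np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    for arr, name in ((yt, "y_true"), (yp, "y_pred")):
        bad = arr[(arr != pos_label) & (arr != neg_label)]
        if bad.size:
            raise ValueError(f"{name} contains unknown label {bad[0]!r}")
    tp = int(np.sum((yt == pos_label) & (yp == pos_label)))
    fn = int(np.sum((yt == pos_label) & (yp == neg_label)))
    tn = int(np.sum((yt == neg_label) & (yp == neg_label)))
    fp = int(np.sum((yt == neg_label) & (yp == pos_label)))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """All eight metrics from one confusion table.

    Requires both classes to be represented in the truth (TP+FN > 0 and
    TN+FP > 0); sensitivity and specificity are otherwise undefined.
    """
    if c.n_pos == 0 or c.n_neg == 0:
        raise ValueError(
            f"both classes must be present: n_pos={c.n_pos}, n_neg={c.n_neg}"
        )
    tp, fp, tn, fn = float(c.tp), float(c.fp), float(c.tn), float(c.fn)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / (tp + tn + fp + fn)

    if tp + fp == 0:
        logger.info("precision denominator TP+FP = 0; reporting precision = 0")
        prec = 0.0
    else:
        prec = tp / (tp + fp)

    denom = (tp + fp) * (tn + fn) * (tp + fn) * (tn + fp)
    if denom == 0:
        logger.info("MCC denominator has a zero factor; reporting MCC = 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)

    if prec + sens == 0:
        logger.info("F1 denominator precision+recall = 0; reporting F1 = 0")
        f1 = 0.0
    else:
        f1 = 2.0 * prec * sens / (prec + sens)

    bal = (sens + spec) / 2.0
    return MetricsReport(
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        precision=prec,
        balanced_accuracy=bal,
        youden=sens + spec - 1.0,
        mcc=mcc,
        f1=f1,
    )


def metrics_from_rates(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> MetricsReport:
    """Metrics from printed sensitivity/specificity plus class sizes.

    Balanced accuracy, Youden's index, sensitivity and specificity come
    straight from the rates (rounding-free); accuracy, precision, MCC and F1
    require integer tallies, reconstructed as TP = round(sens * n_pos),
    TN = round(spec * n_neg).  Lets published tables be checked for internal
    consistency without the underlying predictions.
    """
    for name, r in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {r}")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("class sizes must be positive")
    tp = round(sensitivity * n_pos)
    tn = round(specificity * n_neg)
    counted = compute_metrics(
        ConfusionCounts(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)
    )
    return MetricsReport(
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=counted.accuracy,
        precision=counted.precision,
        balanced_accuracy=(sensitivity + specificity) / 2.0,
        youden=sensitivity + specificity - 1.0,
        mcc=counted.mcc,
        f1=counted.f1,
    )
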
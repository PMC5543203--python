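"""ROC analysis of Ki-67 against luminal A/B labels and Youden cut selection.

Thresholds are the midpoints between adjacent distinct observed values plus
the two infinities; a case is called positive (luminal B-like) when its value
is strictly above the threshold. The trapezoidal AUC over these points equals
the Mann-Whitney statistic with ties credited 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cut: float


def roc_curve(values, labels) -> ROCResult:
    """ROC of ``values`` against boolean ``labels`` (True = positive class)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be 1-D and equal length")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")

    distinct = np.unique(values)
    thresholds = np.concatenate(
        [[-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]]
    )
    pos = np.sort(values[labels])
    neg = np.sort(values[~labels])
    # P(value > t | positive) and P(value <= t | negative)
    sens = 1.0 - np.searchsorted(pos, thresholds, side="right") / pos.size
    spec = np.searchsorted(neg, thresholds, side="right") / neg.size

    # thresholds ascend, so FPR = 1 - spec descends; integrate in FPR order
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))

    j = sens + spec - 1.0
    youden = float(thresholds[int(np.argmax(j))])  # argmax -> lowest tied threshold
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_cut=youden,
    )


def youden_cutpoint(roc: ROCResult) -> float:
    """Threshold maximizing sensitivity + specificity - 1 (ties -> lower cut)."""
    j = roc.sensitivity + roc.specificity - 1.0
    return float(roc.thresholds[int(np.argmax(j))])


def youden_j_at(roc: ROCResult, cut: float) -> float:
    """Youden's J of the dichotomization at an arbitrary cut value."""
    idx = int(np.searchsorted(roc.thresholds, cut, side="right")) - 1
    idx = max(idx, 0)
    return float(roc.sensitivity[idx] + roc.specificity[idx] - 1.0)
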
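"""Regression and classification metrics for logBB models.

Regression quality is summarized by the coefficient of determination

    R^2 = 1 - sum_i (y_i - yhat_i)^2 / sum_i (y_i - ybar)^2

(about the mean of the *observed* values) and the mean squared error. For
qualitative use, predicted logBB is binarized at the conventional cutoff of
-1: a compound with logBB >= -1 is called BBB-permeable. Classification
quality is reported as accuracy, sensitivity, specificity, MCC, PPV and
NPV; a metric with a zero denominator is reported as absent with a reason,
never silently coerced to 0.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError

PERMEABLE = "permeable"
NONPERMEABLE = "nonpermeable"
LOGBB_CUTOFF = -1.0


@dataclass
class RegressionMetrics:
    r2: float
    mse: float
    n: int


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class ClassificationMetrics:
    """Binary metrics; a None value is undefined, with the reason recorded."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    mcc: float | None
    npv: float | None
    ppv: float | None
    undefined: dict[str, str] = field(default_factory=dict)


def _check_lengths(actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {p.shape}")
    return a, p


def r_squared(actual, predicted) -> float:
    """Coefficient of determination about the mean of the observed values."""
    a, p = _check_lengths(actual, predicted)
    if a.size < 2:
        raise ValueError("need at least 2 observations for R^2")
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateInputError("actual values are constant; R^2 undefined")
    ss_res = float(np.sum((a - p) ** 2))
    return 1.0 - ss_res / ss_tot


def mse(actual, predicted) -> float:
    """Mean squared error."""
    a, p = _check_lengths(actual, predicted)
    if a.size == 0:
        raise ValueError("empty input")
    return float(np.mean((a - p) ** 2))


def regression_metrics(actual, predicted) -> RegressionMetrics:
    a, _ = _check_lengths(actual, predicted)
    return RegressionMetrics(r2=r_squared(actual, predicted), mse=mse(actual, predicted), n=a.size)


def binarize(logbb, cutoff: float = LOGBB_CUTOFF) -> list[str]:
    """Map logBB values to permeability classes: value >= cutoff -> permeable.

    The boundary itself is permeable (logBB >= -1 at the default cutoff).
    """
    values = np.asarray(logbb, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("binarize requires finite logBB values")
    return [PERMEABLE if v >= cutoff else NONPERMEABLE for v in values]


def confusion(actual_labels, predicted_labels) -> ConfusionCounts:
    """Count TP/TN/FP/FN with 'permeable' as the positive class."""
    if len(actual_labels) != len(predicted_labels):
        raise ValueError("label vectors differ in length")
    valid = {PERMEABLE, NONPERMEABLE}
    counts = ConfusionCounts(0, 0, 0, 0)
    for a, p in zip(actual_labels, predicted_labels):
        if a not in valid or p not in valid:
            raise ValueError(f"unknown label in pair ({a!r}, {p!r})")
        if a == PERMEABLE:
            if p == PERMEABLE:
                counts.tp += 1
            else:
                counts.fn += 1
        else:
            if p == PERMEABLE:
                counts.fp += 1
            else:
                counts.tn += 1
    return counts


def classification_metrics(c: ConfusionCounts) -> ClassificationMetrics:
    """Accuracy, sensitivity, specificity, MCC, NPV, PPV from a confusion table.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    PPV = TP/(TP+FP); NPV = TN/(TN+FN); accuracy = (TP+TN)/total;
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    undefined: dict[str, str] = {}

    def ratio(name: str, num: int, denom: int) -> float | None:
        if denom == 0:
            undefined[name] = f"zero denominator ({name})"
            return None
        return num / denom

    accuracy = ratio("accuracy", c.tp + c.tn, c.total)
    sensitivity = ratio("sensitivity", c.tp, c.tp + c.fn)
    specificity = ratio("specificity", c.tn, c.tn + c.fp)
    ppv = ratio("ppv", c.tp, c.tp + c.fp)
    npv = ratio("npv", c.tn, c.tn + c.fn)

    mcc_denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if mcc_denom == 0:
        undefined["mcc"] = "zero denominator (a confusion-table margin is empty)"
        mcc = None
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(mcc_denom)

    return ClassificationMetrics(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        mcc=mcc,
        npv=npv,
        ppv=ppv,
        undefined=undefined,
    )


def metrics_to_dict(m: ClassificationMetrics, c: ConfusionCounts) -> dict:
    """JSON-friendly report combining the confusion table and derived metrics."""
    return {
        "confusion": {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn},
        "accuracy": m.accuracy,
        "sensitivity": m.sensitivity,
        "specificity": m.specificity,
        "mcc": m.mcc,
        "npv": m.npv,
        "ppv": m.ppv,
        "undefined": m.undefined,
    }
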
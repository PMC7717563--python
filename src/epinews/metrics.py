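"""Evaluation metrics for imbalanced two-class problems.

Beyond the usual confusion-count scores (precision, sensitivity,
specificity, F1), this module implements the index balanced accuracy

    IBA_alpha = (1 + alpha * (sensitivity - specificity))
                * sensitivity * specificity

where ``sensitivity - specificity`` is the *dominance* and ``alpha``
(default 0.1) weights how much the dominating class matters.  IBA
rewards classifiers with good true-positive rates on imbalanced data,
where plain accuracy is misleading.

Key-extraction accuracy uses exact matching for disease, country and
count, and an inclusive three-day window for dates (annotators often
return date ranges; a small window absorbs that fuzziness).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_curve

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "UndefinedMetricError",
    "confusion",
    "precision",
    "sensitivity",
    "specificity",
    "f1",
    "iba",
    "evaluate",
    "roc_points",
    "key_extraction_accuracy",
]


class UndefinedMetricError(ZeroDivisionError):
    """A score's denominator is zero, so the score is undefined."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.TP + self.TN + self.FP + self.FN < 1:
            raise ValueError("confusion counts must describe at least one sample")


def confusion(y_true: Sequence, y_pred: Sequence, positive_label) -> ConfusionCounts:
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive_label:
            if p == positive_label:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_label:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        raise UndefinedMetricError(f"{name} undefined: denominator is zero")
    return num / den


def precision(c: ConfusionCounts) -> float:
    return _ratio(c.TP, c.TP + c.FP, "precision")


def sensitivity(c: ConfusionCounts) -> float:
    return _ratio(c.TP, c.TP + c.FN, "sensitivity")


def specificity(c: ConfusionCounts) -> float:
    return _ratio(c.TN, c.TN + c.FP, "specificity")


def f1(c: ConfusionCounts) -> float:
    return _ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN, "f1")


def iba(sens: float, spec: float, alpha: float = 0.1) -> float:
    """Index balanced accuracy from sensitivity and specificity."""
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return (1.0 + alpha * (sens - spec)) * sens * spec


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    iba: float
    alpha: float
    n_positive: int
    n_negative: int

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "iba": self.iba,
            "alpha": self.alpha,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
        }


def evaluate(c: ConfusionCounts, alpha: float = 0.1) -> MetricsReport:
    """All scores from one confusion table."""
    sens, spec = sensitivity(c), specificity(c)
    return MetricsReport(
        precision=precision(c),
        sensitivity=sens,
        specificity=spec,
        f1=f1(c),
        iba=iba(sens, spec, alpha),
        alpha=alpha,
        n_positive=c.TP + c.FN,
        n_negative=c.TN + c.FP,
    )


def roc_points(y_true: Sequence[int], scores: Sequence[float]) -> list[tuple[float, float]]:
    """ROC curve as (FPR, TPR) points swept over the unique scores,
    anchored at (0, 0) and (1, 1)."""
    fpr, tpr, _ = roc_curve(np.asarray(y_true), np.asarray(scores))
    points = list(zip(fpr.tolist(), tpr.tolist()))
    if points[0] != (0.0, 0.0):
        points.insert(0, (0.0, 0.0))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points


def key_extraction_accuracy(
    predictions: Mapping[str, "object"],
    gold: Sequence,
    date_window_days: int = 3,
) -> dict[str, float]:
    """Fraction of articles whose extracted value matches the gold value,
    per class.

    ``predictions`` maps article_id to a KeyExtractionResult-like object
    with ``disease``/``country``/``date``/``count`` attributes; ``gold``
    is a sequence of GoldRecord.  Disease, country and count require
    exact equality; dates match within ``date_window_days`` (inclusive);
    a missing prediction counts as incorrect.
    """
    if not gold:
        raise ValueError("gold records required")
    correct = {"disease": 0, "country": 0, "date": 0, "count": 0}
    for record in gold:
        result = predictions.get(record.article_id)
        if result is None:
            continue
        if result.disease == record.disease:
            correct["disease"] += 1
        if result.country == record.country:
            correct["country"] += 1
        if (
            isinstance(result.date, Date)
            and abs((result.date - record.date).days) <= date_window_days
        ):
            correct["date"] += 1
        if result.count == record.confirmed_case_count:
            correct["count"] += 1
    return {cls: n / len(gold) for cls, n in correct.items()}
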
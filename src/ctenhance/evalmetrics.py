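"""Classification metrics, rank-based AUC and the dataset split rule.

All ratio metrics derive from the four confusion-matrix cells:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 * precision * recall / (precision + recall)

A ratio with a zero denominator is reported as ``None`` (absent), never as
zero, so degenerate predictions cannot silently inflate a report.  AUC is
the rank statistic: the probability that a random positive outscores a
random negative, ties counted one half.

``split_counts`` reproduces scan-level train/test/validation sizes by
rounding the train and test fractions half away from zero and giving the
validation set the remainder, so the three counts always sum to the total
(888 scans at 70/20/10 gives 622/178/88).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score as _sk_auc

from .exceptions import EmptyClassError

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "SplitCounts",
    "confusion_counts",
    "metrics_from_confusion",
    "auc",
    "split_counts",
    "format_percent",
    "report_to_json",
]


def _round_half_away(x: float) -> float:
    return float(np.sign(x) * np.floor(np.abs(x) + 0.5))


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN cell counts of a binary confusion matrix."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Fraction-valued metrics; undefined ratios are ``None``."""

    accuracy: float | None
    precision: float | None
    recall: float | None
    specificity: float | None
    f1: float | None
    auc: float | None = None


@dataclass(frozen=True)
class SplitCounts:
    n_train: int
    n_test: int
    n_val: int


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Count the four outcome cells of binary predictions."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or len(y_true) < 1:
        raise ValueError("labels and predictions must be equal-length 1-D")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must contain only 0/1 values")
    tn, fp, fn, tp = _sk_confusion(y_true, y_pred, labels=[0, 1]).ravel()
    return ConfusionCounts(tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn))


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics_from_confusion(c: ConfusionCounts) -> MetricsReport:
    """Evaluate the five confusion-derived metrics on unrounded fractions."""
    if c.total <= 0:
        raise ValueError("confusion matrix is empty")
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(
        accuracy=_ratio(c.tp + c.tn, c.total),
        precision=precision,
        recall=recall,
        specificity=_ratio(c.tn, c.tn + c.fp),
        f1=f1,
    )


def auc(scores, labels) -> float:
    """Probability a random positive outscores a random negative (ties 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must contain only 0/1 values")
    if labels.min() == labels.max():
        raise EmptyClassError("AUC requires both classes present")
    return float(_sk_auc(labels, scores))


def split_counts(n_total: int, fractions=(0.7, 0.2, 0.1)) -> SplitCounts:
    """Scan counts for a (train, test, val) fractional split of n_total.

    Train and test counts are rounded half away from zero; validation takes
    the remainder so the three counts sum exactly to ``n_total``.
    """
    f_train, f_test, f_val = fractions
    if min(f_train, f_test, f_val) <= 0:
        raise ValueError("split fractions must be positive")
    if abs(f_train + f_test + f_val - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n_train = int(_round_half_away(f_train * n_total))
    n_test = int(_round_half_away(f_test * n_total))
    return SplitCounts(n_train=n_train, n_test=n_test,
                       n_val=n_total - n_train - n_test)


def format_percent(fraction: float, decimals: int = 2) -> float:
    """fraction * 100 rounded half away from zero to ``decimals`` places."""
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    scale = 10.0**decimals
    return float(_round_half_away(fraction * 100.0 * scale) / scale)


def report_to_json(report: MetricsReport) -> str:
    return json.dumps(asdict(report), indent=2, sort_keys=True)
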
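"""Binary-classification metrics from confusion counts, plus ROC/PR curves.

MCI is the positive class. Degenerate denominators (a metric whose defining
ratio is 0/0 on the given counts) return 0 by convention with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


@dataclass
class MetricReport:
    acc: float
    precision: float
    recall: float
    f1: float
    sensitivity: float
    specificity: float
    mcc: float
    auc: float = float("nan")
    ap: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (0/0); reporting 0 by convention",
                      RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """Accuracy, precision/recall/F1, sensitivity, specificity and MCC."""
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    acc = (tp + tn) / counts.total
    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall/sensitivity")
    f1 = _ratio(2 * precision * recall, precision + recall, "F1")
    specificity = _ratio(tn, tn + fp, "specificity")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        warnings.warn("MCC undefined (zero denominator); reporting 0 by convention",
                      RuntimeWarning, stacklevel=2)
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(float(denom))
    return MetricReport(acc=acc, precision=precision, recall=recall, f1=f1,
                        sensitivity=recall, specificity=specificity, mcc=float(mcc))


@dataclass
class CurveReport:
    fpr: np.ndarray
    tpr: np.ndarray
    roc_thresholds: np.ndarray
    auc: float
    precision: np.ndarray
    recall: np.ndarray
    ap: float


def roc_pr(scores, labels) -> CurveReport:
    """ROC (trapezoidal AUC) and PR (step-wise AP) by a tie-grouped
    threshold sweep over the positive-class scores."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1D arrays")
    pos = int(labels.sum())
    neg = labels.size - pos
    if pos == 0 or neg == 0:
        raise ValueError("ROC/PR undefined: both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # last index of each tie group
    distinct = np.where(np.diff(s))[0]
    idx = np.r_[distinct, s.size - 1]
    tps = np.cumsum(y)[idx]
    fps = np.cumsum(1 - y)[idx]
    tpr = tps / pos
    fpr = fps / neg
    thresholds = s[idx]
    auc = float(np.trapezoid(np.r_[0.0, tpr], np.r_[0.0, fpr]))
    precision = tps / (tps + fps)
    recall = tpr
    ap = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    return CurveReport(fpr=np.r_[0.0, fpr], tpr=np.r_[0.0, tpr],
                       roc_thresholds=np.r_[np.inf, thresholds], auc=auc,
                       precision=precision, recall=recall, ap=ap)


def concordance_auc(scores, labels) -> float:
    """Mann-Whitney AUC: concordant-pair fraction, ties count one half."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * equal) / (pos.size * neg.size))
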
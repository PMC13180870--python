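"""Binary-classification metrics computed from first principles.

All quantities are derived directly from their defining formulas over the
score vector: threshold metrics from the confusion matrix at a fixed cut,
ROC-AUC by the trapezoidal rule over the full threshold sweep, average
precision by step-wise integration of the precision-recall curve, and a
calibration curve over equal-width probability bins.  Conventions for the
degenerate denominators: precision/recall/F1 are 0 when undefined, MCC is 0
when any marginal is empty, and AUC is ``None`` (with a warning) when the
evaluation set contains one class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_at(y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> ConfusionCounts:
    """Counts with the predicted-active rule ``score >= threshold``."""
    y = np.asarray(y_true).astype(int)
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
    )


def accuracy(c: ConfusionCounts) -> float:
    return (c.tp + c.tn) / c.total if c.total else 0.0


def precision(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0


def recall(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0


def f1_score(c: ConfusionCounts) -> float:
    p, r = precision(c), recall(c)
    return 2 * p * r / (p + r) if (p + r) else 0.0


def mcc(c: ConfusionCounts) -> float:
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / np.sqrt(denom)


def roc_curve(y_true: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(fpr, tpr) swept over every distinct score, tie groups collapsed."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    y = y[order]
    s = s[order]
    distinct = np.r_[np.where(np.diff(s))[0], len(s) - 1]  # last index of each tie group
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(1 - y)[distinct]
    tpr = np.r_[0.0, tps / max(tps[-1], 1)]
    fpr = np.r_[0.0, fps / max(fps[-1], 1)]
    return fpr, tpr


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float | None:
    y = np.asarray(y_true).astype(int)
    if y.min() == y.max():
        warnings.warn("single-class evaluation set: ROC-AUC undefined", stacklevel=2)
        return None
    fpr, tpr = roc_curve(y_true, scores)
    return float(np.trapezoid(tpr, fpr))


def average_precision(y_true: np.ndarray, scores: np.ndarray) -> float | None:
    """Step-wise PR integration: sum of precision × recall increments."""
    y = np.asarray(y_true).astype(int)
    if y.sum() == 0:
        warnings.warn("no positives: average precision undefined", stacklevel=2)
        return None
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    y = y[order]
    s = s[order]
    distinct = np.r_[np.where(np.diff(s))[0], len(s) - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(1 - y)[distinct]
    prec = tps / (tps + fps)
    rec = tps / y.sum()
    drec = np.diff(np.r_[0.0, rec])
    return float((prec * drec).sum())


def calibration_curve(
    y_true: np.ndarray, scores: np.ndarray, n_bins: int = 10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(bin centers, mean predicted, observed frequency); empty bins are NaN."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2
    mean_pred = np.full(n_bins, np.nan)
    obs_freq = np.full(n_bins, np.nan)
    which = np.clip(np.digitize(s, edges[1:-1]), 0, n_bins - 1)
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            mean_pred[b] = s[mask].mean()
            obs_freq[b] = y[mask].mean()
    return centers, mean_pred, obs_freq
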
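"""Binary-classification evaluation: confusion counts, the five headline
metrics (accuracy, precision, recall, F1, ROC-AUC) and ROC curves.

Conventions: a prediction is positive iff p >= threshold; tied scores get
half credit in the AUC (trapezoid AUC therefore equals the normalized
Mann-Whitney U statistic); zero-denominator ratios are reported as 0.0
with an explicit flag, so downstream tables stay total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    threshold: float
    undefined: frozenset[str] = field(default_factory=frozenset)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _check_lengths(y: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=int)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: |y|={y.shape} vs |p|={p.shape}")
    if len(y) < 1:
        raise ValueError("need at least one sample")
    return y, p


def confusion(y: np.ndarray, p: np.ndarray, threshold: float = 0.5) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) with prediction = 1 iff p >= threshold."""
    y, p = _check_lengths(y, p)
    pred = p >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return tp, fp, tn, fn


def roc_curve(y: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points (fpr, tpr) from (0,0) to (1,1) plus trapezoid AUC.

    Duplicate scores collapse to single vertices; the trapezoid area then
    equals Mann-Whitney pair counting with half credit for ties.
    """
    y, p = _check_lengths(y, p)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _sk_roc_curve(y, p, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def classification_metrics(y: np.ndarray, p: np.ndarray, threshold: float = 0.5) -> MetricsReport:
    """The five-metric report at a decision threshold.

    With a single-class ``y`` the AUC is undefined; it is reported as 0.0
    and flagged rather than raising, so per-fold tables stay rectangular.
    """
    tp, fp, tn, fn = confusion(y, p, threshold)
    n = tp + fp + tn + fn
    undefined = set()

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.add(name)
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    accuracy = (tp + tn) / n
    if precision + recall == 0:
        undefined.add("f1")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    y_arr = np.asarray(y)
    if len(np.unique(y_arr)) < 2:
        undefined.add("auc")
        auc = 0.0
    else:
        _, _, auc = roc_curve(y, p)
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        auc=auc, threshold=threshold, undefined=frozenset(undefined),
    )
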
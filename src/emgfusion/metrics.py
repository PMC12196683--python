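"""Confusion-matrix metrics and one-vs-rest ROC/AUC.

Averaging conventions: ACC is overall agreement (trace / total); SENS, SP
and F1 are unweighted (macro) means of the per-class one-vs-rest values.
All four are reported in percent. Per-class ratios with a 0/0 numerator
(class absent from truth or predictions) are defined as 0, so segments of
never-predicted classes penalize the macro scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve, auc as _sk_auc

from .gestures import as_gesture


def confusion(true_labels, predicted_labels, n_classes: int) -> np.ndarray:
    """K x K count matrix; rows are true classes, columns predictions."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("true and predicted label arrays must have equal length")
    if t.size == 0:
        return np.zeros((n_classes, n_classes), dtype=np.int64)
    for name, arr in (("true", t), ("predicted", p)):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"{name} labels out of range [0, {n_classes})")
    return _sk_confusion(t, p, labels=np.arange(n_classes)).astype(np.int64)


@dataclass(frozen=True)
class MetricSet:
    """SENS / SP / ACC / F1, each in percent."""

    sens: float
    sp: float
    acc: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {"SENS": self.sens, "SP": self.sp, "ACC": self.acc, "F1": self.f1}


def _safe_div(num, den):
    return num / den if den > 0 else 0.0


def macro_metrics(cm: np.ndarray) -> MetricSet:
    """Macro one-vs-rest SENS/SP/F1 and overall ACC from a confusion matrix."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    K = cm.shape[0]
    sens, sp, f1 = [], [], []
    for k in range(K):
        tp = cm[k, k]
        fn = cm[k].sum() - tp
        fp = cm[:, k].sum() - tp
        tn = total - tp - fn - fp
        sens.append(_safe_div(tp, tp + fn))
        sp.append(_safe_div(tn, tn + fp))
        prec = _safe_div(tp, tp + fp)
        rec = sens[-1]
        f1.append(_safe_div(2 * prec * rec, prec + rec))
    return MetricSet(sens=100 * float(np.mean(sens)),
                     sp=100 * float(np.mean(sp)),
                     acc=100 * float(np.trace(cm) / total),
                     f1=100 * float(np.mean(f1)))


@dataclass(frozen=True)
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    gesture: str | None = None


def roc_curve(scores, binary_truth, gesture=None) -> ROCCurve:
    """One-vs-rest ROC with thresholds at the unique scores (ties grouped).

    AUC is the trapezoidal area; with all thresholds retained it equals the
    Mann-Whitney probability that a positive outranks a negative (ties
    counted one half).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(binary_truth).astype(int)
    n_pos = int(truth.sum())
    if n_pos == 0 or n_pos == truth.size:
        raise ValueError("need at least one positive and one negative instance")
    fpr, tpr, _ = _sk_roc_curve(truth, scores, drop_intermediate=False)
    return ROCCurve(fpr=fpr, tpr=tpr, auc=float(_sk_auc(fpr, tpr)),
                    gesture=None if gesture is None else as_gesture(gesture).value)


def auc_all_classes(scores: np.ndarray, true_labels, gesture_order) -> dict[str, float]:
    """One-vs-rest AUC per gesture from pooled cross-validation scores.

    ``scores`` is (n_segments, K) with columns following ``gesture_order``;
    ``true_labels`` are integer labels in the same order. Every class must
    be present in the truth.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(true_labels, dtype=np.int64)
    out = {}
    for k, g in enumerate(gesture_order):
        name = as_gesture(g).value
        mask = (y == k).astype(int)
        if mask.sum() == 0:
            raise ValueError(f"class {name!r} absent from the pooled truth")
        out[name] = roc_curve(scores[:, k], mask, gesture=name).auc
    return out
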
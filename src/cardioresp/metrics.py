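"""Classification metrics: accuracy, macro precision/recall/F1, multiclass
MCC, and one-vs-rest macro AUC, all derived from the confusion table.

Multiclass MCC:

    MCC = (n * sum_i 1{yhat_i = y_i} - sum_k p_k t_k)
          / sqrt(n^2 - sum_k p_k^2) / sqrt(n^2 - sum_k t_k^2)

with p_k the number of times class k was predicted and t_k the number of
times it truly occurred; a vanishing denominator factor yields MCC = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["MetricSet", "compute_metrics", "confusion_matrix"]


@dataclass
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    auc: float
    confusion: np.ndarray = field(repr=False, default=None)  # type: ignore

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "mcc": self.mcc,
            "auc": self.auc,
        }


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, k: int) -> np.ndarray:
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[int(t), int(p)] += 1
    return cm


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    y_prob: Optional[np.ndarray] = None,
    k: int = 3,
) -> MetricSet:
    """Metric battery for one evaluation split.

    Precision/recall/F1 are computed per class from TP/FP/FN and
    macro-averaged (a class with no predicted/true positives contributes
    0). AUC is the one-vs-rest macro average and requires ``y_prob`` with
    rows summing to 1.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must align")
    n = len(y_true)
    cm = confusion_matrix(y_true, y_pred, k)
    correct = int(np.trace(cm))
    accuracy = correct / n

    precisions, recalls, f1s = [], [], []
    for c in range(k):
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = cm[c, :].sum() - tp
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * tp / (2 * tp + fn + fp) if 2 * tp + fn + fp > 0 else 0.0
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(f1)

    p_k = cm.sum(axis=0).astype(float)   # predicted counts
    t_k = cm.sum(axis=1).astype(float)   # true counts
    num = n * correct - float(p_k @ t_k)
    d1 = n * n - float(p_k @ p_k)
    d2 = n * n - float(t_k @ t_k)
    mcc = num / np.sqrt(d1) / np.sqrt(d2) if d1 > 0 and d2 > 0 else 0.0
    mcc = float(np.clip(mcc, -1.0, 1.0))

    auc = np.nan
    if y_prob is not None:
        y_prob = np.asarray(y_prob, dtype=float)
        if y_prob.shape != (n, k):
            raise ValueError("y_prob must be (n, k)")
        if np.any(np.abs(y_prob.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("probability rows must sum to 1")
        present = np.unique(y_true)
        try:
            if len(present) == k:
                auc = float(
                    roc_auc_score(y_true, y_prob, multi_class="ovr",
                                  average="macro", labels=np.arange(k))
                )
            else:
                aucs = [
                    roc_auc_score((y_true == c).astype(int), y_prob[:, c])
                    for c in present
                ]
                auc = float(np.mean(aucs))
        except ValueError:
            auc = np.nan

    return MetricSet(
        accuracy=float(accuracy),
        precision=float(np.mean(precisions)),
        recall=float(np.mean(recalls)),
        f1=float(np.mean(f1s)),
        mcc=float(mcc),
        auc=auc,
        confusion=cm,
    )
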
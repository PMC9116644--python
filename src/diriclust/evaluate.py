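"""Clustering evaluation: optimal label matching, accuracy, precision, recall.

Cluster indices returned by a clustering algorithm are arbitrary, so before
accuracy can be computed predicted clusters are aligned to true classes by
an optimal one-to-one assignment on the confusion matrix (Hungarian
algorithm, maximizing the matched count).  Precision and recall are
computed one-vs-rest per class from the matched confusion matrix and
macro-averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "match_clusters", "score"]


@dataclass
class ConfusionMatrix:
    """k_true x k_pred contingency counts between truth and prediction."""

    counts: np.ndarray
    true_classes: np.ndarray
    pred_clusters: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    matching: dict  # predicted cluster -> true class

    def as_row(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
        }


def confusion(true_labels, pred_labels) -> ConfusionMatrix:
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    if true_labels.shape != pred_labels.shape:
        raise ValueError("true and predicted label vectors differ in length")
    t_classes, t_idx = np.unique(true_labels, return_inverse=True)
    p_classes, p_idx = np.unique(pred_labels, return_inverse=True)
    counts = np.zeros((t_classes.size, p_classes.size), dtype=int)
    np.add.at(counts, (t_idx, p_idx), 1)
    return ConfusionMatrix(counts, t_classes, p_classes)


def match_clusters(cm: ConfusionMatrix | np.ndarray) -> dict:
    """Optimal one-to-one map from predicted-cluster index to true-class index.

    The confusion matrix is padded to square if the cluster counts differ;
    assignment maximizes the total matched count.  Keys/values are positions
    in the confusion matrix, not original label values.
    """
    counts = cm.counts if isinstance(cm, ConfusionMatrix) else np.asarray(cm)
    kt, kp = counts.shape
    dim = max(kt, kp)
    padded = np.zeros((dim, dim), dtype=counts.dtype)
    padded[:kt, :kp] = counts
    rows, cols = linear_sum_assignment(padded, maximize=True)
    return {int(c): int(r) for r, c in zip(rows, cols) if c < kp and r < kt}


def score(true_labels, pred_labels, average: str = "macro") -> MetricsReport:
    """Matched accuracy plus macro (or micro) precision and recall.

    Accuracy is the matched-diagonal total over N.  Per-class precision
    TP/(TP+FP) and recall TP/(TP+FN) are taken one-vs-rest on the matched
    confusion matrix and averaged over true classes; classes whose matched
    cluster captured no points score 0 for both.
    """
    cm = confusion(true_labels, pred_labels)
    mapping = match_clusters(cm)
    counts = cm.counts
    n = cm.n

    matched_total = sum(counts[t, p] for p, t in mapping.items())
    accuracy = matched_total / n

    if average == "micro":
        precision = recall = accuracy
    elif average == "macro":
        cls_to_pred = {t: p for p, t in mapping.items()}
        precisions, recalls = [], []
        for t in range(counts.shape[0]):
            row_total = counts[t].sum()
            if t in cls_to_pred:
                p = cls_to_pred[t]
                tp = counts[t, p]
                col_total = counts[:, p].sum()
                precisions.append(tp / col_total if col_total else 0.0)
                recalls.append(tp / row_total if row_total else 0.0)
            else:
                precisions.append(0.0)
                recalls.append(0.0)
        precision = float(np.mean(precisions))
        recall = float(np.mean(recalls))
    else:
        raise ValueError(f"unknown average {average!r}")

    matching = {
        int(cm.pred_clusters[p]): int(cm.true_classes[t]) for p, t in mapping.items()
    }
    return MetricsReport(float(accuracy), float(precision), float(recall), matching)
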
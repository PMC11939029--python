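"""Confusion matrices, cluster-to-label matching, and classification metrics.

Metrics follow the usual one-vs-rest lifting of the binary definitions:
per class, precision = TP/(TP+FP) and recall = TP/(TP+FN), F1 is their
harmonic mean (0/0 := 0), and overall accuracy is trace/total.  Both
micro-F1 (from pooled TP/FP/FN; identical to accuracy for single-label
multi-class data) and macro-F1 (unweighted mean of class F1s) are
reported.  Unsupervised cluster assignments are scored after finding
the cluster-to-class bijection that maximises agreement (Hungarian
matching; solved exhaustively for C <= 8, by the assignment algorithm
otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "hungarian_match",
           "metrics", "evaluate_clustering"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """C x C counts; rows are true classes, columns predicted classes or
    raw cluster ids (class order: objective, methods, results, conclusion)."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be 2-D")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: tuple[float, ...]
    recall: tuple[float, ...]
    f1: tuple[float, ...]
    macro_f1: float
    micro_f1: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": list(self.precision),
            "recall": list(self.recall),
            "f1": list(self.f1),
            "macro_f1": self.macro_f1,
            "micro_f1": self.micro_f1,
        }


def confusion(true_labels, predicted_labels, num_classes: int = 4) -> ConfusionMatrix:
    """Tally counts[i][j] = #sentences with true class i and prediction j."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError("true and predicted label lists differ in length")
    if t.size and (t.min() < 0 or t.max() >= num_classes
                   or p.min() < 0 or p.max() >= num_classes):
        raise ValueError("label out of range")
    counts = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def hungarian_match(m: ConfusionMatrix) -> tuple[tuple[int, ...], int]:
    """Best column -> class bijection maximising the matched count.

    Returns ``(perm, matched)`` where ``perm[j]`` is the true-class index
    assigned to column j and ``matched = sum_j counts[perm[j], j]``.
    For C <= 8 all permutations are searched exhaustively (ties broken
    by the lexicographically smallest permutation); larger C uses the
    standard assignment algorithm.
    """
    M = m.counts
    if M.shape[0] != M.shape[1]:
        raise ValueError("confusion matrix must be square to match")
    C = M.shape[0]
    if C <= 8:
        best_perm, best_score = None, -1
        for perm in permutations(range(C)):   # lexicographic order
            score = int(sum(M[perm[j], j] for j in range(C)))
            if score > best_score:
                best_perm, best_score = perm, score
        return best_perm, best_score
    rows, cols = linear_sum_assignment(-M)
    perm = [0] * C
    for r, c in zip(rows, cols):
        perm[c] = r
    return tuple(perm), int(M[rows, cols].sum())


def _round_half_away(x: float, decimals: int) -> float:
    scale = 10 ** decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


def metrics(m: ConfusionMatrix, decimals: int | None = None) -> MetricsReport:
    """One-vs-rest precision/recall/F1 per class plus accuracy and
    micro/macro F1, optionally rounded half-away-from-zero."""
    M = m.counts.astype(float)
    total = M.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(M)
    fp = M.sum(axis=0) - tp
    fn = M.sum(axis=1) - tp

    def safe_div(a, b):
        return np.where(b > 0, a / np.where(b > 0, b, 1), 0.0)

    precision = safe_div(tp, tp + fp)
    recall = safe_div(tp, tp + fn)
    f1 = safe_div(2 * precision * recall, precision + recall)
    accuracy = tp.sum() / total
    macro_f1 = float(f1.mean())
    micro_p = tp.sum() / max(tp.sum() + fp.sum(), 1e-300)
    micro_r = tp.sum() / max(tp.sum() + fn.sum(), 1e-300)
    micro_f1 = 0.0 if micro_p + micro_r == 0 else 2 * micro_p * micro_r / (micro_p + micro_r)

    vals = {
        "accuracy": float(accuracy),
        "precision": tuple(float(v) for v in precision),
        "recall": tuple(float(v) for v in recall),
        "f1": tuple(float(v) for v in f1),
        "macro_f1": macro_f1,
        "micro_f1": float(micro_f1),
    }
    if decimals is not None:
        vals = {
            k: (_round_half_away(v, decimals) if isinstance(v, float)
                else tuple(_round_half_away(x, decimals) for x in v))
            for k, v in vals.items()
        }
    return MetricsReport(**vals)


def evaluate_clustering(true_labels, assignment, decimals: int | None = None,
                        num_classes: int = 4) -> tuple[ConfusionMatrix, MetricsReport]:
    """Score an unsupervised assignment against true labels.

    Builds the raw label-by-cluster matrix, relabels the columns with
    the optimal Hungarian bijection, and computes the metrics on the
    remapped matrix; accuracy equals matched count / total.
    """
    raw = confusion(true_labels, assignment, num_classes=num_classes)
    perm, _ = hungarian_match(raw)
    remapped = np.zeros_like(raw.counts)
    for j in range(num_classes):
        remapped[:, perm[j]] = raw.counts[:, j]
    cm = ConfusionMatrix(remapped)
    return cm, metrics(cm, decimals=decimals)
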
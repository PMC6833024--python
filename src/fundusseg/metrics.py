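"""Segmentation losses and evaluation statistics.

The training loss is the soft Dice loss evaluated directly on the
probability map (no interior thresholding), so the same formula serves
real-valued predictions during training and binary masks at evaluation.
Evaluation statistics (precision, recall, F-score, IoU, sensitivity,
specificity) derive from per-pixel confusion counts; screening performance
is summarised by the rank-statistic ROC-AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "SegmentationScores",
    "dice_loss",
    "dice_loss_grad",
    "confusion_counts",
    "scores_from_counts",
    "evaluate_masks",
    "roc_auc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-pixel confusion counts between a predicted and a true binary mask."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class SegmentationScores:
    """Overlap statistics derived from :class:`ConfusionCounts`."""

    precision: float
    recall: float
    f_score: float
    iou: float
    sensitivity: float
    specificity: float


def _check_prob_grid(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 2 or p.size == 0:
        raise ValueError("probability grid must be a non-empty 2-D array")
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("probability grid values must lie in [0, 1]")
    return p


def _check_binary_mask(g: np.ndarray) -> np.ndarray:
    g = np.asarray(g)
    if g.ndim != 2 or g.size == 0:
        raise ValueError("binary mask must be a non-empty 2-D array")
    if not np.isin(g, (0, 1)).all():
        raise ValueError("binary mask values must be exactly 0 or 1")
    return g.astype(np.float64)


def dice_loss(p: np.ndarray, g: np.ndarray) -> float:
    """Soft Dice loss ``1 - 2*sum(P*G) / (sum(P^2) + sum(G^2))``.

    ``p`` is a probability map with entries in [0, 1]; ``g`` is a binary
    ground-truth mask of the same shape.  Returns 0 exactly when ``p`` is
    binary and equals a non-empty ``g``, and 1 when the soft intersection
    is empty.

    Raises
    ------
    ValueError
        If shapes differ, or both arrays are identically zero (the loss
        is an undefined 0/0 in that case).
    """
    p = _check_prob_grid(p)
    g = _check_binary_mask(g)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    denom = float((p * p).sum() + (g * g).sum())
    if denom == 0.0:
        raise ValueError("dice loss undefined: prediction and ground truth are both empty")
    return 1.0 - 2.0 * float((p * g).sum()) / denom


def dice_loss_grad(p: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Gradient of :func:`dice_loss` with respect to the probability map.

    With N = 2*sum(P*G) and D = sum(P^2) + sum(G^2), the loss is 1 - N/D and

        dL/dP = -(2*G*D - 2*P*N) / D**2.
    """
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    num = 2.0 * float((p * g).sum())
    den = float((p * p).sum() + (g * g).sum())
    if den == 0.0:
        raise ValueError("dice loss undefined: prediction and ground truth are both empty")
    return (-2.0 * g * den + 2.0 * p * num) / (den * den)


def confusion_counts(pred: np.ndarray, g: np.ndarray) -> ConfusionCounts:
    """Pixel-wise TP/FP/FN/TN between two binary masks of equal shape."""
    pred = np.asarray(pred)
    g = np.asarray(g)
    if pred.shape != g.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {g.shape}")
    p = pred.astype(bool)
    t = g.astype(bool)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def scores_from_counts(c: ConfusionCounts) -> SegmentationScores:
    """Precision, recall, F-score, IoU, sensitivity, specificity from counts.

    Degenerate 0/0 ratios resolve by convention rather than NaN: an empty
    prediction of an empty target is vacuously perfect (precision, F and
    IoU all 1), an empty prediction of a non-empty target scores 0, and
    specificity is 1 when there are no true negatives to misclassify.
    """
    tp, fp, fn, tn = c.tp, c.fp, c.fn, c.tn
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fp == 0:
        precision = 1.0 if fn == 0 else 0.0
    else:
        precision = tp / (tp + fp)
    recall = 1.0 if tp + fn == 0 else tp / (tp + fn)
    if tp + fp + fn == 0:
        f_score = 1.0
        iou = 1.0
    else:
        iou = tp / (tp + fp + fn)
        f_score = 2.0 * iou / (1.0 + iou)
    specificity = 1.0 if tn + fp == 0 else tn / (tn + fp)
    return SegmentationScores(
        precision=precision,
        recall=recall,
        f_score=f_score,
        iou=iou,
        sensitivity=recall,
        specificity=specificity,
    )


def evaluate_masks(pred: np.ndarray, g: np.ndarray) -> SegmentationScores:
    """Convenience wrapper: confusion counts then scores."""
    return scores_from_counts(confusion_counts(pred, g))


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve as the Mann-Whitney concordance probability.

    Equals P(score_pos > score_neg) + 0.5 * P(score_pos == score_neg) over
    all positive/negative pairs, computed exactly from midranks.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires at least one positive and one negative label")
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(len(s), dtype=np.float64)
    sorted_s = s[order]
    i = 0
    rank = 1.0
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        midrank = 0.5 * (rank + rank + (j - i))
        ranks[order[i : j + 1]] = midrank
        rank += j - i + 1
        i = j + 1
    rank_sum_pos = float(ranks[y == 1].sum())
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)
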
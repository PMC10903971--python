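"""Detection evaluation: IoU matching and average precision.

Predicted instance masks are scored against ground truth with average
precision (AP) at a fixed intersection-over-union (IoU) threshold,
conventionally 0.5 and 0.75.  AP is the exact area under the
all-point-interpolated precision-recall curve,

    AP = integral_0^1 p~(r) dr,    p~(r) = max_{r' >= r} p(r'),

built by sweeping predictions in descending score order.  Matching is
greedy: each prediction, visited in score order, claims the unmatched
ground truth of highest IoU provided that IoU reaches the threshold;
each truth is used at most once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry2d import InstanceMask
from .segmentation import SegmentationResult

__all__ = [
    "MatchResult",
    "mask_iou",
    "match_detections",
    "average_precision",
    "evaluate_dataset",
]


@dataclass(frozen=True)
class MatchResult:
    """Outcome of greedy prediction-to-truth matching at one threshold."""

    pairs: tuple[tuple[int, int], ...]
    unmatched_predictions: tuple[int, ...]
    unmatched_truths: tuple[int, ...]
    iou_threshold: float


def mask_iou(a: InstanceMask, b: InstanceMask) -> float:
    """|a n b| / |a u b|; 0 by convention when the union is empty."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    inter = np.logical_and(a.pixels, b.pixels).sum()
    union = np.logical_or(a.pixels, b.pixels).sum()
    if union == 0:
        return 0.0
    return float(inter) / float(union)


def _as_ranked_instances(preds) -> tuple[InstanceMask, ...]:
    """Accept a SegmentationResult or any score-sorted mask sequence.

    A SegmentationResult guarantees disjoint instances (label-image
    semantics), but real detectors emit overlapping candidates, so the
    evaluation entry points also take a plain sequence — it must already
    be sorted by score descending.
    """
    inst = tuple(preds)
    scores = [m.score for m in inst]
    if scores != sorted(scores, reverse=True):
        raise ValueError("predictions must be sorted by score descending")
    return inst


def match_detections(preds: SegmentationResult | Sequence[InstanceMask],
                     truths: Sequence[InstanceMask],
                     iou_threshold: float) -> MatchResult:
    """Greedy score-order matching of predictions to ground truths.

    Predictions are visited in their stored order (score descending).
    IoU ties between truths break toward the smaller truth index, making
    matching deterministic.
    """
    if not 0 < iou_threshold <= 1:
        raise ValueError(f"iou_threshold must be in (0, 1], got {iou_threshold}")
    preds = _as_ranked_instances(preds)
    taken: set[int] = set()
    pairs: list[tuple[int, int]] = []
    unmatched_preds: list[int] = []
    for i, pred in enumerate(preds):
        best_j, best_iou = -1, 0.0
        for j, truth in enumerate(truths):
            if j in taken:
                continue
            iou = mask_iou(pred, truth)
            if iou > best_iou:  # strict: ties keep the earlier truth
                best_j, best_iou = j, iou
        if best_j >= 0 and best_iou >= iou_threshold:
            taken.add(best_j)
            pairs.append((i, best_j))
        else:
            unmatched_preds.append(i)
    unmatched_truths = tuple(j for j in range(len(truths)) if j not in taken)
    return MatchResult(
        pairs=tuple(pairs),
        unmatched_predictions=tuple(unmatched_preds),
        unmatched_truths=unmatched_truths,
        iou_threshold=iou_threshold,
    )


def average_precision(preds: SegmentationResult | Sequence[InstanceMask],
                      truths: Sequence[InstanceMask],
                      iou_threshold: float) -> float:
    """AP at one IoU threshold for a single scene.

    Exact area under the right-max interpolated precision-recall curve
    (all-point interpolation, not 11-point sampling).  Requires at least
    one ground-truth instance; returns 0 when there are no predictions.
    """
    if len(truths) == 0:
        raise ValueError("average precision is undefined with no ground truth")
    n_truth = len(truths)
    preds = _as_ranked_instances(preds)
    match = match_detections(preds, truths, iou_threshold)
    matched_preds = {i for i, _ in match.pairs}
    tp = np.array([i in matched_preds for i in range(len(preds))], dtype=float)
    if tp.size == 0:
        return 0.0
    cum_tp = np.cumsum(tp)
    ranks = np.arange(1, tp.size + 1)
    precision = cum_tp / ranks
    recall = cum_tp / n_truth
    # right-max envelope, then exact area over recall increments
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    prev_recall = np.concatenate(([0.0], recall[:-1]))
    ap = float(np.sum((recall - prev_recall) * envelope))
    return ap


def evaluate_dataset(pred_sets: Sequence[SegmentationResult],
                     truth_sets: Sequence[Sequence[InstanceMask]],
                     iou_thresholds: Sequence[float] = (0.5, 0.75),
                     pooled: bool = False) -> dict[float, dict]:
    """Score many scenes at several IoU thresholds.

    Default: AP per scene, then an unweighted mean over scenes.  With
    ``pooled=True`` all predictions compete in one global ranking instead
    (each prediction matched within its own scene, then a single PR curve
    over the pooled, score-sorted detections).

    Returns ``{threshold: {"mean_ap": float, "per_image": list[float]}}``;
    in pooled mode ``per_image`` is still reported for reference.
    """
    if len(pred_sets) != len(truth_sets):
        raise ValueError("pred_sets and truth_sets must have equal length")
    out: dict[float, dict] = {}
    for thr in iou_thresholds:
        per_image = [
            average_precision(p, t, thr) for p, t in zip(pred_sets, truth_sets)
        ]
        if pooled:
            mean_ap = _pooled_ap(pred_sets, truth_sets, thr)
        else:
            mean_ap = float(np.mean(per_image)) if per_image else 0.0
        out[thr] = {"mean_ap": mean_ap, "per_image": per_image}
    return out


def _pooled_ap(pred_sets, truth_sets, thr: float) -> float:
    n_truth = sum(len(t) for t in truth_sets)
    if n_truth == 0:
        raise ValueError("average precision is undefined with no ground truth")
    scored: list[tuple[float, bool]] = []
    for preds, truths in zip(pred_sets, truth_sets):
        match = match_detections(preds, truths, thr)
        matched = {i for i, _ in match.pairs}
        for i, p in enumerate(preds):
            scored.append((p.score, i in matched))
    if not scored:
        return 0.0
    scored.sort(key=lambda t: -t[0])
    tp = np.array([m for _, m in scored], dtype=float)
    cum_tp = np.cumsum(tp)
    precision = cum_tp / np.arange(1, tp.size + 1)
    recall = cum_tp / n_truth
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    prev_recall = np.concatenate(([0.0], recall[:-1]))
    return float(np.sum((recall - prev_recall) * envelope))
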
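"""Detection and counting metrics.

A detection *matches* a ground-truth interval when both carry the same
label and their IOU exceeds the threshold (0.5 by default).  Matching
is greedy in descending score with each ground truth claimable once
(the PASCAL-VOC convention).  From the matches follow precision
P = TP/(TP+FP), recall R = TP/(TP+FN), per-class average precision as
the all-point integral of the interpolated precision envelope over
recall, and mAP as the unweighted mean over classes present in the
ground truth.  Top-5 proposal recall (label-agnostic) evaluates raw
candidate quality; a cycle-count report evaluates the periodic
matcher.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .anchors import ScoredDetection, iou
from .io import IntervalAnnotation
from .matching import CycleSegment


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[ScoredDetection, IntervalAnnotation]] = field(
        default_factory=list)


@dataclass
class PRCurve:
    """(recall, precision) points by descending score, and their AP."""

    recall: np.ndarray
    precision: np.ndarray
    ap: float


def _per_record(items):
    """Accept either a flat list (single record) or a list of per-record
    lists; returns a list of per-record lists."""
    if items and isinstance(items[0], (list, tuple)) \
            and not isinstance(items[0], IntervalAnnotation):
        return [list(r) for r in items]
    return [list(items)]


def match_detections(dets: Sequence[ScoredDetection],
                     gts: Sequence[IntervalAnnotation],
                     iou_threshold: float = 0.5) -> MatchResult:
    """Greedy score-ordered matching within one record."""
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    claimed = [False] * len(gts)
    pairs = []
    tp = fp = 0
    for di in order:
        d = dets[di]
        best_j, best_v = -1, iou_threshold
        for j, g in enumerate(gts):
            if claimed[j] or g.label != d.interval.label:
                continue
            v = iou(d.interval.start, d.interval.end, g.start, g.end)
            if v > best_v:
                best_j, best_v = j, v
        if best_j >= 0:
            claimed[best_j] = True
            pairs.append((d, gts[best_j]))
            tp += 1
        else:
            fp += 1
    fn = len(gts) - tp
    return MatchResult(tp=tp, fp=fp, fn=fn, pairs=pairs)


def precision_recall(match: MatchResult) -> tuple[float, float]:
    p = match.tp / (match.tp + match.fp) if (match.tp + match.fp) else 0.0
    r = match.tp / (match.tp + match.fn) if (match.tp + match.fn) else 1.0
    return p, r


def _tp_fp_flags(dets_per_record, gts_per_record, iou_threshold):
    """Pooled detections over records -> (scores, tp_flags, n_gt)."""
    scores, flags = [], []
    n_gt = sum(len(g) for g in gts_per_record)
    entries = []
    for rid, dets in enumerate(dets_per_record):
        for d in dets:
            entries.append((d.score, rid, d))
    entries.sort(key=lambda e: -e[0])
    claimed = [[False] * len(g) for g in gts_per_record]
    for score, rid, d in entries:
        gts = gts_per_record[rid]
        best_j, best_v = -1, iou_threshold
        for j, g in enumerate(gts):
            if claimed[rid][j]:
                continue
            v = iou(d.interval.start, d.interval.end, g.start, g.end)
            if v > best_v:
                best_j, best_v = j, v
        if best_j >= 0:
            claimed[rid][best_j] = True
            flags.append(1)
        else:
            flags.append(0)
        scores.append(score)
    return np.array(scores), np.array(flags, dtype=int), n_gt


def pr_curve(dets_per_record, gts_per_record,
             iou_threshold: float = 0.5) -> PRCurve:
    """Single-class precision-recall curve and all-point AP.

    Inputs are per-record lists of detections / ground truths already
    restricted to one class.
    """
    dets_per_record = _per_record(dets_per_record)
    gts_per_record = _per_record(gts_per_record)
    _scores, flags, n_gt = _tp_fp_flags(dets_per_record, gts_per_record,
                                        iou_threshold)
    if n_gt == 0:
        return PRCurve(np.array([]), np.array([]), ap=0.0)
    if len(flags) == 0:
        return PRCurve(np.array([0.0]), np.array([0.0]), ap=0.0)
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(1 - flags)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope, then all-point integral sum (R_k - R_{k-1}) P_env
    env = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        ap += (r - prev_r) * p
        prev_r = r
    return PRCurve(recall, precision, ap=float(ap))


def average_precision(dets_per_record, gts_per_record,
                      iou_threshold: float = 0.5) -> float:
    """All-point AP of one class (see :func:`pr_curve`)."""
    return pr_curve(dets_per_record, gts_per_record, iou_threshold).ap


def map_over_classes(dets_per_record, gts_per_record,
                     iou_threshold: float = 0.5
                     ) -> tuple[float, dict[str, float]]:
    """mAP = unweighted mean AP over classes with at least one ground
    truth; detections of absent classes are ignored."""
    dets_per_record = _per_record(dets_per_record)
    gts_per_record = _per_record(gts_per_record)
    labels = sorted({g.label for gts in gts_per_record for g in gts})
    per_class = {}
    for label in labels:
        d_sub = [[d for d in dets if d.interval.label == label]
                 for dets in dets_per_record]
        g_sub = [[g for g in gts if g.label == label]
                 for gts in gts_per_record]
        per_class[label] = average_precision(d_sub, g_sub, iou_threshold)
    if not per_class:
        return 0.0, {}
    return float(np.mean(list(per_class.values()))), per_class


def proposal_recall(candidates_per_record, gts_per_record,
                    iou_threshold: float = 0.5) -> float:
    """Fraction of ground truths covered by at least one candidate with
    IOU above threshold, label-agnostic (top-N filtering is upstream)."""
    candidates_per_record = _per_record(candidates_per_record)
    gts_per_record = _per_record(gts_per_record)
    covered = total = 0
    for cands, gts in zip(candidates_per_record, gts_per_record):
        for g in gts:
            total += 1
            for c in cands:
                interval = c.interval if isinstance(c, ScoredDetection) else c
                if iou(interval.start, interval.end, g.start, g.end) \
                        > iou_threshold:
                    covered += 1
                    break
    return covered / total if total else 1.0


@dataclass
class CycleCountReport:
    per_class_error: dict[str, int]
    total_error: int
    accuracy: Optional[float]  # per-cycle label accuracy, when resolvable


def _overlap(a_start, a_end, b_start, b_end) -> float:
    return max(0.0, min(a_end, b_end) - max(a_start, b_start))


def cycle_count_report(pred, true) -> CycleCountReport:
    """Compare predicted and true cycle inventories.

    ``pred``/``true`` are either label->count dicts or lists of
    segments (:class:`CycleSegment` / labeled intervals).  With
    segments on both sides, each predicted segment is matched to the
    true cycle it overlaps most and the per-cycle label accuracy is the
    fraction of matched segments with the correct label; with bare
    counts the accuracy is None.
    """
    def counts_of(x):
        if isinstance(x, dict):
            return dict(x), None
        labels = Counter()
        for s in x:
            labels[s.label] += 1
        return dict(labels), list(x)

    pred_counts, pred_segs = counts_of(pred)
    true_counts, true_segs = counts_of(true)
    labels = sorted(set(pred_counts) | set(true_counts))
    per_class = {l: abs(pred_counts.get(l, 0) - true_counts.get(l, 0))
                 for l in labels}
    accuracy = None
    if pred_segs is not None and true_segs is not None:
        correct = matched = 0
        for s in pred_segs:
            best = None
            best_ov = 0.0
            for t in true_segs:
                ov = _overlap(s.start, s.end, t.start, t.end)
                if ov > best_ov:
                    best, best_ov = t, ov
            if best is not None:
                matched += 1
                if best.label == s.label:
                    correct += 1
        accuracy = correct / matched if matched else 1.0
    return CycleCountReport(per_class_error=per_class,
                            total_error=sum(per_class.values()),
                            accuracy=accuracy)
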
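"""Detection matching, PR/AP/mAP and cycle-count reports."""

import numpy as np
import pytest

from actiseg.anchors import ScoredDetection, iou
from actiseg.evaluation import (average_precision, cycle_count_report,
                                map_over_classes, match_detections,
                                pr_curve, precision_recall, proposal_recall)
from actiseg.io import IntervalAnnotation
from actiseg.matching import CycleSegment

from conftest import random_interval


def det(start, end, label="x", score=1.0):
    return ScoredDetection(IntervalAnnotation(start, end, label), score)


def brute_force_match(dets, gts, thr):
    """Oracle: same greedy semantics, re-derived step by step."""
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    used = set()
    tp = 0
    for i in order:
        best, best_v = None, thr
        for j, g in enumerate(gts):
            if j in used or g.label != dets[i].interval.label:
                continue
            v = iou(dets[i].interval.start, dets[i].interval.end,
                    g.start, g.end)
            if v > best_v:
                best, best_v = j, v
        if best is not None:
            used.add(best)
            tp += 1
    return tp, len(dets) - tp, len(gts) - tp


def brute_force_ap(dets, gts, thr):
    """AP by explicit enumeration of every score threshold."""
    flags = []
    used = set()
    for d in sorted(dets, key=lambda d: -d.score):
        best, best_v = None, thr
        for j, g in enumerate(gts):
            if j in used:
                continue
            v = iou(d.interval.start, d.interval.end, g.start, g.end)
            if v > best_v:
                best, best_v = j, v
        if best is not None:
            used.add(best)
            flags.append(1)
        else:
            flags.append(0)
    n_gt = len(gts)
    ap = 0.0
    prev_recall = 0.0
    for k in range(len(flags)):
        tp = sum(flags[:k + 1])
        recall = tp / n_gt
        # interpolated precision at this recall: max precision at any
        # cut with recall >= current
        p_interp = max(
            (sum(flags[:m + 1]) / (m + 1)
             for m in range(k, len(flags))
             if sum(flags[:m + 1]) / n_gt >= recall), default=0.0)
        ap += (recall - prev_recall) * p_interp
        prev_recall = recall
    return ap


class TestMatchDetections:
    def test_perfect_detections(self):
        gts = [IntervalAnnotation(0, 30, "a"), IntervalAnnotation(50, 90, "b")]
        dets = [det(0, 30, "a"), det(50, 90, "b")]
        m = match_detections(dets, gts)
        assert (m.tp, m.fp, m.fn) == (2, 0, 0)

    def test_wrong_label_counts_twice(self):
        gts = [IntervalAnnotation(0, 30, "a")]
        m = match_detections([det(0, 30, "b")], gts)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_each_gt_claimed_once(self):
        gts = [IntervalAnnotation(0, 30, "a")]
        m = match_detections([det(0, 30, "a", 0.9), det(1, 31, "a", 0.8)], gts)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            gts = [IntervalAnnotation(iv.start, iv.end,
                                      str(rng.integers(2)))
                   for iv in (random_interval(rng) for _ in range(4))]
            dets = [ScoredDetection(
                IntervalAnnotation(iv.start, iv.end, str(rng.integers(2))),
                float(rng.random()))
                for iv in (random_interval(rng) for _ in range(10))]
            m = match_detections(dets, gts, 0.5)
            assert (m.tp, m.fp, m.fn) == brute_force_match(dets, gts, 0.5)
            assert m.tp + m.fn == len(gts)
            assert m.tp + m.fp == len(dets)


class TestPrecisionRecall:
    def test_formula(self):
        from actiseg.evaluation import MatchResult
        p, r = precision_recall(MatchResult(tp=3, fp=1, fn=2))
        assert (p, r) == (0.75, 0.6)

    def test_no_detections(self):
        from actiseg.evaluation import MatchResult
        p, r = precision_recall(MatchResult(tp=0, fp=0, fn=4))
        assert (p, r) == (0.0, 0.0)

    def test_perfect(self):
        from actiseg.evaluation import MatchResult
        assert precision_recall(MatchResult(tp=5, fp=0, fn=0)) == (1.0, 1.0)


class TestAveragePrecision:
    def test_single_correct_detection(self):
        gts = [IntervalAnnotation(10, 40, "a")]
        assert average_precision([det(10, 40, "a")], gts) == 1.0

    def test_all_wrong(self):
        gts = [IntervalAnnotation(10, 40, "a")]
        assert average_precision([det(200, 240, "a", 0.9)], gts) == 0.0

    def test_matches_threshold_enumeration_oracle(self, rng):
        for _ in range(100):
            gts = [random_interval(rng) for _ in range(5)]
            dets = [ScoredDetection(random_interval(rng), float(rng.random()))
                    for _ in range(15)]
            ours = average_precision(dets, gts, 0.5)
            assert ours == pytest.approx(brute_force_ap(dets, gts, 0.5),
                                         abs=1e-9)

    def test_invariant_under_monotone_score_rescaling(self, rng):
        gts = [random_interval(rng) for _ in range(5)]
        dets = [ScoredDetection(random_interval(rng), float(rng.random()))
                for _ in range(15)]
        rescaled = [ScoredDetection(d.interval, 0.1 + 0.5 * d.score)
                    for d in dets]
        assert average_precision(dets, gts) == pytest.approx(
            average_precision(rescaled, gts))

    def test_recall_non_decreasing_on_curve(self, rng):
        gts = [random_interval(rng) for _ in range(5)]
        dets = [ScoredDetection(random_interval(rng), float(rng.random()))
                for _ in range(15)]
        curve = pr_curve(dets, gts)
        assert np.all(np.diff(curve.recall) >= 0)
        assert 0.0 <= curve.ap <= 1.0


class TestMAP:
    def test_perfect_self_evaluation(self):
        gts = [IntervalAnnotation(0, 30, "a"), IntervalAnnotation(50, 90, "b"),
               IntervalAnnotation(120, 160, "a")]
        dets = [det(g.start, g.end, g.label) for g in gts]
        m, per_class = map_over_classes([dets], [gts])
        assert m == 1.0
        assert per_class == {"a": 1.0, "b": 1.0}

    def test_classes_without_gt_excluded(self):
        gts = [IntervalAnnotation(0, 30, "a")]
        dets = [det(0, 30, "a"), det(50, 80, "ghost", 0.9)]
        m, per_class = map_over_classes([dets], [gts])
        assert set(per_class) == {"a"}
        assert m == 1.0


class TestProposalRecall:
    def test_identity_candidates(self):
        gts = [IntervalAnnotation(0, 30), IntervalAnnotation(50, 90)]
        cands = [det(0, 30), det(50, 90)]
        assert proposal_recall([cands], [gts]) == 1.0

    def test_empty_candidates(self):
        gts = [IntervalAnnotation(0, 30)]
        assert proposal_recall([[]], [gts]) == 0.0

    def test_label_agnostic_with_perturbed_bounds(self, rng):
        gts = [IntervalAnnotation(50, 100, "a"), IntervalAnnotation(150, 200, "b")]
        cands = [det(g.start + int(rng.integers(-3, 4)),
                     g.end + int(rng.integers(-3, 4)), "other")
                 for g in gts]
        for c, g in zip(cands, gts):
            assert iou(c.interval.start, c.interval.end, g.start, g.end) > 0.5
        assert proposal_recall([cands], [gts]) == 1.0


class TestCycleCountReport:
    def test_identical_counts(self):
        r = cycle_count_report({"a": 3, "b": 2}, {"a": 3, "b": 2})
        assert r.total_error == 0
        assert r.accuracy is None

    def test_one_mislabeled_of_ten(self):
        true = [CycleSegment(i * 10, (i + 1) * 10, "a", 10) for i in range(10)]
        pred = [CycleSegment(i * 10, (i + 1) * 10,
                             "a" if i else "b", 10) for i in range(10)]
        r = cycle_count_report(pred, true)
        assert r.accuracy == pytest.approx(0.9)
        assert r.per_class_error == {"a": 1, "b": 1}

    def test_three_class_toy_by_hand(self):
        true = [CycleSegment(0, 10, "x", 10), CycleSegment(10, 20, "y", 10),
                CycleSegment(20, 30, "z", 10)]
        pred = [CycleSegment(0, 9, "x", 9), CycleSegment(11, 20, "y", 9),
                CycleSegment(20, 30, "x", 10)]
        r = cycle_count_report(pred, true)
        # counts: x predicted 2/true 1, y 1/1, z 0/1
        assert r.per_class_error == {"x": 1, "y": 0, "z": 1}
        assert r.total_error == 2
        assert r.accuracy == pytest.approx(2 / 3)
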
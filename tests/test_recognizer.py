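"""Feature projection, adaptive pooling and joint recognition."""

import numpy as np
import pytest

from actiseg.anchors import ScoredDetection
from actiseg.io import IntervalAnnotation, SensorSequence
from actiseg.recognizer import (NONE_LABEL, IntervalRecognizer,
                                adaptive_avg_pool, loss_l2,
                                project_to_feature_map, train_joint)

from conftest import random_interval


class TestProjection:
    @pytest.mark.parametrize("interval,expected", [
        ((40, 120), (10, 30)),   # exact 1/4 ratio
        ((0, 200), (0, 50)),     # full signal
        ((41, 44), (10, 11)),    # 3-sample interval -> single feature
    ])
    def test_examples(self, interval, expected):
        assert project_to_feature_map(*interval, lf=50, los=200) == expected

    def test_outside_signal_rejected(self):
        with pytest.raises(ValueError):
            project_to_feature_map(-1, 10, 50, 200)
        with pytest.raises(ValueError):
            project_to_feature_map(10, 300, 50, 200)

    def test_never_degenerate(self, rng):
        for _ in range(300):
            iv = random_interval(rng, hi=200)
            s, e = project_to_feature_map(iv.start, iv.end, 50, 200)
            assert 0 <= s < e <= 50

    def test_monotone_under_inclusion(self, rng):
        for _ in range(300):
            inner = random_interval(rng, hi=190)
            ds = int(rng.integers(0, 10))
            de = int(rng.integers(0, 10))
            outer_s = max(0, inner.start - ds)
            outer_e = min(200, inner.end + de)
            si, ei = project_to_feature_map(inner.start, inner.end, 50, 200)
            so, eo = project_to_feature_map(outer_s, outer_e, 50, 200)
            assert so <= si and ei <= eo


class TestAdaptivePool:
    def test_identity_when_sizes_match(self, rng):
        x = rng.standard_normal((8, 32))
        np.testing.assert_allclose(adaptive_avg_pool(x, 8), x)

    def test_constant_rows(self):
        x = np.tile(np.arange(32.0), (16, 1))
        out = adaptive_avg_pool(x, 8)
        np.testing.assert_allclose(out, np.tile(np.arange(32.0), (8, 1)))

    def test_bins_match_direct_partition(self, rng):
        x = rng.standard_normal((10, 4))
        out = adaptive_avg_pool(x, 4)
        # as-equal-as-possible contiguous bins of 10 rows into 4: 3,3,2,2
        expected = np.vstack([x[0:3].mean(0), x[3:6].mean(0),
                              x[6:8].mean(0), x[8:10].mean(0)])
        np.testing.assert_allclose(out, expected)

    def test_upsampling_repeats_nearest(self, rng):
        x = rng.standard_normal((3, 5))
        out = adaptive_avg_pool(x, 8)
        # width-1 bins with nearest (floor) assignment
        idx = [(j * 3) // 8 for j in range(8)]
        np.testing.assert_allclose(out, x[idx])

    def test_global_mean_preserved_when_divisible(self, rng):
        x = rng.standard_normal((24, 32))
        out = adaptive_avg_pool(x, 8)
        np.testing.assert_allclose(out.mean(axis=0), x.mean(axis=0),
                                   atol=1e-9)


class TestLossL2:
    def test_perfect_one_hot_zero(self):
        dist = np.eye(3)[[0, 1, 2, 1]]
        assert loss_l2(dist, [0, 1, 2, 1]) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_log3(self):
        dist = np.full((4, 3), 1 / 3)
        assert loss_l2(dist, [0, 2, 1, 0]) == pytest.approx(np.log(3))

    def test_matches_hand_sum(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 6))
            raw = rng.random((n, 4)) + 1e-3
            dist = raw / raw.sum(axis=1, keepdims=True)
            labels = rng.integers(0, 4, size=n)
            by_hand = -sum(np.log(dist[i, labels[i]]) for i in range(n)) / n
            assert loss_l2(dist, labels) == pytest.approx(by_hand)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            loss_l2(np.full((2, 3), 1 / 3), [0, 1, 2])


class TestJointTraining:
    def test_loss_trace_decreases(self, trained_recognizer):
        trace = trained_recognizer.joint_loss_trace_
        assert trace[-1] < trace[0]

    def test_classes_none_last(self, trained_recognizer):
        assert trained_recognizer.classes_[-1] == NONE_LABEL
        assert set(trained_recognizer.classes_) == {"serve", "swing",
                                                    NONE_LABEL}

    def test_zero_jitter_keeps_gt_verbatim(self, trained_detector,
                                           np_records):
        rec = IntervalRecognizer(gt_jitter=0, epochs=1, random_state=0)
        rec.detector_ = trained_detector
        rec.classes_ = ["serve", "swing", NONE_LABEL]
        seq, anns = np_records[0]
        vimg, grid, _t = trained_detector.prepare_record(seq, anns)
        fmap = trained_detector.encode_features(vimg)
        logits, offsets = trained_detector._heads(fmap)
        cands = rec._joint_candidates(grid, logits, offsets, anns,
                                      vimg.source_len,
                                      np.random.default_rng(0))
        for a in anns:
            assert (float(a.start), float(a.end)) in cands

    def test_requires_pretrained_detector(self, np_records):
        with pytest.raises(ValueError):
            IntervalRecognizer().fit(np_records[:2], detector=None)

    def test_train_joint_wrapper(self, np_records, trained_detector):
        rec = IntervalRecognizer(epochs=1, random_state=0)
        det, rec = train_joint(trained_detector, rec, np_records[:4])
        assert rec.joint_loss_trace_


class TestDetectAndRecognize:
    def test_output_contracts(self, trained_recognizer, np_records):
        seq, _ = np_records[20]
        dets = trained_recognizer.detect_and_recognize(seq)
        for d in dets:
            assert d.interval.label in ("serve", "swing")
            assert 0 <= d.interval.start < d.interval.end <= seq.n_samples
            assert d.class_probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_duplicate_candidates_same_distribution(self, trained_recognizer,
                                                    np_records):
        seq, anns = np_records[0]
        det = trained_recognizer.detector_
        from actiseg.io import preprocess, to_virtual_image
        vimg = to_virtual_image(preprocess(seq))
        fmap = det.encode_features(vimg)
        c = ScoredDetection(IntervalAnnotation(anns[0].start, anns[0].end), 1.0)
        dists = trained_recognizer.classify_candidates(
            fmap, [c, c], vimg.source_len)
        np.testing.assert_allclose(dists[0], dists[1])
        np.testing.assert_allclose(dists.sum(axis=1), 1.0, atol=1e-6)

    def test_pure_noise_low_confidence(self, trained_recognizer, rng):
        # per-recording standardization makes a burst-free record look
        # loud, so spurious candidates can appear; none of them should
        # carry the near-certain confidence real bursts get (~0.99)
        for _ in range(3):
            noise = SensorSequence(rng.standard_normal((6, 500)))
            dets = trained_recognizer.detect_and_recognize(noise)
            assert all(d.score < 0.75 for d in dets)

    def test_classifies_gt_interval_correctly(self, trained_recognizer,
                                              np_records):
        # a ground-truth burst on a held-out record classifies as its label
        from actiseg.io import preprocess, to_virtual_image
        hits = total = 0
        for seq, anns in np_records[20:]:
            det = trained_recognizer.detector_
            vimg = to_virtual_image(preprocess(seq))
            fmap = det.encode_features(vimg)
            cands = [ScoredDetection(IntervalAnnotation(a.start, a.end), 1.0)
                     for a in anns]
            dists = trained_recognizer.classify_candidates(
                fmap, cands, vimg.source_len)
            for a, dist in zip(anns, dists):
                total += 1
                pred = trained_recognizer.classes_[int(np.argmax(dist))]
                hits += (pred == a.label and dist.max() > 0.5)
        assert hits / total >= 0.8
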
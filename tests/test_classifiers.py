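"""Handcrafted features, cycle classifiers and sliding-window baselines."""

import numpy as np
import pytest
import pywt

from actiseg.classifiers import (NONE_LABEL, CNNCycleClassifier,
                                 ClassicalCycleClassifier, SlidingWindowSpec,
                                 extract_features, fit_classical,
                                 make_classifier, sliding_window_baseline,
                                 train_sliding_baseline, window_starts)
from actiseg.io import SensorSequence, resample_to_length
from actiseg.simulate import simulate_wp_cms, harvest_none_segments


def filterbank_detail_sums(row, wavelet="db4"):
    """Independent DWT via explicit filter-bank convolution with the
    wavelet's decomposition filters (symmetric padding, downsample by 2)."""
    w = pywt.Wavelet(wavelet)
    lo, hi = np.array(w.dec_lo), np.array(w.dec_hi)
    flen = len(lo)

    def one_level(x):
        p = flen - 1
        xp = np.concatenate([x[:p][::-1], x, x[-p:][::-1]])
        out_len = (len(x) + flen - 1) // 2
        a = np.convolve(xp, lo, mode="full")[flen::2][:out_len]
        d = np.convolve(xp, hi, mode="full")[flen::2][:out_len]
        return a, d

    a1, d1 = one_level(np.asarray(row, float))
    _a2, d2 = one_level(a1)
    return d1.sum(), d2.sum()


class TestExtractFeatures:
    def test_shape_and_finite(self, rng):
        f = extract_features(rng.standard_normal((6, 50)))
        assert f.shape == (41,)
        assert np.all(np.isfinite(f))

    def test_zero_segment(self):
        f = extract_features(np.zeros((6, 32)))
        np.testing.assert_allclose(f, 0.0)

    def test_equal_neighbours_correlate_one(self, rng):
        seg = rng.standard_normal((6, 40))
        seg[1] = seg[0]
        f = extract_features(seg)
        assert f[36] == pytest.approx(1.0)  # first adjacent pair

    def test_against_per_statistic_oracles(self, rng):
        for _ in range(100):
            L = int(rng.integers(16, 120))
            seg = rng.standard_normal((6, L))
            f = extract_features(seg)
            for c in range(6):
                row = seg[c]
                base = 6 * c
                assert f[base + 0] == pytest.approx(np.mean(row), abs=1e-9)
                assert f[base + 1] == pytest.approx(np.sum(row ** 2), abs=1e-9)
                assert f[base + 2] == pytest.approx(np.var(row), abs=1e-9)
                assert f[base + 3] == pytest.approx(
                    np.percentile(row, 75) - np.percentile(row, 25), abs=1e-9)
                d1, d2 = filterbank_detail_sums(row)
                assert f[base + 4] == pytest.approx(d1, abs=1e-6)
                assert f[base + 5] == pytest.approx(d2, abs=1e-6)
            for k in range(5):
                r = np.corrcoef(seg[k], seg[k + 1])[0, 1]
                assert f[36 + k] == pytest.approx(r, abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            extract_features(np.zeros((6, 3)))


@pytest.fixture(scope="module")
def cycle_data():
    records = simulate_wp_cms(8, n_cycles_per_stroke=5, rng_seed=21)
    segs, labels = [], []
    for r in records:
        for c in r.cycles:
            segs.append(r.seq.data[:, c.start:c.end])
            labels.append(c.label)
    nones = harvest_none_segments(records, n=len(segs) // 4, rng_seed=2)
    return segs + nones, labels + [NONE_LABEL] * len(nones)


class TestCNNClassifier:
    def test_initial_loss_is_log_classes(self, cycle_data):
        segs, labels = cycle_data
        clf = CNNCycleClassifier(epochs=0, random_state=0)
        # epochs=0 builds the (zero-initialised) head without training
        clf.fit(segs[:20], labels[:20])
        dist = clf.predict_proba_one(segs[0])
        n = len(clf.classes_)
        np.testing.assert_allclose(dist, 1.0 / n, atol=1e-12)
        from actiseg.recognizer import loss_l2
        assert loss_l2(np.tile(dist, (5, 1)), [0] * 5) == pytest.approx(
            np.log(n))

    def test_deterministic_given_seed(self, cycle_data):
        segs, labels = cycle_data
        a = CNNCycleClassifier(epochs=2, random_state=3).fit(
            segs[:40], labels[:40])
        b = CNNCycleClassifier(epochs=2, random_state=3).fit(
            segs[:40], labels[:40])
        np.testing.assert_array_equal(a.fc_.W, b.fc_.W)
        np.testing.assert_array_equal(a.net_.layers[0].W, b.net_.layers[0].W)

    def test_resampled_cycles_predict_alike(self, cycle_data):
        segs, labels = cycle_data
        clf = CNNCycleClassifier(epochs=8, random_state=0).fit(segs, labels)
        seg = segs[0]
        stretched = resample_to_length(seg, 2 * seg.shape[1])
        d1 = clf.predict_proba_one(seg)
        d2 = clf.predict_proba_one(stretched)
        # both resample to the same 128-sample input up to interpolation error
        np.testing.assert_allclose(d1, d2, atol=2e-2)

    def test_single_class_rejected(self, cycle_data):
        segs, labels = cycle_data
        with pytest.raises(ValueError):
            CNNCycleClassifier().fit(segs[:5], ["freestyle"] * 5)

    def test_high_accuracy_on_clean_cycles(self):
        train = simulate_wp_cms(6, n_cycles_per_stroke=5, rng_seed=31,
                                noise_sd=0.0)
        test = simulate_wp_cms(3, n_cycles_per_stroke=5, rng_seed=32,
                               noise_sd=0.0)

        def cycles(recs):
            return ([r.seq.data[:, c.start:c.end] for r in recs
                     for c in r.cycles],
                    [c.label for r in recs for c in r.cycles])

        Xtr, ytr = cycles(train)
        Xte, yte = cycles(test)
        clf = CNNCycleClassifier(epochs=15, random_state=0).fit(Xtr, ytr)
        acc = np.mean([p == l for p, l in zip(clf.predict(Xte), yte)])
        assert acc >= 0.95


class TestClassicalClassifiers:
    def test_one_nn_memorizes_training_set(self, cycle_data):
        segs, labels = cycle_data
        clf = ClassicalCycleClassifier(kind="knn").fit(segs, labels)
        preds = clf.predict(segs)
        assert preds == list(labels)

    def test_deterministic(self, cycle_data):
        segs, labels = cycle_data
        a = fit_classical("rf", segs[:60], labels[:60], random_state=1)
        b = fit_classical("rf", segs[:60], labels[:60], random_state=1)
        assert a.predict(segs[60:80]) == b.predict(segs[60:80])

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            fit_classical("lda", [], [])
        with pytest.raises(ValueError):
            make_classifier("boosted-stump")

    def test_svm_grid_search_runs(self, cycle_data):
        segs, labels = cycle_data
        clf = ClassicalCycleClassifier(
            kind="svm", svm_C_grid=(1.0, 10.0),
            svm_gamma_grid=(0.01, 0.1)).fit(segs, labels)
        assert set(clf.best_params_) == {"C", "gamma"}
        dist = clf.predict_proba_one(segs[0])
        assert dist.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("kind", ["knn", "nb", "rf", "svm"])
    def test_all_kinds_accurate_on_low_noise_cycles(self, kind):
        train = simulate_wp_cms(6, n_cycles_per_stroke=5, rng_seed=41,
                                noise_sd=0.05)
        test = simulate_wp_cms(3, n_cycles_per_stroke=5, rng_seed=42,
                               noise_sd=0.05)

        def cycles(recs):
            return ([r.seq.data[:, c.start:c.end] for r in recs
                     for c in r.cycles],
                    [c.label for r in recs for c in r.cycles])

        Xtr, ytr = cycles(train)
        Xte, yte = cycles(test)
        clf = make_classifier(kind, random_state=0).fit(Xtr, ytr)
        acc = np.mean([p == l for p, l in zip(clf.predict(Xte), yte)])
        assert acc >= 0.9


class TestSlidingWindows:
    def test_window_count_arithmetic(self):
        spec = SlidingWindowSpec(lengths=(60,), overlap=0.4)
        starts = window_starts(500, 60, spec.stride(60))
        assert len(starts) == (500 - 60) // 36 + 1 == 13

    def test_signal_shorter_than_window(self):
        assert window_starts(40, 60, 36) == []

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            SlidingWindowSpec(lengths=(0,))
        with pytest.raises(ValueError):
            SlidingWindowSpec(overlap=1.0)

    def test_baseline_detections_contract(self, np_records):
        spec = SlidingWindowSpec(lengths=(30, 50), overlap=0.4)
        clfs = train_sliding_baseline(np_records[:8], spec, mode="assw",
                                      kind="nb", random_state=0)
        assert set(clfs) == {30, 50}
        dets = sliding_window_baseline(np_records[8][0], spec, clfs)
        for d in dets:
            assert d.interval.label != NONE_LABEL
            assert d.interval.length in (30, 50)
        from actiseg.anchors import iou
        for i, a in enumerate(dets):
            for b in dets[i + 1:]:
                assert iou(a.interval.start, a.interval.end,
                           b.interval.start, b.interval.end) <= 0.3
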
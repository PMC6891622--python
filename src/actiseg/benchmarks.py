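"""Reproducible study-scale experiments on synthetic data.

These functions bundle the full experimental designs the package is
meant to support — subject-wise splits, two-stage detector training,
sliding-window baselines, classification-guided periodic matching with
every classifier kind — at problem sizes that run in minutes on one
CPU.  They are what the acceptance script and the heavier tests call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .classifiers import (NONE_LABEL, SlidingWindowSpec, make_classifier,
                          sliding_window_baseline, train_sliding_baseline)
from .detector import IntervalDetector
from .evaluation import map_over_classes, proposal_recall
from .matching import MatcherConfig, run_matching
from .recognizer import IntervalRecognizer
from .simulate import (WPRecord, default_wp_strokes, harvest_none_segments,
                       simulate_np_cms, simulate_wp_cms, split_by_subject)


def _subject_split(records, test_fold: int = 0, n_folds: int = 4,
                   seed: int = 0):
    """Subject-wise train/test split of (seq, anns) records."""
    folds = split_by_subject(records, n_folds, rng_seed=seed)
    test_subjects = set(folds[test_fold])
    train = [r for r in records if r[0].subject_id not in test_subjects]
    test = [r for r in records if r[0].subject_id in test_subjects]
    return train, test


@dataclass
class NPBenchmarkResult:
    proposal_recall_top5: float
    map_interval: float
    map_assw: Optional[float] = None
    map_flsw: Optional[float] = None
    recall_assw: Optional[float] = None
    recall_flsw: Optional[float] = None
    n_train: int = 0
    n_test: int = 0


def np_detection_benchmark(seed: int = 0, n_records: int = 260,
                           detector_epochs: int = 25,
                           joint_epochs: int = 12,
                           with_baselines: bool = True
                           ) -> NPBenchmarkResult:
    """Train the interval pipeline on synthetic non-periodic records and
    evaluate on a held-out subject fold; optionally run the ASSW and
    FLSW sliding-window baselines on the same fold.

    Defaults: 260 ten-second records over 12 subjects, one subject fold
    (~1/4) held out, so training uses roughly 200 records.
    """
    records = simulate_np_cms(n_records, rng_seed=seed)
    train, test = _subject_split(records, seed=seed)
    detector = IntervalDetector(epochs=detector_epochs, random_state=seed)
    detector.fit(train)
    recognizer = IntervalRecognizer(epochs=joint_epochs, random_state=seed)
    recognizer.fit(train, detector=detector)

    test_seqs = [seq for seq, _ in test]
    test_gts = [anns for _, anns in test]
    top5 = [detector.generate_candidates(s, top_n=5) for s in test_seqs]
    recall5 = proposal_recall(top5, test_gts)
    dets = [recognizer.detect_and_recognize(s) for s in test_seqs]
    m_interval, _ = map_over_classes(dets, test_gts, 0.5)

    result = NPBenchmarkResult(proposal_recall_top5=recall5,
                               map_interval=m_interval,
                               n_train=len(train), n_test=len(test))
    if with_baselines:
        assw_spec = SlidingWindowSpec(lengths=(30, 40, 50), overlap=0.4)
        flsw_spec = SlidingWindowSpec(lengths=(60,), overlap=0.4)
        assw = train_sliding_baseline(train, assw_spec, mode="assw",
                                      random_state=seed)
        flsw = train_sliding_baseline(train, flsw_spec, mode="flsw",
                                      random_state=seed)
        d_assw = [sliding_window_baseline(s, assw_spec, assw)
                  for s in test_seqs]
        d_flsw = [sliding_window_baseline(s, flsw_spec, flsw)
                  for s in test_seqs]
        result.map_assw, _ = map_over_classes(d_assw, test_gts, 0.5)
        result.map_flsw, _ = map_over_classes(d_flsw, test_gts, 0.5)
        result.recall_assw = proposal_recall(d_assw, test_gts)
        result.recall_flsw = proposal_recall(d_flsw, test_gts)
    return result


# ---------------------------------------------------------------------------
# weakly periodic benchmarks


def dominant_gt_label(record: WPRecord, start: int, end: int) -> Optional[str]:
    """Ground-truth stroke with the largest overlap with [start, end)."""
    best, best_ov = None, 0
    for c in record.cycles:
        ov = min(end, c.end) - max(start, c.start)
        if ov > best_ov:
            best, best_ov = c.label, ov
    return best


def cycle_training_set(records: Sequence[WPRecord], none_fraction: float = 1 / 3,
                       seed: int = 0):
    """Ground-truth cycles plus harvested 'None' material."""
    segs, labels = [], []
    for r in records:
        for c in r.cycles:
            segs.append(r.seq.data[:, c.start:c.end])
            labels.append(c.label)
    nones = harvest_none_segments(records, n=int(len(segs) * none_fraction),
                                  rng_seed=seed)
    return segs + nones, labels + [NONE_LABEL] * len(nones)


def fixed_window_set(records: Sequence[WPRecord], window_len: int = 125,
                     overlap: float = 0.5):
    """Fixed-length windows labeled by their dominant ground-truth stroke
    (the conventional sliding-window segmentation: 2.5 s, overlap 0.5)."""
    stride = max(1, int(round(window_len * (1 - overlap))))
    segs, labels = [], []
    for r in records:
        T = r.seq.n_samples
        for s in range(0, T - window_len + 1, stride):
            label = dominant_gt_label(r, s, s + window_len)
            if label is None:
                continue
            segs.append(r.seq.data[:, s:s + window_len])
            labels.append(label)
    return segs, labels


def default_matcher_config(strokes=None) -> MatcherConfig:
    strokes = strokes or default_wp_strokes()
    periods = [s.base_period for s in strokes]
    return MatcherConfig(window_len=3 * max(periods), gap=min(periods))


@dataclass
class WPBenchmarkResult:
    accuracy_matching: dict[str, float] = field(default_factory=dict)
    accuracy_fixed: dict[str, float] = field(default_factory=dict)
    n_segments: dict[str, int] = field(default_factory=dict)
    n_windows: int = 0


def wp_segmentation_benchmark(seed: int = 0, kinds: Sequence[str] =
                              ("cnn", "knn", "nb", "rf", "svm"),
                              n_train: int = 12, n_test: int = 6,
                              n_cycles_per_stroke: int = 6,
                              cnn_epochs: int = 15) -> WPBenchmarkResult:
    """Per-classifier accuracy with periodic-matching segmentation versus
    fixed 2.5-s / 0.5-overlap windows, on the same synthetic test set.

    With matching, each classifier both gates the matcher and labels the
    resulting single-cycle segments; accuracy is scored against the
    dominant-overlap ground-truth stroke.  Without matching, the same
    classifier kind is trained and evaluated on the fixed windows.
    """
    train = simulate_wp_cms(n_train, n_cycles_per_stroke=n_cycles_per_stroke,
                            rng_seed=seed)
    test = simulate_wp_cms(n_test, n_cycles_per_stroke=n_cycles_per_stroke,
                           rng_seed=seed + 1_000_003)
    tr_segs, tr_labels = cycle_training_set(train, seed=seed)
    tr_w, tr_wl = fixed_window_set(train)
    te_w, te_wl = fixed_window_set(test)
    cfg = default_matcher_config()
    result = WPBenchmarkResult(n_windows=len(te_w))
    for kind in kinds:
        kw = {"epochs": cnn_epochs} if kind == "cnn" else {}
        clf_m = make_classifier(kind, random_state=seed, **kw)
        clf_m.fit(tr_segs, tr_labels)
        correct = total = 0
        for r in test:
            for s in run_matching(r.seq, clf_m, cfg):
                total += 1
                correct += (s.label == dominant_gt_label(r, s.start, s.end))
        result.accuracy_matching[kind] = correct / total if total else 0.0
        result.n_segments[kind] = total
        clf_w = make_classifier(kind, random_state=seed, **kw)
        clf_w.fit(tr_w, tr_wl)
        preds = clf_w.predict(te_w)
        result.accuracy_fixed[kind] = float(
            np.mean([p == l for p, l in zip(preds, te_wl)]))
    return result


@dataclass
class CycleRecoveryResult:
    blocks: int
    count_errors: int            # blocks whose recovered count differs
    total_abs_count_error: int
    period_mae: float            # mean over blocks of |mean consensus - mean true|


def cycle_recovery_benchmark(seed: int = 0, n_blocks: int = 50,
                             n_cycles: int = 8, jitter_sd: float = 0.0,
                             noise_sd: float = 0.0) -> CycleRecoveryResult:
    """Single-stroke blocks with an oracle label: does the matcher
    recover every cycle and the right period?

    With ``jitter_sd = 0`` and no noise, recovered counts must equal the
    simulated counts exactly; with jitter the consensus period should
    track the true mean period closely.
    """
    strokes = default_wp_strokes()
    count_errors = total_err = 0
    maes = []
    for b in range(n_blocks):
        stroke = strokes[b % len(strokes)]
        stroke.period_jitter_sd = jitter_sd
        rec = simulate_wp_cms(1, strokes=[stroke], n_cycles_per_stroke=n_cycles,
                              rng_seed=seed * 1_000 + b, noise_sd=noise_sd,
                              shuffle_blocks=False)[0]
        cfg = MatcherConfig(window_len=3 * stroke.base_period,
                            gap=max(stroke.base_period - 10, 2))
        segs = run_matching(rec.seq, lambda s, lab=stroke.label: lab, cfg)
        err = abs(len(segs) - len(rec.cycles))
        count_errors += err > 0
        total_err += err
        if segs:
            true_mean = np.mean([c.length for c in rec.cycles])
            est_mean = np.mean([s.consensus_period for s in segs])
            maes.append(abs(est_mean - true_mean))
        else:
            maes.append(np.nan)
    return CycleRecoveryResult(blocks=n_blocks, count_errors=count_errors,
                               total_abs_count_error=total_err,
                               period_mae=float(np.nanmean(maes)))
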
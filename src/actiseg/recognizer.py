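"""Shared-convolution recognition of candidate intervals (Net_2).

Instead of re-convolving the signal inside every candidate interval,
the recognizer reuses the detector's feature map: each candidate is
projected onto feature coordinates (stride-4 sampling of the input),
its feature slice is adaptively average-pooled to a fixed length
``ls``, and a fully connected softmax head assigns one of ``C + 1``
classes — the C target motion states plus "None" for candidates that
match no ground truth.

Training is the second, joint stage: the detector loss L1 and the
recognition cross-entropy L2 are minimised together, with gradients
from both flowing into the shared encoder.  The recognition head is
fed the union of the detector's current candidates and the ground
truth with a mild random jitter, so it keeps seeing high-quality
intervals even when the detector is still weak.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from . import _nn
from .anchors import (N_ANCHOR_SCALES, ScoredDetection, decode_interval,
                      iou, nms)
from .detector import IntervalDetector
from .io import IntervalAnnotation, SensorSequence, preprocess, to_virtual_image

NONE_LABEL = "None"

__all__ = ["IntervalRecognizer", "project_to_feature_map",
           "adaptive_avg_pool", "loss_l2", "train_joint",
           "detect_and_recognize", "NONE_LABEL"]


def project_to_feature_map(start: float, end: float, lf: int, los: int
                           ) -> tuple[int, int]:
    """Map a sample interval onto feature-map coordinates.

    The feature map samples the signal at rate ``lf / los``; the start
    is floored and the end is ceiled so that the projected span always
    covers the interval, is non-degenerate, and is monotone under
    interval inclusion.
    """
    if not (0 <= start < end <= los):
        raise ValueError(f"interval [{start}, {end}) outside signal [0, {los})")
    scale = lf / los
    xstaf = int(np.floor(start * scale))
    xendf = int(np.ceil(end * scale))
    xstaf = min(xstaf, lf - 1)
    xendf = min(max(xendf, xstaf + 1), lf)
    return xstaf, xendf


def _pool_bins(w: int, ls: int) -> list[np.ndarray]:
    if w >= ls:
        return np.array_split(np.arange(w), ls)
    # fewer features than bins: width-1 bins with nearest assignment
    return [np.array([min(w - 1, (j * w) // ls)]) for j in range(ls)]


def adaptive_avg_pool(fmap_slice: np.ndarray, ls: int) -> np.ndarray:
    """Average-pool a ``w x d`` feature slice into ``ls x d`` contiguous,
    as-equal-as-possible bins (variable-step average pooling)."""
    fmap_slice = np.asarray(fmap_slice, float)
    if fmap_slice.ndim != 2 or fmap_slice.shape[0] < 1:
        raise ValueError("fmap_slice must be w x d with w >= 1")
    bins = _pool_bins(fmap_slice.shape[0], ls)
    return np.vstack([fmap_slice[idx].mean(axis=0) for idx in bins])


def loss_l2(distributions: np.ndarray, label_indices: np.ndarray) -> float:
    """Mean cross-entropy of candidate class distributions.

    Zero exactly at one-hot correct predictions.
    """
    distributions = np.asarray(distributions, float)
    label_indices = np.asarray(label_indices, int)
    if distributions.shape[0] != label_indices.shape[0]:
        raise ValueError("distributions/labels length mismatch")
    if distributions.shape[0] == 0:
        return 0.0
    p = np.clip(distributions[np.arange(len(label_indices)), label_indices],
                1e-12, None)
    return float(-np.log(p).mean())


class IntervalRecognizer(BaseEstimator):
    """Candidate-interval classifier sharing the detector's encoder.

    Parameters
    ----------
    ls : int
        Pooled feature length per candidate (the fully connected head
        sees ``ls x 32`` values).
    gt_jitter : int
        Maximum absolute jitter, in samples, applied to ground-truth
        boundaries when feeding them to the head during joint training.
    match_iou : float
        IOU above which a candidate inherits a ground truth's label;
        below it the candidate is labeled "None".
    epochs, lr : joint-training schedule (Adam).
    max_candidates : int
        Cap on detector candidates per record in each joint step.

    Attributes
    ----------
    classes_ : list of class names, "None" last
    joint_loss_trace_ : per-epoch mean of L1 + L2 during joint training
    """

    def __init__(self, ls: int = 8, gt_jitter: int = 4,
                 match_iou: float = 0.5, epochs: int = 15, lr: float = 2e-3,
                 max_candidates: int = 8, random_state: int = 0):
        self.ls = ls
        self.gt_jitter = gt_jitter
        self.match_iou = match_iou
        self.epochs = epochs
        self.lr = lr
        self.max_candidates = max_candidates
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    def _check_fitted(self) -> None:
        if not getattr(self, "fitted_", False):
            raise NotFittedError("IntervalRecognizer is not fitted yet")

    def _pool_candidate(self, fmap: np.ndarray, start: float, end: float,
                        los: int) -> tuple[np.ndarray, tuple[int, int]]:
        lf = fmap.shape[0]
        xstaf, xendf = project_to_feature_map(start, end, lf, los)
        pooled = adaptive_avg_pool(fmap[xstaf:xendf], self.ls)
        return pooled, (xstaf, xendf)

    def _label_index(self, label: str) -> int:
        return self.classes_.index(label)

    def _candidate_label(self, start: float, end: float,
                         gts: list[IntervalAnnotation]) -> str:
        best, best_iou = NONE_LABEL, self.match_iou
        for g in gts:
            v = iou(start, end, g.start, g.end)
            if v > best_iou:
                best, best_iou = g.label, v
        return best

    def classify_candidates(self, fmap: np.ndarray,
                            candidates: list[ScoredDetection],
                            los: int) -> np.ndarray:
        """Class distributions (n x C+1) for projected candidates."""
        self._check_fitted()
        if not candidates:
            return np.zeros((0, len(self.classes_)))
        X = np.vstack([
            self._pool_candidate(fmap, c.interval.start, c.interval.end,
                                 los)[0].ravel()[None, :]
            for c in candidates])
        return _nn.softmax(self.fc_.forward(X), axis=1)

    # -- joint training ---------------------------------------------------

    def fit(self, records, detector: IntervalDetector | None = None,
            classes: list[str] | None = None):
        """Jointly train with a pre-trained detector (stage 2).

        ``records`` is a list of (SensorSequence, annotations).
        """
        if detector is None:
            raise ValueError("fit requires a pre-trained detector")
        detector._check_fitted()
        self.detector_ = detector
        if classes is None:
            seen: list[str] = []
            for _seq, anns in records:
                for a in anns:
                    if a.label not in seen:
                        seen.append(a.label)
            classes = sorted(seen)
        self.classes_ = list(classes) + [NONE_LABEL]
        rng = np.random.default_rng(self.random_state)
        self.fc_ = _nn.Linear(self.ls * 32, len(self.classes_), rng=rng)
        det = detector
        prepared = [(det.prepare_record(seq, anns), anns)
                    for seq, anns in records]
        params = det._parameters() + self.fc_.parameters()
        opt = _nn.Adam(params, lr=self.lr)
        self.joint_loss_trace_ = []
        k = N_ANCHOR_SCALES
        order = np.arange(len(prepared))
        self.fitted_ = True  # weights exist; refined below
        for _epoch in range(self.epochs):
            rng.shuffle(order)
            losses = []
            for idx in order:
                (vimg, grid, targets), anns = prepared[idx]
                los = vimg.source_len
                det._zero_grad()
                self.fc_.zero_grad()
                fmap = det.encode_features(vimg)
                logits, offsets = det._heads(fmap)
                l1, g_logits, g_off = det._head_loss_grads(
                    logits, offsets, targets, rng)
                lf = fmap.shape[0]
                g_fmap = det.score_head_.backward(g_logits.reshape(lf, 2 * k))
                g_fmap += det.offset_head_.backward(g_off.reshape(lf, 2 * k))

                cands = self._joint_candidates(
                    grid, logits, offsets, anns, los, rng)
                l2 = 0.0
                if cands:
                    l2 = self._recognition_step(fmap, g_fmap, cands, anns, los)
                det._backprop_encoder(g_fmap)
                opt.step()
                losses.append(l1 + l2)
            self.joint_loss_trace_.append(float(np.mean(losses)))
        return self

    def _joint_candidates(self, grid, logits, offsets, anns, los, rng
                          ) -> list[tuple[float, float]]:
        """Union of current detector candidates and jittered ground truth."""
        probs = _nn.softmax(logits, axis=1)
        dets: list[ScoredDetection] = []
        for i, anchor in enumerate(grid.anchors):
            if probs[i, 1] <= probs[i, 0]:
                continue
            s, e = decode_interval(anchor.start, anchor.end,
                                   offsets[i, 0], offsets[i, 1],
                                   clip_to=float(los))
            if e - s >= 2:
                dets.append(ScoredDetection(
                    IntervalAnnotation(int(s), int(np.ceil(e))),
                    score=float(probs[i, 1])))
        kept = nms(dets, self.detector_.nms_iou)[:self.max_candidates]
        out = [(float(d.interval.start), float(d.interval.end)) for d in kept]
        j = self.gt_jitter
        for a in anns:
            ds = int(rng.integers(-j, j + 1)) if j > 0 else 0
            de = int(rng.integers(-j, j + 1)) if j > 0 else 0
            s = max(0, a.start + ds)
            e = min(los, a.end + de)
            if e - s < 2:
                s, e = a.start, a.end
            out.append((float(s), float(e)))
        return out

    def _recognition_step(self, fmap, g_fmap, cands, anns, los) -> float:
        """L2 forward/backward; scatters pooled-feature gradients into
        the shared feature-map gradient."""
        feats, spans, labels = [], [], []
        for (s, e) in cands:
            pooled, span = self._pool_candidate(fmap, s, e, los)
            feats.append(pooled.ravel())
            spans.append(span)
            labels.append(self._label_index(self._candidate_label(s, e, anns)))
        X = np.vstack(feats)
        onehot = np.zeros((len(cands), len(self.classes_)))
        onehot[np.arange(len(cands)), labels] = 1.0
        logits2 = self.fc_.forward(X)
        l2, g_logits2 = _nn.softmax_cross_entropy(logits2, onehot)
        gX = self.fc_.backward(g_logits2)
        for ci, (xstaf, xendf) in enumerate(spans):
            g_pooled = gX[ci].reshape(self.ls, 32)
            bins = _pool_bins(xendf - xstaf, self.ls)
            for bi, idx in enumerate(bins):
                g_fmap[xstaf + idx] += g_pooled[bi] / len(idx)
        return l2

    # -- inference --------------------------------------------------------

    def detect_and_recognize(self, seq: SensorSequence,
                             top_n: int | None = None
                             ) -> list[ScoredDetection]:
        """Full pipeline on one sequence: candidates from the detector,
        classification, "None" candidates dropped.

        The returned detections carry the predicted class label, the
        combined confidence (foreground score times class probability)
        and the full class distribution; intervals are in original
        signal coordinates.
        """
        self._check_fitted()
        det = self.detector_
        cands = det.generate_candidates(seq, top_n=top_n)
        if not cands:
            return []
        vimg = to_virtual_image(preprocess(seq, sigma=det.smoothing_sigma))
        fmap = det.encode_features(vimg)
        dists = self.classify_candidates(fmap, cands, vimg.source_len)
        out: list[ScoredDetection] = []
        none_idx = len(self.classes_) - 1
        for c, dist in zip(cands, dists):
            k = int(np.argmax(dist))
            if k == none_idx:
                continue
            labeled = IntervalAnnotation(c.interval.start, c.interval.end,
                                         self.classes_[k])
            out.append(ScoredDetection(labeled,
                                       score=float(c.score * dist[k]),
                                       class_probs=dist))
        return out

    def predict(self, sequences, top_n: int | None = None):
        return [self.detect_and_recognize(s, top_n=top_n) for s in sequences]


def train_joint(detector: IntervalDetector, recognizer: IntervalRecognizer,
                records, config: dict | None = None
                ) -> tuple[IntervalDetector, IntervalRecognizer]:
    """Stage-2 joint training of a pre-trained detector and a recognizer."""
    if config:
        recognizer.set_params(**config)
    recognizer.fit(records, detector=detector)
    return detector, recognizer


def detect_and_recognize(seq: SensorSequence, detector: IntervalDetector,
                         recognizer: IntervalRecognizer,
                         top_n: int | None = None) -> list[ScoredDetection]:
    """Functional form of :meth:`IntervalRecognizer.detect_and_recognize`."""
    assert recognizer.detector_ is detector
    return recognizer.detect_and_recognize(seq, top_n=top_n)
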
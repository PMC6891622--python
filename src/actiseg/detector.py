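"""Anchor-based interval detector for non-periodic motion states.

A shallow convolutional encoder (total horizontal stride 4, 32 feature
channels) scores, at every feature position, ten preset anchor lengths
as foreground/background and regresses two offsets (centre shift, log
width ratio) for foreground anchors.  Decoded candidates are pruned by
non-maximum suppression.  Training minimises

    L1 = Lscore + Loffset

where ``Lscore`` is the softmax cross-entropy over foreground vs
background averaged over all anchors and ``Loffset`` is the smooth-L1
offset regression error averaged over foreground anchors.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from . import _nn
from .anchors import (AnchorGrid, AnchorTargets, ScoredDetection,
                      build_anchor_grid, label_anchors, nms,
                      decode_interval, N_ANCHOR_SCALES)
from .io import (IntervalAnnotation, SensorSequence, VirtualImage,
                 preprocess, to_virtual_image)

__all__ = ["IntervalDetector", "score_loss", "offset_loss", "smooth_l1",
           "detector_loss", "train_detector"]

smooth_l1 = _nn.smooth_l1


def score_loss(p_fg: np.ndarray, p_bg: np.ndarray,
               targets: AnchorTargets) -> float:
    """Foreground/background cross-entropy averaged over all anchors."""
    p_fg, p_bg = np.asarray(p_fg, float), np.asarray(p_bg, float)
    if p_fg.shape != p_bg.shape or len(p_fg) != len(targets.fg):
        raise ValueError("score/target length mismatch")
    fg = targets.fg
    terms = fg * np.log(np.clip(p_fg, 1e-12, None)) + \
        (1 - fg) * np.log(np.clip(p_bg, 1e-12, None))
    return float(-terms.mean())


def offset_loss(offsets: np.ndarray, targets: AnchorTargets) -> float:
    """Smooth-L1 regression error averaged over foreground anchors
    (0 when there are none)."""
    offsets = np.asarray(offsets, float)
    if offsets.shape != (len(targets.fg), 2):
        raise ValueError("offsets must be (Nan, 2)")
    n_fg = int(targets.fg.sum())
    if n_fg == 0:
        return 0.0
    per = _nn.smooth_l1(offsets[:, 0] - targets.alpha) + \
        _nn.smooth_l1(offsets[:, 1] - targets.beta)
    return float((targets.fg * per).sum() / n_fg)


def detector_loss(p_fg, p_bg, offsets, targets) -> float:
    """Total detector loss L1 = Lscore + Loffset."""
    return score_loss(p_fg, p_bg, targets) + offset_loss(offsets, targets)


class IntervalDetector(BaseEstimator):
    """Anchor-based temporal interval detector (scikit-learn style).

    Parameters
    ----------
    fg_threshold : float
        IOU above which an anchor is labeled foreground during training.
    nms_iou : float
        IOU threshold of non-maximum suppression at inference.
    lr, epochs : float, int
        Adam learning rate and number of passes over the training records.
    smoothing_sigma : float
        Gaussian preprocessing width in samples.
    balance_sampling : bool
        When True, background anchors in the score loss are subsampled
        to ``3 x`` the foreground count per record; default follows the
        plain all-anchor average.
    random_state : int
        Seed controlling initialization and record shuffling.

    Attributes
    ----------
    encoder_ : the fitted convolutional encoder (shared with the recognizer)
    loss_trace_ : per-epoch mean training loss
    """

    def __init__(self, fg_threshold: float = 0.5, nms_iou: float = 0.3,
                 lr: float = 2e-3, epochs: int = 30,
                 smoothing_sigma: float = 1.0,
                 balance_sampling: bool = False,
                 random_state: int = 0):
        self.fg_threshold = fg_threshold
        self.nms_iou = nms_iou
        self.lr = lr
        self.epochs = epochs
        self.smoothing_sigma = smoothing_sigma
        self.balance_sampling = balance_sampling
        self.random_state = random_state

    # -- network ----------------------------------------------------------

    def _build(self, rng: np.random.Generator) -> None:
        k = N_ANCHOR_SCALES
        self.encoder_ = _nn.Sequential(
            _nn.Conv2d(1, 16, (8, 7), stride_w=2, pad_w=3, rng=rng),
            _nn.ReLU(),
            _nn.Conv2d(16, 32, (1, 5), stride_w=2, pad_w=2, rng=rng),
            _nn.ReLU(),
            _nn.Conv2d(32, 32, (1, 3), stride_w=1, pad_w=1, rng=rng),
            _nn.ReLU(),
            _nn.Conv2d(32, 32, (1, 3), stride_w=1, pad_w=1, rng=rng),
            _nn.ReLU(),
        )
        # 1x1-convolution heads, applied per feature position
        self.score_head_ = _nn.Linear(32, 2 * k, rng=rng)
        self.offset_head_ = _nn.Linear(32, 2 * k, rng=rng)
        # receptive field of one feature position, in samples
        self.receptive_field_ = 1 + 6 * 1 + 4 * 2 + 2 * 4 + 2 * 4

    def _check_fitted(self) -> None:
        if not getattr(self, "fitted_", False):
            raise NotFittedError("IntervalDetector is not fitted yet")

    def encode_features(self, vimg: VirtualImage) -> np.ndarray:
        """Run the shared encoder; returns the lf x 32 feature map."""
        if vimg.width % 4 != 0:
            raise ValueError("virtual-image width must be a multiple of 4")
        out = self.encoder_.forward(vimg.grid[None, None, :, :])
        return out[0, :, 0, :].T  # (lf, 32)

    def _heads(self, fmap: np.ndarray):
        """Per-anchor logits and offsets from the feature map.

        Returns ``score_logits (Nan, 2)`` ordered like the anchor grid
        (position-major, then scale; columns = (bg, fg)) and
        ``offsets (Nan, 2)`` (columns = (o1, o2))."""
        k = N_ANCHOR_SCALES
        lf = fmap.shape[0]
        logits = self.score_head_.forward(fmap).reshape(lf * k, 2)
        offsets = self.offset_head_.forward(fmap).reshape(lf * k, 2)
        return logits, offsets

    def forward_anchors(self, vimg: VirtualImage):
        """Per-anchor softmax probabilities (p_bg, p_fg) and offsets."""
        self._check_fitted()
        fmap = self.encode_features(vimg)
        logits, offsets = self._heads(fmap)
        return _nn.softmax(logits, axis=1), offsets

    # -- training ---------------------------------------------------------

    def _head_loss_grads(self, logits: np.ndarray, offsets: np.ndarray,
                         targets: AnchorTargets, rng: np.random.Generator):
        """Loss L1 and its gradients w.r.t. head outputs."""
        n = logits.shape[0]
        onehot = np.zeros((n, 2))
        onehot[np.arange(n), targets.fg] = 1.0   # col 0 = bg, col 1 = fg
        if self.balance_sampling:
            n_fg = int(targets.fg.sum())
            weights = targets.fg.astype(float).copy()
            bg_idx = np.flatnonzero(targets.fg == 0)
            take = min(len(bg_idx), max(3 * n_fg, 1))
            weights[rng.choice(bg_idx, size=take, replace=False)] = 1.0
            score_l, g_logits = _nn.softmax_cross_entropy(
                logits, onehot, weights)
        else:
            score_l, g_logits = _nn.softmax_cross_entropy(logits, onehot)
        n_fg = int(targets.fg.sum())
        resid = np.stack([offsets[:, 0] - targets.alpha,
                          offsets[:, 1] - targets.beta], axis=1)
        if n_fg > 0:
            off_l = float((targets.fg[:, None] *
                           _nn.smooth_l1(resid)).sum() / n_fg)
            g_off = targets.fg[:, None] * _nn.smooth_l1_grad(resid) / n_fg
        else:
            off_l, g_off = 0.0, np.zeros_like(offsets)
        return score_l + off_l, g_logits, g_off

    def _loss_and_grads(self, vimg: VirtualImage, targets: AnchorTargets,
                        rng: np.random.Generator):
        """Forward + head backward for one record.  Returns the loss and
        the feature-map gradient (the encoder backward is left to the
        caller so a recognizer loss can be added to the same features)."""
        k = N_ANCHOR_SCALES
        fmap = self.encode_features(vimg)
        logits, offsets = self._heads(fmap)
        loss, g_logits, g_off = self._head_loss_grads(logits, offsets,
                                                      targets, rng)
        lf = fmap.shape[0]
        g_fmap = self.score_head_.backward(g_logits.reshape(lf, 2 * k))
        g_fmap = g_fmap + self.offset_head_.backward(g_off.reshape(lf, 2 * k))
        return loss, fmap, g_fmap

    def _backprop_encoder(self, g_fmap: np.ndarray) -> None:
        self.encoder_.backward(g_fmap.T[None, :, None, :])

    def _zero_grad(self) -> None:
        self.encoder_.zero_grad()
        self.score_head_.zero_grad()
        self.offset_head_.zero_grad()

    def _parameters(self):
        return (self.encoder_.parameters() + self.score_head_.parameters()
                + self.offset_head_.parameters())

    def prepare_record(self, seq: SensorSequence,
                       annotations: list[IntervalAnnotation]):
        """Preprocess one record into (virtual image, grid, targets)."""
        vimg = to_virtual_image(preprocess(seq, sigma=self.smoothing_sigma))
        grid = build_anchor_grid(vimg.width)
        targets = label_anchors(grid, annotations, self.fg_threshold)
        return vimg, grid, targets

    def fit(self, records, y=None):
        """Train on ``records``: a list of (SensorSequence, annotations).

        Raises if no anchor in the whole training set is foreground.
        """
        rng = np.random.default_rng(self.random_state)
        self._build(rng)
        prepared = [self.prepare_record(seq, anns) for seq, anns in records]
        if not any(t.fg.sum() for _, _, t in prepared):
            raise ValueError("training set yields no foreground anchors")
        opt = _nn.Adam(self._parameters(), lr=self.lr)
        self.loss_trace_ = []
        order = np.arange(len(prepared))
        for _epoch in range(self.epochs):
            rng.shuffle(order)
            losses = []
            for idx in order:
                vimg, _grid, targets = prepared[idx]
                self._zero_grad()
                loss, _fmap, g_fmap = self._loss_and_grads(vimg, targets, rng)
                self._backprop_encoder(g_fmap)
                opt.step()
                losses.append(loss)
            self.loss_trace_.append(float(np.mean(losses)))
        self.fitted_ = True
        return self

    # -- inference --------------------------------------------------------

    def generate_candidates(self, seq: SensorSequence,
                            top_n: int | None = 5) -> list[ScoredDetection]:
        """Propose intervals: anchors with p_fg > p_bg, offsets decoded,
        NMS applied, the ``top_n`` best by foreground score kept
        (all survivors when ``top_n`` is None).  Intervals are clipped
        to the unpadded signal extent."""
        self._check_fitted()
        vimg = to_virtual_image(preprocess(seq, sigma=self.smoothing_sigma))
        grid = build_anchor_grid(vimg.width)
        probs, offsets = self.forward_anchors(vimg)
        los = vimg.source_len
        dets: list[ScoredDetection] = []
        for i, anchor in enumerate(grid.anchors):
            p_bg, p_fg = probs[i]
            if p_fg <= p_bg:
                continue
            s, e = decode_interval(anchor.start, anchor.end,
                                   offsets[i, 0], offsets[i, 1],
                                   clip_to=float(los))
            s_i, e_i = int(round(s)), int(round(e))
            if e_i - s_i < 1:
                continue
            dets.append(ScoredDetection(
                IntervalAnnotation(max(s_i, 0), min(e_i, los)),
                score=float(p_fg)))
        kept = nms(dets, self.nms_iou)
        return kept[:top_n] if top_n is not None else kept

    def predict(self, sequences, top_n: int | None = 5):
        """Candidate intervals for each sequence in ``sequences``."""
        return [self.generate_candidates(s, top_n=top_n) for s in sequences]


def train_detector(records, config: dict | None = None) -> IntervalDetector:
    """Functional wrapper: fit an :class:`IntervalDetector` with the given
    config dict (keys = constructor parameters)."""
    return IntervalDetector(**(config or {})).fit(records)
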
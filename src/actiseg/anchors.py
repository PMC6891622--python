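"""Interval anchors: the 1-D analogue of region-proposal candidate boxes.

The encoder maps an ``la``-sample virtual image to ``la / 4`` feature
positions.  At the centre of each position's receptive field we preset
ten candidate intervals ("anchors") with lengths spanning the observed
motion-state durations (16-96 samples at 50 Hz, i.e. 0.32-1.92 s).  An
anchor is *foreground* when its IOU with some ground-truth interval
exceeds 0.5.  Foreground anchors regress two offsets: a centre shift
normalised by the anchor width and a log width ratio; decoding is the
exact algebraic inverse of encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import STRIDE, IntervalAnnotation

#: preset anchor lengths in samples
ANCHOR_LENGTHS = (16, 24, 32, 40, 48, 56, 64, 72, 80, 96)
N_ANCHOR_SCALES = len(ANCHOR_LENGTHS)


@dataclass(frozen=True)
class Anchor:
    """A preset candidate interval tied to one encoder feature position."""

    center: float
    length: int
    feature_index: int

    @property
    def start(self) -> float:
        return self.center - self.length / 2.0

    @property
    def end(self) -> float:
        return self.center + self.length / 2.0


@dataclass
class AnchorGrid:
    """All ``(la/4) * 10`` anchors of a signal, ordered by (position, scale)."""

    la: int
    anchors: list[Anchor]

    def __len__(self) -> int:
        return len(self.anchors)

    @property
    def n_positions(self) -> int:
        return self.la // STRIDE

    def starts_ends(self) -> tuple[np.ndarray, np.ndarray]:
        s = np.array([a.start for a in self.anchors])
        e = np.array([a.end for a in self.anchors])
        return s, e


@dataclass
class AnchorTargets:
    """Per-anchor training targets for the detector loss."""

    fg: np.ndarray            # (Nan,) {0,1}
    alpha: np.ndarray         # (Nan,) defined where fg == 1, else 0
    beta: np.ndarray          # (Nan,)
    matched_gt: list[Optional[IntervalAnnotation]]

    @property
    def bg(self) -> np.ndarray:
        return 1 - self.fg


@dataclass
class ScoredDetection:
    """A decoded candidate interval with its foreground score and, after
    recognition, a class distribution."""

    interval: IntervalAnnotation
    score: float
    class_probs: Optional[np.ndarray] = field(default=None)


def build_anchor_grid(la: int) -> AnchorGrid:
    """Preset 10 anchors at the centre of each stride-4 cell of an
    ``la``-sample signal.  Anchors may extend past the signal bounds;
    they are clipped only at decode time."""
    if la % STRIDE != 0:
        raise ValueError(f"la must be a multiple of {STRIDE}, got {la}")
    anchors = []
    for i in range(la // STRIDE):
        center = STRIDE * i + STRIDE / 2.0
        for length in ANCHOR_LENGTHS:
            anchors.append(Anchor(center=center, length=length, feature_index=i))
    return AnchorGrid(la=la, anchors=anchors)


def iou(a_start: float, a_end: float, b_start: float, b_end: float) -> float:
    """Intersection-over-union of two half-open sample intervals."""
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    union = (a_end - a_start) + (b_end - b_start) - inter
    return inter / union


def iou_matrix(starts_a: np.ndarray, ends_a: np.ndarray,
               starts_b: np.ndarray, ends_b: np.ndarray) -> np.ndarray:
    """Pairwise IOU between interval sets a (rows) and b (columns)."""
    sa = np.asarray(starts_a, float)[:, None]
    ea = np.asarray(ends_a, float)[:, None]
    sb = np.asarray(starts_b, float)[None, :]
    eb = np.asarray(ends_b, float)[None, :]
    inter = np.clip(np.minimum(ea, eb) - np.maximum(sa, sb), 0.0, None)
    union = (ea - sa) + (eb - sb) - inter
    return np.where(inter > 0, inter / union, 0.0)


def encode_offsets(anchor_start: float, anchor_end: float,
                   gt_start: float, gt_end: float) -> tuple[float, float]:
    """Offset targets (alpha, beta) taking the anchor onto the ground truth.

    ``alpha`` is the centre displacement normalised by the anchor width
    (times 2), ``beta`` the log width ratio.  ``decode_interval`` is the
    exact inverse.
    """
    w = anchor_end - anchor_start
    gw = gt_end - gt_start
    if w <= 0 or gw <= 0:
        raise ValueError("intervals must have positive length")
    alpha = (gt_end + gt_start - anchor_end - anchor_start) / w
    beta = float(np.log(gw / w))
    return alpha, beta


def decode_interval(anchor_start: float, anchor_end: float,
                    o1: float, o2: float,
                    clip_to: Optional[float] = None) -> tuple[float, float]:
    """Apply predicted offsets to an anchor: inverse of :func:`encode_offsets`.

    ``o1 = o2 = 0`` returns the anchor unchanged.  When ``clip_to`` is
    given, the result is clipped to ``[0, clip_to]``.
    """
    w = anchor_end - anchor_start
    center = 0.5 * (anchor_start + anchor_end) + o1 * w / 2.0
    new_w = w * float(np.exp(o2))
    s, e = center - new_w / 2.0, center + new_w / 2.0
    if clip_to is not None:
        s = min(max(s, 0.0), clip_to)
        e = min(max(e, 0.0), clip_to)
    return s, e


def label_anchors(grid: AnchorGrid, gts: Sequence[IntervalAnnotation],
                  fg_threshold: float = 0.5) -> AnchorTargets:
    """Assign foreground/background labels and offset targets to a grid.

    An anchor is foreground iff its best IOU over ground truths exceeds
    ``fg_threshold``; it is matched to the argmax-IOU ground truth
    (earliest on ties).
    """
    n = len(grid)
    fg = np.zeros(n, dtype=int)
    alpha = np.zeros(n)
    beta = np.zeros(n)
    matched: list[Optional[IntervalAnnotation]] = [None] * n
    if gts:
        s, e = grid.starts_ends()
        gs = np.array([g.start for g in gts], float)
        ge = np.array([g.end for g in gts], float)
        mat = iou_matrix(s, e, gs, ge)
        best = np.argmax(mat, axis=1)  # argmax takes the earliest on ties
        best_iou = mat[np.arange(n), best]
        for i in range(n):
            if best_iou[i] > fg_threshold:
                g = gts[int(best[i])]
                fg[i] = 1
                matched[i] = g
                alpha[i], beta[i] = encode_offsets(s[i], e[i], g.start, g.end)
    return AnchorTargets(fg=fg, alpha=alpha, beta=beta, matched_gt=matched)


def nms(detections: Sequence[ScoredDetection],
        iou_threshold: float = 0.3) -> list[ScoredDetection]:
    """Greedy non-maximum suppression, highest score first.

    Every surviving pair of intervals has IOU <= ``iou_threshold``;
    the output is sorted by descending score.
    """
    order = sorted(range(len(detections)),
                   key=lambda i: -detections[i].score)
    keep: list[ScoredDetection] = []
    for idx in order:
        d = detections[idx]
        if all(iou(d.interval.start, d.interval.end,
                   k.interval.start, k.interval.end) <= iou_threshold
               for k in keep):
            keep.append(d)
    return keep
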
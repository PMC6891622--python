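"""Classification-guided periodic matching for weakly periodic signals.

The matcher walks along a 6-channel recording extracting one movement
cycle at a time.  At the current position it autocorrelates an
N-sample window of each channel,

    R[i][t] = sum_{n=0}^{N-1} S[i][j+n] * S[i][j+n+t],   t = 0..N-1,

finds each channel's first peak beyond a minimum lag that clears half
of the window's self inner product, and lets the channels vote: lags
that pairwise agree within a tolerance (10 samples by default) form a
cluster, and a cluster of two or more channels yields the consensus
period (the cluster mean).  A classifier then gates the extracted
cycle: only when it recognises a target motion state is the segment
recorded and the scan continued from its end; otherwise the scan steps
forward by the gap ``z`` (nominally the minimum expected period).

Near the end of the record the autocorrelation window no longer fits —
periodicity of the final cycles cannot be confirmed from the signal
ahead of them — so the matcher first shrinks the window and finally
reuses the last confirmed period, still gated by the classifier, to
segment the remaining cycles.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .io import SensorSequence

NONE_LABEL = "None"


class WindowingError(ValueError):
    """Not enough samples for the requested autocorrelation window."""


@dataclass
class MatcherConfig:
    """Tunables of the periodic matcher.

    ``window_len`` should be 2-3 times the maximum expected cycle;
    ``gap`` the minimum expected cycle.  ``min_peak_lag`` defaults to
    ``gap / 2``, excluding the lag-0 neighbourhood where R is maximal
    for smooth signals.
    """

    window_len: int = 300
    gap: int = 50
    peak_threshold_fraction: float = 0.5
    vote_tolerance: int = 10
    min_votes: int = 2
    min_peak_lag: Optional[int] = None
    zero_pad: bool = False
    tail_completion: bool = True

    def __post_init__(self) -> None:
        if self.window_len < 2 or self.gap < 1:
            raise ValueError("window_len must be >= 2 and gap >= 1")
        if not (0 < self.peak_threshold_fraction <= 1):
            raise ValueError("peak_threshold_fraction must be in (0, 1]")
        if self.min_peak_lag is None:
            self.min_peak_lag = max(self.gap // 2, 2)


@dataclass
class CycleSegment:
    """One detected single-cycle span with its predicted motion state."""

    start: int
    end: int
    label: str
    consensus_period: float

    @property
    def length(self) -> int:
        return self.end - self.start


def autocorrelation(data: np.ndarray | SensorSequence, j: int, N: int,
                    zero_pad: bool = False) -> np.ndarray:
    """Windowed autocorrelation of each channel at position ``j``.

    Returns a ``6 x N`` array; lag ``t`` correlates the window with
    itself shifted ``t`` samples, reading ``2N - 1`` samples from ``j``
    (or zero-extending past the end when ``zero_pad``).
    """
    if isinstance(data, SensorSequence):
        data = data.data
    data = np.asarray(data, float)
    T = data.shape[1]
    if j < 0 or N < 1:
        raise WindowingError("need j >= 0 and N >= 1")
    needed = j + 2 * N
    if needed > T:
        if not zero_pad:
            raise WindowingError(
                f"window needs samples through {needed - 1}, record has {T}")
        data = np.pad(data, ((0, 0), (0, needed - T)))
    X = data[:, j:j + 2 * N - 1]
    windows = np.lib.stride_tricks.sliding_window_view(X, N, axis=1)
    base = X[:, :N]
    return np.einsum("ctn,cn->ct", windows, base, optimize=True)


def first_peak(R_row: np.ndarray, threshold: float,
               min_peak_lag: int) -> Optional[int]:
    """Smallest lag >= ``min_peak_lag`` that is a local maximum (strict
    rise, non-strict fall) above ``threshold``; None when absent."""
    R_row = np.asarray(R_row, float)
    n = len(R_row)
    for t in range(max(min_peak_lag, 1), n - 1):
        if R_row[t] > R_row[t - 1] and R_row[t] >= R_row[t + 1] \
                and R_row[t] > threshold:
            return t
    return None


def vote_peaks(lags: Sequence[Optional[float]], vote_tolerance: float = 10,
               min_votes: int = 2) -> Optional[float]:
    """Cross-channel consensus: the mean of the largest cluster of lags
    that pairwise agree within ``vote_tolerance``, provided the cluster
    has at least ``min_votes`` members (ties go to the smaller mean)."""
    present = sorted(v for v in lags if v is not None)
    if not present:
        return None
    best: Optional[list[float]] = None
    for i in range(len(present)):
        cluster = [v for v in present[i:] if v - present[i] <= vote_tolerance]
        if best is None or len(cluster) > len(best):
            best = cluster
    if best is None or len(best) < min_votes:
        return None
    return float(np.mean(best))


def _consensus_at(data: np.ndarray, p: int, N: int,
                  config: MatcherConfig) -> Optional[float]:
    R = autocorrelation(data, p, N, zero_pad=config.zero_pad)
    lags = []
    for row in R:
        thr = config.peak_threshold_fraction * row[0]
        lags.append(first_peak(row, thr, config.min_peak_lag))
    return vote_peaks(lags, config.vote_tolerance, config.min_votes)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def run_matching(seq: SensorSequence | np.ndarray,
                 classifier, config: MatcherConfig) -> list[CycleSegment]:
    """Scan a record and emit non-overlapping, ordered single-cycle
    segments whose labels the classifier accepted.

    ``classifier`` is either a callable ``segment -> label`` or an
    object with ``predict_one(segment) -> label`` (a 6 x L array in,
    a class name out); the label "None" rejects the segment.
    """
    data = seq.data if isinstance(seq, SensorSequence) else np.asarray(seq, float)
    predict = classifier if callable(classifier) else classifier.predict_one
    T = data.shape[1]
    z = config.gap
    segments: list[CycleSegment] = []
    last_period: Optional[int] = None
    p = 0
    while True:
        N = min(config.window_len, (T - p) // 2)
        if N <= config.min_peak_lag + 1:
            break  # window cannot reveal any admissible period
        if last_period is not None and N <= last_period + 1:
            break  # shrunken window cannot confirm the running period; tail
            # completion below takes over from the current position
        period = _consensus_at(data, p, N, config)
        if period is None:
            p += z
            continue
        # single backward re-match to align the cycle start
        floor = segments[-1].end if segments else 0
        p2 = max(p - z // 2, floor, 0)
        p_start = p
        if p2 < p:
            N2 = min(config.window_len, (T - p2) // 2)
            if N2 > config.min_peak_lag + 1:
                period2 = _consensus_at(data, p2, N2, config)
                if period2 is not None:
                    p_start, period = p2, period2
        L = _round_half_up(period)
        if p_start + L > T:
            break
        label = predict(data[:, p_start:p_start + L])
        if label != NONE_LABEL:
            segments.append(CycleSegment(p_start, p_start + L, label,
                                         consensus_period=period))
            last_period = L
            p = max(p_start + L, p + 1)
        else:
            p += z
    if config.tail_completion and last_period is not None:
        while p + last_period <= T:
            label = predict(data[:, p:p + last_period])
            if label == NONE_LABEL:
                break
            segments.append(CycleSegment(p, p + last_period, label,
                                         consensus_period=float(last_period)))
            p += last_period
        else:
            # boundary drift can leave a final cycle slightly shorter than
            # the running period; accept it if the classifier does
            rem = T - p
            if rem >= 0.75 * last_period and rem >= 2:
                label = predict(data[:, p:T])
                if label != NONE_LABEL:
                    segments.append(CycleSegment(
                        p, T, label, consensus_period=float(rem)))
    return segments


def count_cycles(segments: Sequence[CycleSegment]) -> dict[str, int]:
    """Cycle counts per motion state (None-labeled segments excluded)."""
    return dict(Counter(s.label for s in segments if s.label != NONE_LABEL))
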
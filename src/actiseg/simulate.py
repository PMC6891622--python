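"""Seeded generators of annotated synthetic wrist-IMU recordings.

Two recording types are emulated, matching the statistical structure of
the badminton- and swimming-style data the methods were designed for:

* **Non-periodic, complex motion states (NP_CMS)** — background noise
  with embedded labeled bursts of 16-96 samples (0.32-1.92 s at 50 Hz),
  e.g. serves and swings.  Bursts are windowed sinusoid mixtures with
  template-specific frequency bands and channel emphasis.
* **Weakly periodic, complex motion states (WP_CMS)** — concatenated
  stroke blocks; each block repeats a 6-channel cycle waveform whose
  per-cycle period jitters around the stroke's base period (1-2.5 s),
  so the period is locally stable but drifts, and strokes switch
  between blocks.

Everything is reproducible from an integer seed.  The generators make
no claim of biomechanical realism: they reproduce burst durations,
weak periodicity, stroke switching and additive noise, not device
physics (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import N_CHANNELS, SensorSequence, IntervalAnnotation


class GenerationError(RuntimeError):
    pass


def _label_seed(label: str) -> int:
    # stable small seed from a label, for per-template waveform banks
    return sum((i + 1) * ord(c) for i, c in enumerate(label)) % (2 ** 31)


# ---------------------------------------------------------------------------
# non-periodic motion-state bursts


@dataclass
class StateTemplate:
    """Waveform recipe for one non-periodic motion state.

    A burst of duration L is a Hann-windowed sum of ``n_components``
    sinusoids with frequencies drawn from ``freq_range_hz``, scaled per
    channel by ``channel_gains`` times a random factor in [0.5, 1.5].
    """

    label: str
    duration_range: tuple[int, int] = (24, 72)
    freq_range_hz: tuple[float, float] = (3.0, 10.0)
    n_components: int = 3
    amplitude: float = 1.0
    channel_gains: np.ndarray = field(
        default_factory=lambda: np.ones(N_CHANNELS))

    def __post_init__(self) -> None:
        lo, hi = self.duration_range
        if not (16 <= lo <= hi <= 96):
            raise ValueError("duration_range must lie within [16, 96] samples")

    def sample_burst(self, rng: np.random.Generator,
                     sample_rate_hz: float = 50.0) -> np.ndarray:
        """Draw one 6 x L burst."""
        L = int(rng.integers(self.duration_range[0],
                             self.duration_range[1] + 1))
        t = np.arange(L) / sample_rate_hz
        window = np.hanning(L)
        burst = np.zeros((N_CHANNELS, L))
        for _ in range(self.n_components):
            f = rng.uniform(*self.freq_range_hz)
            phase = rng.uniform(0, 2 * np.pi, size=N_CHANNELS)
            amps = self.amplitude * np.asarray(self.channel_gains) * \
                rng.uniform(0.5, 1.5, size=N_CHANNELS)
            burst += amps[:, None] * np.sin(
                2 * np.pi * f * t[None, :] + phase[:, None])
        return burst * window[None, :] / self.n_components * 2.0


def default_np_templates() -> list[StateTemplate]:
    """Two badminton-like states: a low-frequency acceleration-dominant
    'serve' and a faster gyro-dominant 'swing'."""
    return [
        StateTemplate("serve", duration_range=(24, 56),
                      freq_range_hz=(3.0, 5.0), n_components=2,
                      channel_gains=np.array([1.2, 1.2, 1.0, 0.5, 0.5, 0.4])),
        StateTemplate("swing", duration_range=(32, 80),
                      freq_range_hz=(6.0, 10.0), n_components=3,
                      channel_gains=np.array([0.5, 0.4, 0.5, 1.2, 1.0, 1.2])),
    ]


def simulate_np_cms(n_records: int,
                    record_len_s: float = 10.0,
                    templates: Optional[Sequence[StateTemplate]] = None,
                    background_sd: float = 0.3,
                    rng_seed: int = 0,
                    sample_rate_hz: float = 50.0,
                    bursts_per_record: tuple[int, int] = (2, 4),
                    min_gap: int = 8,
                    n_subjects: int = 12,
                    ) -> list[tuple[SensorSequence, list[IntervalAnnotation]]]:
    """Generate NP_CMS records: noise background + k non-overlapping bursts.

    Bursts keep at least ``min_gap`` samples between them; annotations
    give the exact burst extents.  Subjects are assigned round-robin.
    """
    if record_len_s < 4:
        raise GenerationError("records must be at least 4 s long")
    templates = list(templates) if templates else default_np_templates()
    if not templates:
        raise GenerationError("need at least one state template")
    T = int(round(record_len_s * sample_rate_hz))
    max_dur = max(t.duration_range[1] for t in templates)
    if T < max_dur:
        raise GenerationError("record too short for the longest template")
    rng = np.random.default_rng(rng_seed)
    records = []
    for r in range(n_records):
        data = background_sd * rng.standard_normal((N_CHANNELS, T)) \
            if background_sd > 0 else np.zeros((N_CHANNELS, T))
        k = int(rng.integers(bursts_per_record[0], bursts_per_record[1] + 1))
        placed: list[IntervalAnnotation] = []
        for _ in range(k):
            tmpl = templates[int(rng.integers(len(templates)))]
            burst = tmpl.sample_burst(rng, sample_rate_hz)
            L = burst.shape[1]
            for _attempt in range(200):
                start = int(rng.integers(0, T - L + 1))
                if all(start >= a.end + min_gap or start + L + min_gap <= a.start
                       for a in placed):
                    data[:, start:start + L] += burst
                    placed.append(IntervalAnnotation(start, start + L,
                                                     tmpl.label))
                    break
        if not placed:
            raise GenerationError("failed to place any burst")
        placed.sort()
        seq = SensorSequence(data, sample_rate_hz,
                             subject_id=f"S{r % n_subjects:02d}")
        records.append((seq, placed))
    return records


# ---------------------------------------------------------------------------
# weakly periodic stroke cycles


@dataclass
class StrokeTemplate:
    """Cycle recipe for one swim-stroke-like motion state.

    The cycle waveform is a per-channel mixture of the first
    ``n_harmonics`` harmonics of the cycle frequency, with fixed
    amplitudes/phases derived deterministically from the label, so two
    templates with different labels have distinct signatures.
    """

    label: str
    base_period: int = 75
    period_jitter_sd: float = 2.0
    n_harmonics: int = 3
    amplitude: float = 1.0
    #: intra-cycle activity envelope: every cycle has an active "pull"
    #: bump and a quiet "glide" floor, so the signal is periodic but not
    #: stationary within the cycle
    envelope_floor: float = 0.25
    envelope_power: Optional[float] = None
    _amps: np.ndarray = field(default=None, repr=False)
    _phases: np.ndarray = field(default=None, repr=False)

    #: seed of the cycle profile shared by all strokes: the dominant
    #: first harmonic has a common amplitude and channel-phase
    #: signature (all strokes share the gross arm-cycle kinematics),
    #: so strokes are distinguished by their weaker higher harmonics —
    #: the finer intra-cycle detail — and by their period
    _SHARED_PROFILE_SEED = 711

    def __post_init__(self) -> None:
        if not (25 <= self.base_period <= 160):
            raise ValueError("base_period should be roughly 0.5-3 s at 50 Hz")
        bank = np.random.default_rng(_label_seed(self.label))
        shared = np.random.default_rng(self._SHARED_PROFILE_SEED)
        if self._amps is None:
            amps = np.empty((N_CHANNELS, self.n_harmonics))
            amps[:, 0] = shared.uniform(0.7, 1.0, size=N_CHANNELS)
            if self.n_harmonics > 1:
                amps[:, 1:] = bank.uniform(
                    0.1, 0.45, size=(N_CHANNELS, self.n_harmonics - 1))
            self._amps = amps
        if self._phases is None:
            phases = np.empty((N_CHANNELS, self.n_harmonics))
            phases[:, 0] = shared.uniform(0, 2 * np.pi, size=N_CHANNELS)
            if self.n_harmonics > 1:
                phases[:, 1:] = bank.uniform(
                    0, 2 * np.pi, size=(N_CHANNELS, self.n_harmonics - 1))
            self._phases = phases
        if self.envelope_power is None:
            self.envelope_power = float(bank.uniform(1.0, 3.0))

    def cycle(self, period: int) -> np.ndarray:
        """Evaluate one 6 x period cycle; phase runs 0..2*pi and the
        activity envelope returns to its floor at both ends, so adjacent
        cycles join continuously."""
        phase = 2 * np.pi * np.arange(period) / period
        h = np.arange(1, self.n_harmonics + 1)
        # (C, H) x (H, P) harmonic stack
        waves = np.sin(h[None, :, None] * phase[None, None, :]
                       + self._phases[:, :, None])
        sig = (self._amps[:, :, None] * waves).sum(axis=1)
        g = self.envelope_floor
        env = g + (1 - g) * (0.5 * (1 - np.cos(phase))) ** self.envelope_power
        return self.amplitude * sig * env[None, :]


def default_wp_strokes() -> list[StrokeTemplate]:
    """Four stroke templates with overlapping periods (1.3-1.8 s), as
    stroke-duration distributions overlap in practice."""
    return [
        StrokeTemplate("freestyle", base_period=65),
        StrokeTemplate("backstroke", base_period=72),
        StrokeTemplate("breaststroke", base_period=80),
        StrokeTemplate("butterfly", base_period=88),
    ]


@dataclass
class WPRecord:
    """One weakly periodic record with per-cycle ground truth."""

    seq: SensorSequence
    cycles: list[IntervalAnnotation]   # one per cycle, label = stroke

    @property
    def block_labels(self) -> list[str]:
        out = []
        for c in self.cycles:
            if not out or out[-1] != c.label:
                out.append(c.label)
        return out


def simulate_wp_cms(n_records: int,
                    strokes: Optional[Sequence[StrokeTemplate]] = None,
                    n_cycles_per_stroke: int = 8,
                    rng_seed: int = 0,
                    noise_sd: float = 0.1,
                    crossfade: int = 4,
                    shuffle_blocks: bool = True,
                    sample_rate_hz: float = 50.0,
                    n_subjects: int = 16,
                    ) -> list[WPRecord]:
    """Generate WP_CMS records as concatenations of stroke blocks.

    Each block repeats its stroke's cycle waveform ``n_cycles_per_stroke``
    times with per-cycle period ``base_period + N(0, jitter_sd)``; block
    joins are cross-faded over at most ``crossfade`` samples.  Per-cycle
    boundaries are returned as ground truth.
    """
    if n_cycles_per_stroke < 2:
        raise GenerationError("need at least 2 cycles per stroke block")
    strokes = list(strokes) if strokes else default_wp_strokes()
    rng = np.random.default_rng(rng_seed)
    records = []
    for r in range(n_records):
        order = list(range(len(strokes)))
        if shuffle_blocks and len(order) > 1:
            rng.shuffle(order)
        pieces: list[np.ndarray] = []
        cycles: list[IntervalAnnotation] = []
        pos = 0
        for bi in order:
            stroke = strokes[bi]
            block_cols = []
            for _ in range(n_cycles_per_stroke):
                period = int(round(stroke.base_period +
                                   rng.normal(0, stroke.period_jitter_sd)))
                period = max(period, 2)
                block_cols.append(stroke.cycle(period))
                cycles.append(IntervalAnnotation(pos, pos + period,
                                                 stroke.label))
                pos += period
            block = np.concatenate(block_cols, axis=1)
            if crossfade > 0:
                f = min(crossfade, block.shape[1] // 2)
                ramp = np.linspace(0.0, 1.0, f + 2)[1:-1]
                if pieces:
                    block[:, :f] *= ramp[None, :]
                block[:, block.shape[1] - f:] *= ramp[::-1][None, :]
            pieces.append(block)
        data = np.concatenate(pieces, axis=1)
        if noise_sd > 0:
            data = data + noise_sd * rng.standard_normal(data.shape)
        seq = SensorSequence(data, sample_rate_hz,
                             subject_id=f"W{r % n_subjects:02d}")
        records.append(WPRecord(seq=seq, cycles=cycles))
    return records


def harvest_none_segments(records: Sequence[WPRecord], n: int,
                          rng_seed: int = 0) -> list[np.ndarray]:
    """Training material for the 'None' class: windows that are not
    valid single-cycle inputs — either straddling a cycle boundary
    (starting mid-cycle, spanning parts of two cycles) or an aligned
    but partial cycle (half to four-fifths of one period)."""
    rng = np.random.default_rng(rng_seed)
    out: list[np.ndarray] = []
    guard = 0
    while len(out) < n and guard < 50 * n:
        guard += 1
        rec = records[int(rng.integers(len(records)))]
        if len(rec.cycles) < 2:
            continue
        ci = int(rng.integers(len(rec.cycles) - 1))
        a, b = rec.cycles[ci], rec.cycles[ci + 1]
        if rng.random() < 0.5:
            # straddling window: mid-cycle start into the next cycle
            mid = (a.start + a.end) // 2
            L = int(rng.integers(max(a.length, 16), a.length + b.length))
            end = min(mid + L, rec.seq.n_samples)
            if end - mid >= 16:
                out.append(rec.seq.data[:, mid:end])
        else:
            # partial cycle: aligned start, truncated before the period ends
            L = int(rng.uniform(0.5, 0.8) * a.length)
            if L >= 16:
                out.append(rec.seq.data[:, a.start:a.start + L])
    return out


def harvest_np_background(records, n: int, length_range=(16, 96),
                          rng_seed: int = 0) -> list[np.ndarray]:
    """'None' material for NP classifiers: spans of background noise and
    windows misaligned with any annotated burst (IOU <= 0.3)."""
    from .anchors import iou as _iou
    rng = np.random.default_rng(rng_seed)
    out: list[np.ndarray] = []
    guard = 0
    while len(out) < n and guard < 100 * n:
        guard += 1
        seq, anns = records[int(rng.integers(len(records)))]
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        if seq.n_samples <= L:
            continue
        s = int(rng.integers(0, seq.n_samples - L))
        if all(_iou(s, s + L, a.start, a.end) <= 0.3 for a in anns):
            out.append(seq.data[:, s:s + L])
    return out


def split_by_subject(records, n_folds: int, rng_seed: int = 0
                     ) -> list[list[str]]:
    """Partition the subject ids present in ``records`` into ``n_folds``
    near-equal folds (deterministic given the seed).

    ``records`` may contain SensorSequence, (seq, annotations) tuples,
    WPRecord, or raw subject-id strings.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    subjects = []
    for r in records:
        if isinstance(r, str):
            sid = r
        elif isinstance(r, WPRecord):
            sid = r.seq.subject_id
        elif isinstance(r, tuple):
            sid = r[0].subject_id
        else:
            sid = r.subject_id
        if sid not in subjects:
            subjects.append(sid)
    if len(subjects) < n_folds:
        raise ValueError(
            f"{len(subjects)} subjects cannot fill {n_folds} folds")
    rng = np.random.default_rng(rng_seed)
    subjects = sorted(subjects)
    rng.shuffle(subjects)
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for i, sid in enumerate(subjects):
        folds[i % n_folds].append(sid)
    return [sorted(f) for f in folds]
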
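"""Data model, file I/O and signal preprocessing shared by both pipelines.

The raw unit of input is a :class:`SensorSequence`: a 6-channel inertial
recording (triaxial acceleration + triaxial angular velocity) from a
wrist-worn device, channel-major, sampled at 50 Hz by default.  Ground
truth and detections are half-open sample intervals (:class:`IntervalAnnotation`).
The detector consumes the sequence as an 8-row "virtual image"
(:class:`VirtualImage`): the two sensor blocks separated by two all-zero
rows so 2-D convolutions do not mix acceleration and angular-velocity
statistics across the seam, and the time axis zero-padded to a multiple
of the encoder stride (4).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

CHANNELS = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")
N_CHANNELS = 6
#: encoder feature-map stride in samples; the virtual-image width is padded
#: to a multiple of this.
STRIDE = 4
DEFAULT_SAMPLE_RATE_HZ = 50.0


class FormatError(ValueError):
    """Raised when an input file does not have the expected layout."""


@dataclass
class SensorSequence:
    """A 6 x T channel-major inertial recording.

    Parameters
    ----------
    data:
        Array of shape ``(6, T)``; rows are acc_x, acc_y, acc_z,
        gyr_x, gyr_y, gyr_z.
    sample_rate_hz:
        Sampling frequency, 50 Hz for the target device class.
    subject_id:
        Opaque identifier used only for subject-wise data splits.
    """

    data: np.ndarray
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != N_CHANNELS:
            raise FormatError(
                f"sensor data must be 6 x T, got shape {self.data.shape}"
            )
        if self.data.shape[1] < 1:
            raise FormatError("sensor data must contain at least one sample")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("sensor data contains non-finite values")
        if self.sample_rate_hz <= 0:
            raise FormatError("sample_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True, order=True)
class IntervalAnnotation:
    """A labeled half-open sample interval ``[start, end)`` (0-based)."""

    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class VirtualImage:
    """8 x la grid fed to the convolutional encoder.

    Rows 0-2 hold acceleration, rows 3-4 are identically zero, rows 5-7
    hold angular velocity.  ``pad_count`` zero columns were appended so
    that ``la`` is a multiple of the encoder stride.
    """

    grid: np.ndarray
    pad_count: int
    source_len: int = field(default=0)

    @property
    def width(self) -> int:
        return self.grid.shape[1]


# ---------------------------------------------------------------------------
# file I/O


def read_signal_csv(path: str | Path, sample_rate_hz: float | None = None,
                    subject_id: str | None = None) -> SensorSequence:
    """Read a 6-channel signal CSV (header ``acc_x,...,gyr_z``, one sample/row).

    A sidecar ``<name>.meta.json`` with keys ``sample_rate_hz`` /
    ``subject_id`` is honoured when present; explicit arguments win.
    An optional ``time_s`` column is ignored.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except (ValueError, pd.errors.ParserError) as exc:  # pragma: no cover
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in CHANNELS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing channel column(s) {missing}")
    sub = frame.loc[:, list(CHANNELS)]
    coerced = sub.apply(pd.to_numeric, errors="coerce")
    bad = (coerced.isna() & sub.notna()).to_numpy()
    if bad.any():
        row = int(np.argwhere(bad)[0, 0])
        raise FormatError(f"{path}: non-numeric value at data row {row}")
    sub = coerced
    meta = {}
    sidecar = path.with_suffix(".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    rate = sample_rate_hz if sample_rate_hz is not None else float(
        meta.get("sample_rate_hz", DEFAULT_SAMPLE_RATE_HZ))
    subj = subject_id if subject_id is not None else str(meta.get("subject_id", ""))
    return SensorSequence(sub.to_numpy(dtype=float).T, rate, subj)


def write_signal_csv(seq: SensorSequence, path: str | Path,
                     write_sidecar: bool = True) -> None:
    """Write a signal CSV, plus a ``.meta.json`` sidecar with rate/subject."""
    path = Path(path)
    pd.DataFrame(seq.data.T, columns=list(CHANNELS)).to_csv(path, index=False)
    if write_sidecar:
        path.with_suffix(".meta.json").write_text(json.dumps(
            {"sample_rate_hz": seq.sample_rate_hz, "subject_id": seq.subject_id}))


def read_annotations_tsv(path: str | Path) -> list[IntervalAnnotation]:
    """Read interval annotations: TSV with columns start, end, label."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    for col in ("start", "end", "label"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    out = []
    for _, row in frame.iterrows():
        out.append(IntervalAnnotation(int(row["start"]), int(row["end"]),
                                      str(row["label"])))
    return out


def write_annotations_tsv(annotations: Iterable[IntervalAnnotation],
                          path: str | Path) -> None:
    rows = [(a.start, a.end, a.label) for a in annotations]
    pd.DataFrame(rows, columns=["start", "end", "label"]).to_csv(
        path, sep="\t", index=False)


def read_detections_json(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())


def write_detections_json(detections: Sequence, path: str | Path) -> None:
    """Write detections as a JSON list of {start, end, label, score}."""
    out = []
    for d in detections:
        out.append({"start": int(d.interval.start), "end": int(d.interval.end),
                    "label": d.interval.label, "score": float(d.score)})
    Path(path).write_text(json.dumps(out, indent=1))


# ---------------------------------------------------------------------------
# preprocessing


def normalize_channels(seq: SensorSequence) -> SensorSequence:
    """Standardize each channel to zero mean / unit standard deviation.

    A constant channel maps to all zeros.  Idempotent up to floating
    point round-off.
    """
    if seq.n_samples < 2:
        raise ValueError("normalization needs at least 2 samples")
    mean = seq.data.mean(axis=1, keepdims=True)
    sd = seq.data.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return SensorSequence((seq.data - mean) / sd, seq.sample_rate_hz,
                          seq.subject_id)


def gaussian_smooth(seq: SensorSequence, sigma: float = 1.0) -> SensorSequence:
    """Smooth each channel with a Gaussian kernel (truncated at 4 sigma,
    reflective boundary)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    smoothed = gaussian_filter1d(seq.data, sigma=sigma, axis=1,
                                 mode="reflect", truncate=4.0)
    return SensorSequence(smoothed, seq.sample_rate_hz, seq.subject_id)


def pad_count(original_len: int, stride: int = STRIDE) -> int:
    """Number of zero columns appended so the length becomes a stride multiple."""
    return (-original_len) % stride


def to_virtual_image(seq: SensorSequence) -> VirtualImage:
    """Stack the 6 channels into the 8-row virtual image and pad the width.

    Rows 3 and 4 are zero separators between the acceleration and
    angular-velocity blocks; ``pad_count`` zero columns make the width a
    multiple of the encoder stride (4).
    """
    los = seq.n_samples
    nzs = pad_count(los)
    la = los + nzs
    grid = np.zeros((8, la), dtype=float)
    grid[0:3, :los] = seq.data[0:3]
    grid[5:8, :los] = seq.data[3:6]
    return VirtualImage(grid=grid, pad_count=nzs, source_len=los)


def from_virtual_image(vimg: VirtualImage) -> np.ndarray:
    """Recover the 6 x los channel matrix from a virtual image."""
    los = vimg.width - vimg.pad_count
    return np.vstack([vimg.grid[0:3, :los], vimg.grid[5:8, :los]])


def resample_to_length(segment: np.ndarray, target_len: int) -> np.ndarray:
    """Linearly resample each row of a ``c x L`` segment to ``target_len``.

    The ``target_len`` points are equally spaced over ``[0, L-1]`` so the
    first and last samples are preserved exactly.
    """
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    L = segment.shape[1]
    if L < 2:
        raise ValueError("segment must have at least 2 samples to resample")
    if target_len < 1:
        raise ValueError("target_len must be positive")
    x_new = np.linspace(0.0, L - 1.0, target_len)
    x_old = np.arange(L, dtype=float)
    return np.vstack([np.interp(x_new, x_old, row) for row in segment])


def preprocess(seq: SensorSequence, sigma: float = 1.0) -> SensorSequence:
    """Standard preprocessing chain: per-channel z-score then Gaussian smooth."""
    return gaussian_smooth(normalize_channels(seq), sigma=sigma)
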
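"""ECG loading and conditioning: plain-text I/O, powerline notch
filtering, and manual artifact masking.

The clinical recordings the method targets arrive as ASCII amplitude
columns at a known sampling rate; conditioning removes 60 Hz mains
interference with a zero-phase notch (so R-peak times are not shifted)
and marks manually identified artifact segments in a per-sample mask
that downstream peak detection honours.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .errors import EmptyInputError, FormatError, InvalidArgumentError, ParseError

DEFAULT_NOTCH_FREQ = 60.0   # Hz, mains frequency of the recordings
DEFAULT_NOTCH_QUALITY = 30.0


@dataclass
class ECGRecord:
    """Raw waveform plus sampling rate and artifact mask.

    ``artifact_mask`` is per-sample; ``True`` marks unusable samples.
    """

    fs: float
    samples: np.ndarray
    artifact_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.fs <= 0:
            raise InvalidArgumentError("fs must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if self.artifact_mask.shape != self.samples.shape:
            raise InvalidArgumentError("artifact mask length must equal sample length")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    def masked_intervals(self) -> list[tuple[float, float]]:
        """Maximal runs of masked samples as half-open (start_s, end_s)."""
        m = self.artifact_mask
        if not m.any():
            return []
        edges = np.flatnonzero(np.diff(np.concatenate(([0], m.view(np.int8), [0]))))
        return [(s / self.fs, e / self.fs) for s, e in zip(edges[::2], edges[1::2])]


def read_ecg_text(path, fs: float) -> ECGRecord:
    """Read a one- or two-column ASCII ECG file.

    One column is interpreted as amplitude sampled at ``fs``; two columns
    as (time_s, amplitude), in which case the time column must be
    uniformly spaced consistently with ``fs`` to within 1%.  Comma or
    whitespace delimited; lines starting with ``#`` are comments.
    """
    if fs <= 0:
        raise InvalidArgumentError("fs must be positive")
    with open(path) as fh:
        text = fh.read()

    rows = []
    ncols = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.replace(",", " ").split()
        try:
            values = [float(p) for p in parts]
        except ValueError:
            raise ParseError(f"{path}: non-numeric data on line {lineno}: {stripped!r}")
        if ncols is None:
            if len(values) not in (1, 2):
                raise FormatError(f"{path}: expected 1 or 2 columns, found {len(values)} on line {lineno}")
            ncols = len(values)
        elif len(values) != ncols:
            raise ParseError(f"{path}: inconsistent column count on line {lineno}")
        rows.append(values)

    if not rows:
        raise EmptyInputError(f"{path}: no data rows")
    arr = np.asarray(rows, dtype=float)
    if ncols == 2:
        dt = np.diff(arr[:, 0])
        if arr.shape[0] < 2:
            raise FormatError(f"{path}: two-column input needs >= 2 rows to check spacing")
        expected = 1.0 / fs
        if np.any(dt <= 0) or np.any(np.abs(dt - expected) > 0.01 * expected):
            raise FormatError(f"{path}: time column spacing inconsistent with fs={fs} Hz")
        samples = arr[:, 1]
    else:
        samples = arr[:, 0]
    return ECGRecord(fs=fs, samples=samples,
                     artifact_mask=np.zeros(samples.size, dtype=bool),
                     meta={"source": str(path)})


def write_ecg_text(record: ECGRecord, path) -> None:
    """Write as two-column text (time_s, amplitude), 6 decimal places."""
    data = np.column_stack([record.times, record.samples])
    np.savetxt(path, data, fmt="%.6f", delimiter=",", header="time_s,amplitude")


def notch_filter(record: ECGRecord, notch_freq: float = DEFAULT_NOTCH_FREQ,
                 quality: float = DEFAULT_NOTCH_QUALITY) -> ECGRecord:
    """Zero-phase band-reject filter removing powerline interference.

    Forward-backward application of an IIR notch keeps R-peak timing
    unshifted; the mask and metadata carry over unchanged.
    """
    if notch_freq >= record.fs / 2:
        raise InvalidArgumentError(
            f"notch_freq={notch_freq} must be below the Nyquist frequency {record.fs / 2}")
    if quality <= 0:
        raise InvalidArgumentError("quality must be positive")
    b, a = signal.iirnotch(notch_freq, quality, fs=record.fs)
    filtered = signal.filtfilt(b, a, record.samples)
    return ECGRecord(fs=record.fs, samples=filtered,
                     artifact_mask=record.artifact_mask.copy(), meta=dict(record.meta))


def mask_artifacts(record: ECGRecord, intervals) -> ECGRecord:
    """Mark artifact segments unusable.

    ``intervals`` is a list of half-open ``(start_s, end_s)`` pairs; the
    mask is set on the sample range ``[start, end)``.  Sample values are
    never altered — downstream stages drop R peaks inside masked regions
    and discard R-R intervals bridging them.
    """
    mask = record.artifact_mask.copy()
    n = record.samples.size
    for start, end in intervals:
        if not (0 <= start < end <= record.duration + 0.5 / record.fs):
            raise InvalidArgumentError(
                f"interval ({start}, {end}) outside record duration {record.duration:.3f} s or start >= end")
        i0 = int(np.ceil(start * record.fs - 1e-9))
        i1 = min(int(np.ceil(end * record.fs - 1e-9)), n)
        mask[i0:i1] = True
    return ECGRecord(fs=record.fs, samples=record.samples.copy(),
                     artifact_mask=mask, meta=dict(record.meta))
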
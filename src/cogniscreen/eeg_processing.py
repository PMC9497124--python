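"""Validation, denoising and segmentation of raw single-channel EEG.

The preprocessing chain mirrors common wearable-EEG practice: screen for
electrode-offset artifacts (flatline or amplifier saturation), apply a
zero-phase second-order Butterworth band-pass (default 0.5–30 Hz) plus a
power-line band-stop notch, then cut the trace into fixed-length
overlapping analysis windows (default 5 s with 60 % overlap).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

log = logging.getLogger(__name__)

__all__ = [
    "EEGRecording",
    "SegmentSet",
    "read_eeg_csv",
    "write_eeg_csv",
    "read_eeg_edf",
    "detect_electrode_offset",
    "denoise_eeg",
    "segment_signal",
]


@dataclass
class EEGRecording:
    """One subject's single-channel EEG trace.

    Attributes
    ----------
    samples : ndarray
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    subject_id : str
        Identifier used to join with the other modalities.
    valid : bool
        Whether the recording passed the electrode-offset screen.
    invalid_reasons : tuple of str
        Why the recording was flagged, empty when valid.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    valid: bool = True
    invalid_reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size < 1:
            raise ValueError("recording must contain at least one sample")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class SegmentSet:
    """Fixed-length overlapping windows cut from one recording."""

    segments: np.ndarray  # shape (n_segments, window_samples)
    window_s: float
    overlap_frac: float
    fs: float
    subject_id: str = ""

    def __len__(self) -> int:
        return self.segments.shape[0]


def read_eeg_csv(path, subject_id: str | None = None) -> EEGRecording:
    """Read the EEG CSV dialect: header line ``# fs=<Hz>``, one sample per line."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#") or "fs=" not in header:
            raise ValueError(f"{path}: missing '# fs=<Hz>' header line")
        fs = float(header.split("fs=")[1])
        samples = np.loadtxt(fh, dtype=float, ndmin=1)
    if subject_id is None:
        import os

        subject_id = os.path.basename(os.path.dirname(str(path))) or ""
    return EEGRecording(samples=samples, fs=fs, subject_id=subject_id)


def write_eeg_csv(rec: EEGRecording, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:g}\n")
        fh.write("\n".join(format(v, ".6f") for v in rec.samples))
        fh.write("\n")


def read_eeg_edf(path, channel: int = 0, subject_id: str | None = None) -> EEGRecording:
    """Read channel ``channel`` of an EDF file (requires :mod:`mne`)."""
    import mne  # deferred: only needed for EDF input

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(picks=[channel])[0] * 1e6  # volts -> microvolts
    return EEGRecording(samples=data, fs=float(raw.info["sfreq"]), subject_id=subject_id or "")


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Return (start, length) of each maximal run of True in a boolean array."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def detect_electrode_offset(
    rec: EEGRecording,
    flat_run_s: float = 1.0,
    rail_frac: float = 0.95,
    full_scale_uv: float = 200.0,
) -> EEGRecording:
    """Flag recordings whose electrode was offset or disconnected.

    A recording is invalid when the signal is *flat* (a run of identical
    consecutive samples spanning at least ``flat_run_s`` seconds) or
    *saturated* (|x| at or above ``rail_frac`` of the amplifier full
    scale for at least ``flat_run_s`` seconds).  Shorter bursts are
    tolerated.  Returns a copy with ``valid`` and ``invalid_reasons``
    set; the sample data are never modified.
    """
    x = rec.samples
    if x.size == 0:
        raise ValueError("empty recording")
    min_run = max(int(round(flat_run_s * rec.fs)), 1)
    reasons: list[str] = []

    # A run of k equal consecutive differences spans k+1 samples.
    flat = np.diff(x) == 0
    if any(length + 1 >= min_run for _, length in _bool_runs(flat)):
        reasons.append("flatline")

    rail = np.abs(x) >= rail_frac * full_scale_uv
    if any(length >= min_run for _, length in _bool_runs(rail)):
        reasons.append("saturation")

    if reasons:
        log.info("recording %s flagged invalid: %s", rec.subject_id, ", ".join(reasons))
    return replace(rec, valid=not reasons, invalid_reasons=tuple(reasons))


def denoise_eeg(
    rec: EEGRecording,
    passband: tuple[float, float] = (0.5, 30.0),
    notch: float | None = 50.0,
    order: int = 2,
    notch_width: float = 2.0,
) -> EEGRecording:
    """Band-pass and notch-filter a recording (zero-phase Butterworth).

    Both filters are second order by default and applied forward and
    backward (``sosfiltfilt``) so event timing is preserved for segment
    alignment.  The notch (band-stop ``notch ± notch_width`` Hz) is
    skipped with a log message when it would fall outside the Nyquist
    range.
    """
    low, high = passband
    nyq = rec.fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"passband ({low}, {high}) Hz must satisfy 0 < low < high < fs/2 = {nyq} Hz"
        )
    y = rec.samples
    if notch is not None:
        lo, hi = notch - notch_width, notch + notch_width
        if 0 < lo and hi < nyq:
            sos = signal.butter(order, [lo, hi], btype="bandstop", fs=rec.fs, output="sos")
            y = signal.sosfiltfilt(sos, y)
        else:
            log.info("notch at %g Hz outside Nyquist range for fs=%g, skipped", notch, rec.fs)
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    y = signal.sosfiltfilt(sos, y)
    return replace(rec, samples=y)


def segment_signal(
    rec: EEGRecording, window_s: float = 5.0, overlap_frac: float = 0.6
) -> SegmentSet:
    """Cut a recording into fixed overlapping windows.

    The hop is ``window_s * (1 - overlap_frac)``; the trailing partial
    window is discarded, so a 33 s trace with a 5 s window at 60 %
    overlap yields floor((33-5)/2)+1 = 15 segments.
    """
    if not (0 <= overlap_frac < 1):
        raise ValueError(f"overlap_frac must be in [0, 1), got {overlap_frac}")
    win = int(round(window_s * rec.fs))
    step = int(round(window_s * (1 - overlap_frac) * rec.fs))
    if step < 1:
        raise ValueError("window/overlap combination gives a zero-sample step")
    n = rec.samples.size
    if n < win:
        raise ValueError(
            f"recording shorter than window: {n / rec.fs:g} s < {window_s:g} s"
        )
    count = (n - win) // step + 1
    starts = np.arange(count) * step
    segs = np.stack([rec.samples[s : s + win] for s in starts])
    return SegmentSet(
        segments=segs,
        window_s=window_s,
        overlap_frac=overlap_frac,
        fs=rec.fs,
        subject_id=rec.subject_id,
    )
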
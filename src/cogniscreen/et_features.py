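"""Gaze-stream preprocessing and oculomotor feature extraction.

The pipeline normalizes gaze to display coordinates, low-pass filters
valid runs (Butterworth, 5 Hz cut-off), detects blinks as bounded
validity gaps, separates fixations from saccades with a velocity
threshold (I-VT), and summarizes each recording into five features:
blink frequency (events/min), mean blink time (s), mean fixation time
(s), sustained attention duration (s, longest unbroken run of in-AOI
fixations), and the Lempel–Ziv complexity of the scan-path speed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig

from .eeg_features import lempel_ziv_complexity

log = logging.getLogger(__name__)

__all__ = [
    "GazeStream",
    "OcularEvent",
    "ETConfig",
    "read_et_csv",
    "write_et_csv",
    "preprocess_gaze",
    "detect_blinks",
    "detect_fixations_saccades",
    "compute_et_metrics",
    "gaze_complexity",
    "extract_subject_et_features",
]

#: sentinel written for gaze coordinates during validity gaps
GAZE_SENTINEL = -1.0


@dataclass
class GazeStream:
    """Eye-tracker sample stream.

    ``x``/``y`` are display-normalized in [0, 1] for valid samples;
    invalid samples carry the sentinel value.  ``t`` must be strictly
    increasing.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pupil: np.ndarray
    valid: np.ndarray
    fs: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.t.size >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return self.t.size / self.fs


@dataclass
class OcularEvent:
    """A detected blink, fixation or saccade."""

    kind: str  # "fixation" | "saccade" | "blink"
    t_start: float
    t_end: float
    centroid: tuple[float, float] | None = None
    peak_velocity: float | None = None

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class ETConfig:
    """Eye-tracking preprocessing and event-detection parameters."""

    lowpass_hz: float = 5.0
    lowpass_order: int = 2
    velocity_threshold: float = 0.5  # normalized display units / s
    blink_min_ms: float = 70.0
    blink_max_ms: float = 500.0
    min_fixation_ms: float = 60.0
    aoi: tuple[float, float, float, float] = (0.25, 0.25, 0.75, 0.75)  # x0,y0,x1,y1


def read_et_csv(path, fs: float | None = None, subject_id: str | None = None) -> GazeStream:
    """Read the ET CSV dialect with columns t,x,y,pupil,valid."""
    import pandas as pd

    df = pd.read_csv(path)
    t = df["t"].to_numpy(float)
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 1.0
    if subject_id is None:
        import os

        subject_id = os.path.basename(os.path.dirname(str(path))) or ""
    return GazeStream(
        t=t,
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        pupil=df["pupil"].to_numpy(float),
        valid=df["valid"].to_numpy(bool),
        fs=fs,
        subject_id=subject_id,
    )


def write_et_csv(stream: GazeStream, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "t": stream.t,
            "x": stream.x,
            "y": stream.y,
            "pupil": stream.pupil,
            "valid": stream.valid.astype(int),
        }
    ).to_csv(path, index=False, float_format="%.6f")


def _valid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([False], valid, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])]


def preprocess_gaze(
    stream: GazeStream,
    display_px: tuple[float, float] | None = None,
    config: ETConfig | None = None,
) -> GazeStream:
    """Normalize to display coordinates and low-pass filter valid runs.

    Invalid samples are excluded from filtering (each maximal valid run
    is filtered independently; runs too short for the filter's padding
    are left unfiltered) and keep their validity flag.
    """
    cfg = config or ETConfig()
    if stream.t.size < 2:
        raise ValueError("stream must contain at least 2 samples")
    if not stream.valid.any():
        raise ValueError("no valid gaze samples")
    x, y = stream.x.copy(), stream.y.copy()
    if display_px is not None:
        w, h = display_px
        if w <= 0 or h <= 0:
            raise ValueError("display size must be positive")
        x[stream.valid] = x[stream.valid] / w
        y[stream.valid] = y[stream.valid] / h
    sos = _sig.butter(cfg.lowpass_order, cfg.lowpass_hz, btype="low", fs=stream.fs, output="sos")
    padlen = 3 * (2 * cfg.lowpass_order + 1)
    for s, e in _valid_runs(stream.valid):
        if e - s > padlen:
            x[s:e] = _sig.sosfiltfilt(sos, x[s:e])
            y[s:e] = _sig.sosfiltfilt(sos, y[s:e])
    return replace(stream, x=x, y=y)


def detect_blinks(
    stream: GazeStream, min_gap_ms: float = 70.0, max_gap_ms: float = 500.0
) -> tuple[list[OcularEvent], GazeStream]:
    """Classify validity gaps: blink, sensor noise, or signal loss.

    Maximal invalid runs with duration in [min_gap, max_gap] become
    blink events.  Shorter runs are treated as tracker noise and
    linearly interpolated (re-flagged valid); longer runs are signal
    loss and stay excluded (logged).  Returns the blink events and the
    cleaned stream.
    """
    dt = 1.0 / stream.fs
    invalid = ~stream.valid
    blinks: list[OcularEvent] = []
    x, y, pupil = stream.x.copy(), stream.y.copy(), stream.pupil.copy()
    valid = stream.valid.copy()
    good = np.flatnonzero(stream.valid)
    for s, e in _valid_runs(invalid):
        dur_ms = (e - s) * dt * 1000.0
        if min_gap_ms <= dur_ms <= max_gap_ms:
            blinks.append(
                OcularEvent(kind="blink", t_start=stream.t[s], t_end=stream.t[e - 1] + dt)
            )
        elif dur_ms < min_gap_ms:
            if good.size >= 2:  # interpolate across the short gap
                idx = np.arange(s, e)
                x[idx] = np.interp(idx, good, stream.x[good])
                y[idx] = np.interp(idx, good, stream.y[good])
                pupil[idx] = np.interp(idx, good, stream.pupil[good])
                valid[idx] = True
        else:
            log.info(
                "subject %s: %d ms validity gap treated as signal loss",
                stream.subject_id,
                int(dur_ms),
            )
    cleaned = replace(stream, x=x, y=y, pupil=pupil, valid=valid)
    return blinks, cleaned


def detect_fixations_saccades(
    stream: GazeStream,
    velocity_threshold: float = 0.5,
    min_fixation_ms: float = 60.0,
) -> list[OcularEvent]:
    """Velocity-threshold (I-VT) fixation/saccade segmentation.

    Sample-wise speed is the central-difference gradient of the gaze
    position in normalized units per second; samples with speed at or
    above the threshold are saccade samples, the rest fixation samples.
    Contiguous runs are merged into events; fixations shorter than
    ``min_fixation_ms`` are discarded.  Validity gaps break events.
    """
    if stream.t.size < 3:
        raise ValueError("stream shorter than 3 samples")
    dt = 1.0 / stream.fs
    events: list[OcularEvent] = []
    for s, e in _valid_runs(stream.valid):
        if e - s < 3:
            continue
        tt = stream.t[s:e]
        xx, yy = stream.x[s:e], stream.y[s:e]
        vx = np.gradient(xx, tt)
        vy = np.gradient(yy, tt)
        speed = np.hypot(vx, vy)
        is_sacc = speed >= velocity_threshold
        runs = _valid_runs(is_sacc) + [
            (a, b) for a, b in _valid_runs(~is_sacc)
        ]
        for a, b in sorted(runs):
            kind = "saccade" if is_sacc[a] else "fixation"
            ev = OcularEvent(kind=kind, t_start=tt[a], t_end=tt[b - 1] + dt)
            if kind == "fixation":
                if ev.duration * 1000.0 < min_fixation_ms:
                    continue
                ev.centroid = (float(xx[a:b].mean()), float(yy[a:b].mean()))
            else:
                ev.peak_velocity = float(speed[a:b].max())
            events.append(ev)
    events.sort(key=lambda ev: ev.t_start)
    return events


def compute_et_metrics(
    events: list[OcularEvent],
    stream_duration_s: float,
    aoi: tuple[float, float, float, float] = (0.25, 0.25, 0.75, 0.75),
) -> dict:
    """Summary oculomotor metrics from the detected event stream.

    ``sustained_attention_duration`` is the total fixated time of the
    longest unbroken run of consecutive fixations whose centroids fall
    inside the AOI rectangle; saccades between them do not break the
    run, but an out-of-AOI fixation or a blink does.  Empty event
    classes yield 0 for the frequency and NaN (missing, logged) for the
    duration means.
    """
    if stream_duration_s <= 0:
        raise ValueError("stream duration must be positive")
    blinks = [e for e in events if e.kind == "blink"]
    fixations = [e for e in events if e.kind == "fixation"]
    out: dict[str, float] = {}
    out["blink_frequency"] = len(blinks) / stream_duration_s * 60.0
    if blinks:
        out["blink_time"] = float(np.mean([e.duration for e in blinks]))
    else:
        out["blink_time"] = np.nan
    if fixations:
        out["fixation_time"] = float(np.mean([e.duration for e in fixations]))
    else:
        log.info("no fixations detected: fixation_time missing")
        out["fixation_time"] = np.nan

    x0, y0, x1, y1 = aoi
    best = run = 0.0
    for ev in sorted(events, key=lambda e: e.t_start):
        if ev.kind == "saccade":
            continue
        in_aoi = (
            ev.kind == "fixation"
            and ev.centroid is not None
            and x0 <= ev.centroid[0] <= x1
            and y0 <= ev.centroid[1] <= y1
        )
        if in_aoi:
            run += ev.duration
            best = max(best, run)
        else:  # out-of-AOI fixation or blink breaks the run
            run = 0.0
    out["sustained_attention_duration"] = best
    return out


def gaze_complexity(stream: GazeStream) -> float:
    """Lempel–Ziv complexity of the scan-path speed sequence.

    Consecutive valid samples form a speed series (normalized units/s),
    which is binarized at its median and parsed with the same LZ76
    kernel used for EEG complexity.
    """
    good = stream.valid
    if good.sum() < 2:
        raise ValueError("need at least 2 valid samples")
    xv, yv = stream.x[good], stream.y[good]
    speed = np.hypot(np.diff(xv), np.diff(yv)) * stream.fs
    if speed.size < 2:
        raise ValueError("too few valid samples for a speed sequence")
    return lempel_ziv_complexity(speed, binarize="median")


def extract_subject_et_features(
    raw: GazeStream,
    config: ETConfig | None = None,
    display_px: tuple[float, float] | None = None,
) -> dict:
    """Full per-subject ET feature vector from a raw stream."""
    cfg = config or ETConfig()
    stream = preprocess_gaze(raw, display_px=display_px, config=cfg)
    blinks, cleaned = detect_blinks(stream, cfg.blink_min_ms, cfg.blink_max_ms)
    events = detect_fixations_saccades(
        cleaned, cfg.velocity_threshold, cfg.min_fixation_ms
    )
    metrics = compute_et_metrics(events + blinks, cleaned.duration_s, cfg.aoi)
    metrics["gaze_lzc"] = gaze_complexity(cleaned)
    return metrics
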
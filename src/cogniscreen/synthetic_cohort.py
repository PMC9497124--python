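"""Synthetic NC/MCI cohort generator.

Real community-screening cohorts of this kind are not publicly
deposited, so every downstream stage is exercised against simulated
two-group data with configurable, literature-typical group effects:

* EEG — sum of band-limited oscillations (delta/theta/alpha/beta) over a
  1/f (pink) noise floor, with MCI drawing lower alpha and higher theta
  amplitude, and a "complexity" latent that smooths the broadband
  component (lower entropy / LZ complexity);
* eye tracking — piecewise-stationary fixations around AOI targets with
  ballistic saccades and Poisson blinks (validity gaps), MCI showing
  longer fixations and more blinks;
* neuropsychological battery — 20 correlated subtests loaded on a
  shared cognition latent that MCI shifts downward, which also drives
  the MoCA-B / ACE-R screening scores;
* demographics — age/gender/education sampled group-balanced.

Effect sizes are standardized shifts (in units of the between-subject
SD of the corresponding latent).  A fixed seed gives byte-identical
output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .eeg_processing import EEGRecording, write_eeg_csv
from .et_features import GAZE_SENTINEL, GazeStream, write_et_csv

log = logging.getLogger(__name__)

__all__ = [
    "CohortSpec",
    "SubjectRecord",
    "SimulatedCohort",
    "DEFAULT_EFFECTS",
    "NTB_RANGES",
    "generate_eeg_recording",
    "generate_et_recording",
    "simulate_cohort",
    "generate_cohort",
]

GROUPS = ("NC", "MCI")

#: MCI-typical standardized shifts applied to the MCI group.
DEFAULT_EFFECTS: dict[str, float] = {
    "alpha_power": -1.0,
    "theta_power": 1.0,
    "complexity": -0.8,
    "fixation_time": 0.8,
    "blink_rate": 0.8,
    "ntb_scores": -1.5,
}

# Base oscillation RMS amplitudes (µV); between-subject SD is a fixed
# fraction of the base so "one SD" has a concrete meaning per band.
_BAND_RMS = {"delta": 4.0, "theta": 3.0, "alpha": 5.0, "beta": 2.0}
_BAND_EDGES = {"delta": (0.5, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}
_SUBJECT_SD_FRAC = 0.25
_PINK_RMS = 3.0

_N_SUBTESTS = 20
NTB_RANGES: dict[str, tuple[float, float]] = {
    f"subtest_{i:02d}": (0.0, 30.0) for i in range(1, _N_SUBTESTS + 1)
}
NTB_RANGES["total"] = (0.0, 600.0)
NTB_RANGES["response_time_s"] = (0.0, 3600.0)


@dataclass
class CohortSpec:
    """Study-design parameters of a simulated two-group cohort."""

    n_nc: int = 184
    n_mci: int = 152
    eeg_duration_s: float = 33.0
    eeg_fs: float = 128.0
    et_duration_s: float = 60.0
    et_fs: float = 60.0
    effect_sizes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    noise_sd: dict[str, float] = field(default_factory=dict)
    base_blink_rate_per_min: float = 12.0
    base_fixation_s: float = 0.40
    line_amplitude_uv: float = 1.0
    artifact_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        eff = dict(DEFAULT_EFFECTS)
        eff.update(self.effect_sizes)
        self.effect_sizes = eff

    def validate(self, min_eeg_window_s: float = 5.0) -> None:
        if self.n_nc < 2 or self.n_mci < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.eeg_duration_s <= min_eeg_window_s:
            raise ValueError(
                f"EEG duration {self.eeg_duration_s} s must exceed the "
                f"{min_eeg_window_s} s analysis window"
            )
        if self.et_duration_s <= 0 or self.eeg_fs <= 0 or self.et_fs <= 0:
            raise ValueError("durations and sampling rates must be positive")

    def with_effects(self, value: float | None = None, **families: float) -> "CohortSpec":
        """Copy with all (or selected) effect families replaced."""
        eff = dict(self.effect_sizes)
        if value is not None:
            sign = {k: np.sign(v) if v else 1.0 for k, v in DEFAULT_EFFECTS.items()}
            eff = {k: sign[k] * abs(value) for k in eff}
        eff.update(families)
        return replace(self, effect_sizes=eff)


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    eeg: EEGRecording
    et: GazeStream


@dataclass
class SimulatedCohort:
    subjects: list[SubjectRecord]
    ntb: pd.DataFrame
    demographics: pd.DataFrame
    spec: CohortSpec


def _check_group(group: str) -> None:
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * scale, n)
    return x / np.std(x)


def _bandlimited(n: int, fs: float, lo: float, hi: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise band-limited to [lo, hi] Hz."""
    sos = _sig.butter(4, [lo, min(hi, 0.99 * fs / 2)], btype="bandpass", fs=fs, output="sos")
    x = _sig.sosfilt(sos, rng.standard_normal(n + int(fs)))[int(fs) :]  # drop warm-up
    sd = np.std(x)
    return x / sd if sd > 0 else x


def generate_eeg_recording(
    group: str,
    spec: CohortSpec,
    rng: np.random.Generator,
    subject_id: str = "",
) -> EEGRecording:
    """Draw one subject's synthetic EEG trace.

    The trace is a sum of four band-limited oscillations with
    subject-specific amplitudes (MCI shifted on alpha/theta per
    ``spec.effect_sizes``), a pink-noise floor whose smoothness encodes
    the "complexity" latent, an optional 50 Hz line component, and an
    optional saturation artifact burst.
    """
    _check_group(group)
    spec.validate()
    eff = spec.effect_sizes
    n = int(round(spec.eeg_duration_s * spec.eeg_fs))
    noise_scale = spec.noise_sd.get("eeg", 1.0)

    x = np.zeros(n)
    for band, base in _BAND_RMS.items():
        shift = 0.0
        if group == "MCI":
            if band == "alpha":
                shift = eff["alpha_power"]
            elif band == "theta":
                shift = eff["theta_power"]
        z = rng.standard_normal()
        rms = base * (1.0 + _SUBJECT_SD_FRAC * (z + shift))
        rms = max(rms, 0.15 * base)
        lo, hi = _BAND_EDGES[band]
        x += rms * _bandlimited(n, spec.eeg_fs, lo, hi, rng)

    # broadband floor; the complexity latent smooths it for MCI draws
    z_c = rng.standard_normal() + (eff["complexity"] if group == "MCI" else 0.0)
    w = int(np.clip(round(3.0 - 1.2 * z_c), 1, 12))
    noise = _pink_noise(n, rng)
    if w > 1:
        noise = np.convolve(noise, np.ones(w) / w, mode="same")
        sd = np.std(noise)
        if sd > 0:
            noise = noise / sd
    x += _PINK_RMS * noise_scale * noise

    if spec.line_amplitude_uv > 0 and 50.0 < spec.eeg_fs / 2:
        t = np.arange(n) / spec.eeg_fs
        x += spec.line_amplitude_uv * np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))

    if spec.artifact_prob > 0 and rng.random() < spec.artifact_prob:
        start = rng.integers(0, max(n - int(0.3 * spec.eeg_fs), 1))
        x[start : start + int(0.3 * spec.eeg_fs)] = 200.0

    return EEGRecording(samples=x, fs=spec.eeg_fs, subject_id=subject_id)


def generate_et_recording(
    group: str,
    spec: CohortSpec,
    rng: np.random.Generator,
    subject_id: str = "",
) -> GazeStream:
    """Draw one subject's synthetic gaze stream.

    Piecewise-stationary fixations around targets (80 % inside a
    central AOI), ballistic 20–60 ms saccades, Poisson blinks encoded
    as validity gaps with the gaze coordinates set to the sentinel.
    """
    _check_group(group)
    if spec.et_duration_s <= 0:
        raise ValueError("duration must be positive")
    eff = spec.effect_sizes
    n = int(round(spec.et_duration_s * spec.et_fs))
    dt = 1.0 / spec.et_fs
    t = np.arange(n) * dt
    jitter_sd = 0.003 * spec.noise_sd.get("et", 1.0)

    mean_fix = spec.base_fixation_s * np.exp(
        0.30 * (rng.standard_normal() + (eff["fixation_time"] if group == "MCI" else 0.0))
    )
    blink_rate = (spec.base_blink_rate_per_min / 60.0) * np.exp(
        0.30 * (rng.standard_normal() + (eff["blink_rate"] if group == "MCI" else 0.0))
    )

    x = np.empty(n)
    y = np.empty(n)
    aoi_center = np.array([0.5, 0.5])

    def next_target() -> np.ndarray:
        if rng.random() < 0.8:  # inside the central AOI
            return aoi_center + rng.uniform(-0.2, 0.2, size=2)
        corner = rng.uniform(0.02, 0.18, size=2)
        side = rng.integers(0, 2, size=2)
        return np.where(side == 1, 1.0 - corner, corner)

    pos = next_target()
    i = 0
    while i < n:
        fix_len = max(int(np.clip(rng.lognormal(np.log(mean_fix), 0.4), 0.08, 3.0) / dt), 1)
        j = min(i + fix_len, n)
        x[i:j] = pos[0]
        y[i:j] = pos[1]
        i = j
        if i >= n:
            break
        target = next_target()
        sac_len = max(int(rng.uniform(0.02, 0.06) / dt), 1)
        j = min(i + sac_len, n)
        frac = np.linspace(0, 1, j - i + 2)[1:-1]
        ease = frac * frac * (3 - 2 * frac)  # smoothstep velocity profile
        x[i:j] = pos[0] + (target[0] - pos[0]) * ease
        y[i:j] = pos[1] + (target[1] - pos[1]) * ease
        pos = target
        i = j

    x += rng.normal(0.0, jitter_sd, size=n)
    y += rng.normal(0.0, jitter_sd, size=n)
    np.clip(x, 0.0, 1.0, out=x)
    np.clip(y, 0.0, 1.0, out=y)

    valid = np.ones(n, dtype=bool)
    if blink_rate > 0:
        tt = rng.exponential(1.0 / blink_rate)
        while tt < spec.et_duration_s:
            dur = rng.uniform(0.10, 0.30)
            s = int(tt / dt)
            e = min(int((tt + dur) / dt) + 1, n)
            valid[s:e] = False
            tt += dur + rng.exponential(1.0 / blink_rate)

    pupil = 3.0 + rng.normal(0.0, 0.05, size=n)
    x[~valid] = GAZE_SENTINEL
    y[~valid] = GAZE_SENTINEL
    pupil[~valid] = 0.0
    return GazeStream(t=t, x=x, y=y, pupil=pupil, valid=valid, fs=spec.et_fs, subject_id=subject_id)


def _ntb_loadings() -> np.ndarray:
    # fixed per-subtest loadings on the shared cognition latent
    return 0.5 + 0.4 * (np.arange(_N_SUBTESTS) % 5) / 4.0


def _draw_subject_tables(
    group: str, spec: CohortSpec, rng: np.random.Generator
) -> tuple[dict, dict]:
    """NTB row and demographics row for one subject."""
    eff = spec.effect_sizes["ntb_scores"]
    g = rng.standard_normal() + (eff if group == "MCI" else 0.0)
    loadings = _ntb_loadings()
    ntb: dict[str, float] = {}
    for i, lam in enumerate(loadings, start=1):
        mean = 18.0 + (i % 5)
        sd = 4.0 * spec.noise_sd.get("ntb", 1.0)
        score = mean + sd * (lam * g + np.sqrt(max(1 - lam**2, 0.0)) * rng.standard_normal())
        ntb[f"subtest_{i:02d}"] = float(np.clip(score, *NTB_RANGES[f"subtest_{i:02d}"]))
    ntb["total"] = float(sum(v for k, v in ntb.items() if k.startswith("subtest")))
    ntb["response_time_s"] = float(
        300.0 * np.exp(0.15 * (rng.standard_normal() - 0.5 * (eff if group == "MCI" else 0.0)))
    )

    # screening scores share the cognition latent; demographics are balanced
    demo = {
        "group": group,
        "age": float(rng.normal(71.7, 4.4)),
        "gender": "male" if rng.random() < 0.55 else "female",
        "education_years": int(np.clip(round(rng.normal(9.0, 3.5)), 0, 22)),
        "moca_b": float(np.clip(27.5 + 2.0 * (0.7 * g + 0.7 * rng.standard_normal()), 0, 30)),
        "ace_r": float(np.clip(72.0 + 8.0 * (0.7 * g + 0.7 * rng.standard_normal()), 0, 100)),
    }
    return ntb, demo


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate a full in-memory cohort (EEG + ET + NTB + demographics)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    subjects: list[SubjectRecord] = []
    ntb_rows: list[dict] = []
    demo_rows: list[dict] = []
    roster = [("NC", i) for i in range(1, spec.n_nc + 1)] + [
        ("MCI", i) for i in range(1, spec.n_mci + 1)
    ]
    for group, idx in roster:
        sid = f"{group}{idx:03d}"
        eeg = generate_eeg_recording(group, spec, rng, subject_id=sid)
        et = generate_et_recording(group, spec, rng, subject_id=sid)
        ntb, demo = _draw_subject_tables(group, spec, rng)
        subjects.append(SubjectRecord(subject_id=sid, group=group, eeg=eeg, et=et))
        ntb_rows.append({"subject_id": sid, **ntb})
        demo_rows.append({"subject_id": sid, **demo})
    return SimulatedCohort(
        subjects=subjects,
        ntb=pd.DataFrame(ntb_rows),
        demographics=pd.DataFrame(demo_rows),
        spec=spec,
    )


def generate_cohort(spec: CohortSpec, out_dir) -> SimulatedCohort:
    """Generate a cohort and write it in the on-disk layout.

    Layout: ``<out_dir>/<subject_id>/eeg.csv`` (``# fs=<Hz>`` header,
    one sample per line), ``<out_dir>/<subject_id>/et.csv``
    (t,x,y,pupil,valid), plus ``ntb.csv`` and ``demographics.csv``.
    Identical specs (including seed) produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(spec)
    for rec in cohort.subjects:
        sdir = out / rec.subject_id
        sdir.mkdir(exist_ok=True)
        write_eeg_csv(rec.eeg, sdir / "eeg.csv")
        write_et_csv(rec.et, sdir / "et.csv")
    cohort.ntb.to_csv(out / "ntb.csv", index=False, float_format="%.6f")
    cohort.demographics.to_csv(out / "demographics.csv", index=False, float_format="%.6f")
    log.info("wrote %d-subject cohort to %s", len(cohort.subjects), out)
    return cohort
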
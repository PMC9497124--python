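"""Linear (spectral) and nonlinear (entropy/complexity) EEG features.

Spectral features come from a Wiener–Khinchin PSD estimate (Fourier
transform of the biased autocorrelation, numerically identical to the
periodogram) integrated over the four classical bands:

    delta 0.5–4 Hz, theta 4–8 Hz, alpha 8–13 Hz, beta 13–30 Hz

together with relative powers and the alpha/theta ratio.  Nonlinear
features are approximate entropy (ApEn), multiscale entropy (MsEn,
sample entropy of coarse-grained series), and Lempel–Ziv complexity
(LZ76 on a binarized sequence).  Segment-level features are averaged to
one vector per subject.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from . import _kernels
from .eeg_processing import SegmentSet

log = logging.getLogger(__name__)

__all__ = [
    "PSDResult",
    "BandDefinition",
    "DEFAULT_BANDS",
    "EEGFeatureConfig",
    "psd_autocorrelation",
    "band_powers",
    "approximate_entropy",
    "sample_entropy",
    "multiscale_entropy",
    "lempel_ziv_complexity",
    "extract_subject_eeg_features",
]


@dataclass
class PSDResult:
    """One-sided power spectral density estimate (µV²/Hz)."""

    freqs: np.ndarray
    power: np.ndarray


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float


DEFAULT_BANDS = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)


def psd_autocorrelation(segment: np.ndarray, fs: float) -> PSDResult:
    """Wiener–Khinchin PSD: FFT of the biased autocorrelation.

    The segment is demeaned, its linear autocorrelation r[k] (biased,
    1/n normalization) computed for all lags, and the DFT of the
    circularly arranged lag sequence taken.  This equals the zero-padded
    periodogram |X(f)|²/(n·fs) exactly; the returned estimate is
    one-sided and power conserving (the two-sided bin sum equals the
    sample variance).
    """
    x = np.asarray(segment, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("segment must contain at least 2 samples")
    x = x - x.mean()
    # biased autocorrelation at lags -(n-1)..(n-1)
    r = _sig.correlate(x, x, mode="full", method="fft") / n
    # circular ordering of the 2n-1 lags: 0..n-1 then -(n-1)..-1
    a = np.concatenate([r[n - 1 :], r[: n - 1]])
    s = np.fft.rfft(a).real
    s = np.clip(s, 0.0, None)
    freqs = np.fft.rfftfreq(a.size, d=1.0 / fs)
    power = s / fs
    power[1:] *= 2.0  # fold negative frequencies (odd length: no Nyquist bin)
    return PSDResult(freqs=freqs, power=power)


def band_powers(
    psd: PSDResult,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    total_range: tuple[float, float] = (0.5, 30.0),
) -> dict:
    """Integrate a PSD over frequency bands.

    Returns a dict with absolute powers (rectangle-rule integral over
    [lo, hi), so each frequency bin belongs to exactly one band and the
    four bands tile the total range), relative powers (absolute / total
    over ``total_range``), and the alpha/theta ratio.  A zero-power
    spectrum yields NaN relative powers and ratios (flagged missing,
    logged).
    """
    f, p = psd.freqs, psd.power
    df = float(f[1] - f[0]) if f.size > 1 else 1.0

    def integrate(lo: float, hi: float) -> float:
        mask = (f >= lo) & (f < hi)
        return float(p[mask].sum() * df)

    absolute = {b.name: integrate(b.lo, b.hi) for b in bands}
    total = integrate(*total_range)
    out = {"absolute": absolute, "total": total}
    if total > 0:
        out["relative"] = {k: v / total for k, v in absolute.items()}
    else:
        log.info("zero total power: relative powers and ratios undefined")
        out["relative"] = {k: np.nan for k in absolute}
    ratios = {}
    if absolute.get("theta", 0.0) > 0:
        ratios["alpha_theta"] = absolute["alpha"] / absolute["theta"]
    else:
        ratios["alpha_theta"] = np.nan
    denom = absolute.get("alpha", 0.0) + absolute.get("beta", 0.0)
    ratios["slowing"] = (
        (absolute.get("delta", 0.0) + absolute.get("theta", 0.0)) / denom
        if denom > 0
        else np.nan
    )
    out["ratios"] = ratios
    return out


def _resolve_r(x: np.ndarray, r: float | None, coef: float = 0.15) -> float:
    return coef * float(np.std(x)) if r is None else float(r)


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Approximate entropy ApEn(m, r) = Phi_m(r) - Phi_{m+1}(r).

    Template matching is self-inclusive under the Chebyshev distance.
    ``r`` defaults to 0.15·SD of the input; a constant sequence returns
    exactly 0 (all templates match).
    """
    x = np.asarray(x, dtype=float)
    if x.size <= m + 1:
        raise ValueError(f"need more than m+1={m + 1} samples, got {x.size}")
    if np.ptp(x) == 0:
        return 0.0
    r = _resolve_r(x, r)
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    return float(_kernels.phi(x, m, r) - _kernels.phi(x, m + 1, r))


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy SampEn(m, r) = -ln(A/B), self-matches excluded.

    Returns NaN when no length-(m+1) matches exist (undefined); a
    constant sequence returns exactly 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size <= m + 1:
        raise ValueError(f"need more than m+1={m + 1} samples, got {x.size}")
    if np.ptp(x) == 0:
        return 0.0
    r = _resolve_r(x, r)
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    a, b = _kernels.sampen_counts(x, m, r)
    if b == 0 or a == 0:
        return np.nan
    return float(-np.log(a / b))


def multiscale_entropy(
    x: np.ndarray, m: int = 2, r: float | None = None, max_scale: int = 10
) -> np.ndarray:
    """Multiscale entropy: sample entropy of coarse-grained series.

    Scale τ replaces the series by non-overlapping means of length-τ
    blocks; the tolerance r is fixed from the *original* series SD so
    the curve reflects genuine loss of structure, not shrinking
    variance.  Scales for which fewer than 10·τ original samples (or
    too-short coarse series) are available are truncated with a warning.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= m + 1:
        raise ValueError("series too short for any scale")
    r = _resolve_r(x, r)
    if r <= 0 and np.ptp(x) != 0:
        raise ValueError("tolerance r must be positive")
    usable = min(max_scale, n // 10) if n // 10 >= 1 else 0
    # also require the coarse series to support the embedding
    while usable > 0 and n // usable <= m + 1:
        usable -= 1
    if usable == 0:
        raise ValueError("no valid scales for this series length")
    if usable < max_scale:
        warnings.warn(
            f"series length {n} supports only {usable} of {max_scale} scales",
            stacklevel=2,
        )
    out = np.empty(usable)
    for tau in range(1, usable + 1):
        ncoarse = n // tau
        coarse = x[: ncoarse * tau].reshape(ncoarse, tau).mean(axis=1)
        if np.ptp(coarse) == 0:
            out[tau - 1] = 0.0
        elif r <= 0:
            out[tau - 1] = 0.0
        else:
            a, b = _kernels.sampen_counts(coarse, m, r)
            out[tau - 1] = -np.log(a / b) if (a > 0 and b > 0) else np.nan
    return out


def _lz76_count(bits: np.ndarray) -> int:
    """Number of components in the LZ76 exhaustive-history parse.

    Each component is the shortest phrase starting at the current
    position that does not occur as a substring of the text preceding
    its last symbol (overlap with the phrase itself is allowed).
    """
    s = np.asarray(bits, dtype=np.uint8).tobytes()
    n = len(s)
    i, c = 0, 0
    while i < n:
        length = 1
        while i + length <= n and s[i : i + length] in s[: i + length - 1]:
            length += 1
        c += 1
        i += length
    return c


def lempel_ziv_complexity(x: np.ndarray, binarize: str = "median") -> float:
    """Normalized Lempel–Ziv complexity C = c(n)·log2(n)/n.

    The sequence is binarized at its median (default) or mean, then
    parsed with the LZ76 exhaustive history.  ``C`` is ≈1 for an i.i.d.
    random binary sequence and small for regular signals.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    if binarize == "median":
        thr = float(np.median(x))
    elif binarize == "mean":
        thr = float(np.mean(x))
    else:
        raise ValueError(f"unknown binarization {binarize!r}")
    bits = (x > thr).astype(np.uint8)
    c = _lz76_count(bits)
    return float(c * np.log2(n) / n)


@dataclass
class EEGFeatureConfig:
    """Registry of EEG features to extract and their parameters."""

    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    apen_m: int = 2
    r_coef: float = 0.15  # tolerance as a fraction of the segment SD
    msen_max_scale: int = 10
    lzc_binarize: str = "median"
    include_slowing_ratio: bool = False

    def feature_names(self) -> list[str]:
        names = [f"{b.name}_power" for b in self.bands]
        names += [f"{b.name}_rel" for b in self.bands]
        names.append("alpha_theta_ratio")
        if self.include_slowing_ratio:
            names.append("slowing_ratio")
        names += ["apen", "lzc"]
        names += [f"msen_scale_{s:02d}" for s in range(1, self.msen_max_scale + 1)]
        names.append("msen_mean")
        return names


def _segment_features(seg: np.ndarray, fs: float, cfg: EEGFeatureConfig) -> dict:
    psd = psd_autocorrelation(seg, fs)
    bp = band_powers(psd, cfg.bands)
    row: dict[str, float] = {}
    for b in cfg.bands:
        row[f"{b.name}_power"] = bp["absolute"][b.name]
        row[f"{b.name}_rel"] = bp["relative"][b.name]
    row["alpha_theta_ratio"] = bp["ratios"]["alpha_theta"]
    if cfg.include_slowing_ratio:
        row["slowing_ratio"] = bp["ratios"]["slowing"]
    row["apen"] = approximate_entropy(seg, m=cfg.apen_m, r=cfg.r_coef * np.std(seg))
    row["lzc"] = lempel_ziv_complexity(seg, binarize=cfg.lzc_binarize)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        msen = multiscale_entropy(
            seg, m=cfg.apen_m, r=cfg.r_coef * np.std(seg), max_scale=cfg.msen_max_scale
        )
    for s in range(1, cfg.msen_max_scale + 1):
        row[f"msen_scale_{s:02d}"] = msen[s - 1] if s <= msen.size else np.nan
    row["msen_mean"] = float(np.nanmean(msen)) if np.isfinite(msen).any() else np.nan
    return row


def extract_subject_eeg_features(
    segments: SegmentSet, config: EEGFeatureConfig | None = None
) -> dict:
    """Average per-segment features into one subject-level vector.

    Segments for which a feature is undefined (NaN) are excluded from
    that feature's mean, with a log entry; a feature undefined in every
    segment stays NaN.
    """
    cfg = config or EEGFeatureConfig()
    if len(segments) < 1:
        raise ValueError("no valid segments")
    rows = [_segment_features(seg, segments.fs, cfg) for seg in segments.segments]
    names = cfg.feature_names()
    out: dict[str, float] = {}
    for name in names:
        vals = np.array([row[name] for row in rows], dtype=float)
        bad = np.isnan(vals).sum()
        if bad:
            log.info(
                "subject %s: feature %s undefined in %d/%d segments",
                segments.subject_id,
                name,
                bad,
                vals.size,
            )
        out[name] = float(np.nanmean(vals)) if bad < vals.size else np.nan
    return out
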
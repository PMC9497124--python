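# Methods

## Scope and pipeline

`cogniscreen` implements a multimodal MCI-vs-NC screening pipeline:
per-subject signal preprocessing, feature extraction, normalization,
MRMR feature selection, and SVM classification with cross-validated
model comparison. The stages are pure functions of (inputs, config,
seed); one configured seed fans out to per-stage seeds by CRC-32
hashing of the stage name.

## EEG preprocessing

Recordings are screened for electrode offset before any filtering: a
run of identical samples (flatline) or of samples at ≥ 95 % of the
amplifier full scale (saturation, default full scale 200 µV) lasting at
least 1 s marks the recording invalid. Invalid recordings are excluded,
not repaired; the inner join at assembly drops those subjects.

Denoising is a second-order Butterworth band-pass (0.5–30 Hz) plus a
band-stop notch (50 ± 2 Hz, the power-line frequency of the regions the
tool targets). Both are applied forward–backward (zero phase): the
effective attenuation is doubled and event timing is preserved for
segment alignment. Segmentation uses a 5 s window with 60 % overlap
(2 s hop); the count is data-driven — a 33 s recording yields 15
segments. EMG/ECG contamination is handled only to the extent the band
filters remove it; no ICA/regression artifact removal is attempted.

## EEG features

The PSD is the Fourier transform of the biased autocorrelation
(Wiener–Khinchin), numerically identical to the zero-padded
periodogram and power-conserving (two-sided bin sum = sample variance).
Band powers integrate the one-sided PSD by the rectangle rule so the
four bands tile 0.5–30 Hz exactly and relative powers sum to 1.
Ratios: α/θ always; the (δ+θ)/(α+β) slowing ratio is available but off
by default, since the canonical feature list of such batteries varies —
the config-driven registry is the extension point.

Nonlinear features, per 5 s segment and averaged across segments
(segments where a feature is undefined are excluded from that feature's
mean, with a log entry):

* **ApEn(m=2, r=0.15·SD)** — Φ_m − Φ_{m+1} with self-inclusive
  Chebyshev template matching. Constant input returns exactly 0.
* **MsEn (scales 1–10)** — sample entropy (self-matches excluded) of
  non-overlapping coarse-grained means, with r fixed from the
  *original* series SD; scale 1 is identically SampEn. Scales
  unsupported by the series length are truncated with a warning.
  Sample entropy (not ApEn) is used inside MsEn, following standard
  multiscale practice.
* **LZC** — LZ76 exhaustive-history parse count c(n) of the
  median-binarized sequence, normalized as c(n)·log₂(n)/n. Median
  binarization is robust to amplitude outliers. The same kernel serves
  the eye-tracking scan-path complexity.

ApEn and LZC are invariant to affine rescaling because r and the
threshold are data-relative.

## Eye tracking

Gaze is normalized to display coordinates, and valid runs are low-pass
filtered (Butterworth, 5 Hz, zero phase). Validity gaps are classified
by duration: 70–500 ms = blink (the physiological range), shorter =
tracker noise (linearly interpolated), longer = signal loss (excluded).
Fixations and saccades are separated by a velocity threshold (I-VT) on
the central-difference speed, default 0.5 normalized units/s — screen
units, not degrees, because viewing geometry is generally unknown for
consumer trackers; fixations shorter than 60 ms are discarded.
"Sustained attention duration" is defined here as the total fixated
time of the longest unbroken run of consecutive in-AOI fixations
(saccades between them do not break the run; blinks and out-of-AOI
fixations do). This is one plausible operationalization of a quantity
that has no canonical definition; it is isolated behind one function so
other readings can be swapped in. The AOI defaults to the central
half-screen rectangle and is configurable.

## NTB and assembly

NTB cleaning sets out-of-range cells missing (per-subtest declared
ranges) and drops subjects missing more than half the subtests, with a
line-oriented exclusion log. Normalization is two-stage — NTB raw
scores min–max scaled to [0, 1], then every assembled feature
z-transformed — and both stages are fit on training data only; the CV
harness re-fits them per fold, and a leakage test asserts that
perturbing validation rows never changes training-fold parameters.
Missing values after the join are median-imputed with training
medians.

The four comparison views are nested column subsets of one assembled
table: clinical (age, one-hot gender, education, MoCA-B, ACE-R), NTB
subtests only, physiological (EEG + ET) only, and all combined. Note a
deliberate circularity caveat: the clinical view includes MoCA-B/ACE-R,
which are themselves cognitive screens; this mirrors common screening-
study practice and is why the clinical model is a strong-ish baseline.

Group statistics use the field's conventional tests: two-sample t for
continuous variables, χ² (no continuity correction) for gender,
Wilcoxon rank-sum for education years; tests are labelled explicitly
per variable in the report.

## MRMR

Mutual information is the plug-in estimate in bits from joint counts;
continuous features are discretized by equal-frequency binning (8 bins
by default), fitted on the data at hand, which also makes the ranking
invariant to monotone feature transforms. Integer marginal counts and
canonical summation order make the estimator exactly symmetric.
Greedy selection picks argmax relevance first, then argmax of the
relevance/redundancy **quotient** (MIQ); the difference criterion (MID)
is a config switch. Redundancy for a candidate is the pairwise-MI sum
against the already-selected set, normalized by |Ω|² with Ω = selected
∪ {candidate}. Ties break by column order. The selected count k
defaults to 20 and can be tuned on training folds.

## Classification and evaluation

The SVM defaults to RBF with C = 1.1, gamma = 0.001; the grid-search
helper spans linear/poly/RBF/sigmoid kernels with
C ∈ {0.1, 0.5, 1.1, 4, 17, 20} and gamma ∈ {0.001, 0.01, 0.02, 0.1},
with ties broken by smaller C then kernel order. MCI is the positive
class (+1), so sensitivity is the MCI detection rate. Metrics are
mean ± SD over the five validation folds. The ROC uses continuous
decision scores; its AUC equals the Mann–Whitney U statistic divided by
n₁n₂ (asserted in tests), and the 95 % CI is a stratified bootstrap
percentile interval (2000 resamples). Independent-cohort evaluation is
single-shot after refitting on the full training cohort; since fold
SDs have no analogue there, a bootstrap SD of accuracy over test-cohort
resamples is reported as the comparable dispersion.

## Synthetic cohort

The generator emulates a two-group community-screening cohort. Group
effects are standardized shifts applied to MCI draws on six latent
families: `alpha_power` (−), `theta_power` (+), `complexity` (−),
`fixation_time` (+), `blink_rate` (+), `ntb_scores` (−); defaults are
MCI-typical (−1.0, +1.0, −0.8, +0.8, +0.8, −1.5 SD).

* **EEG**: sum of four band-limited oscillations with subject-specific
  RMS amplitudes (base 4/3/5/2 µV for δ/θ/α/β, between-subject SD 25 %
  of base) over a pink-noise floor (RMS 3 µV); a latent complexity
  variable controls a moving-average smoothing of the floor (power
  preserved), lowering entropy and LZC for MCI draws; plus a 1 µV 50 Hz
  line component that the notch must remove. Defaults: fs = 128 Hz
  (Nyquist 64 Hz comfortably covers the 0.5–30 Hz analysis band, and is
  typical of wearable single-channel devices) and 33 s duration, which
  yields exactly 15 overlapping 5 s segments.
* **ET**: 60 Hz, 60 s; lognormal fixation durations (base mean 0.4 s,
  multiplicative shift 0.30 per SD), smoothstep ballistic saccades to
  targets (80 % inside the central AOI), Poisson blinks (base
  12/min) as 100–300 ms validity gaps with gaze set to the −1 sentinel.
* **NTB**: 20 subtests loading (0.5–0.9) on a shared cognition latent
  shifted by the `ntb_scores` effect; MoCA-B and ACE-R load on the same
  latent (so the null cohort is null for the clinical view too, rather
  than hard-coding group means); demographics (age ≈ 71.7 ± 4.4 y,
  education ≈ 9 ± 3.5 y, 55 % male) are group-balanced. Default group
  sizes are 184 NC / 152 MCI for cohort 1-style runs.

What the generator does **not** emulate: biophysically realistic neural
mass dynamics, non-stationarity and drowsiness drift, real ocular/EMG
artifact morphology, task-dependent gaze structure, item-level NTB
response processes, and covariate–outcome confounding (age effects on
EEG, education effects on NTB). Passing tests therefore demonstrate
pipeline correctness and sensitivity to the modeled effect families,
not clinical-grade performance on real cohorts.

## Numerical choices and problem sizes

Entropy kernels are numba-JIT double loops (a numpy broadcast fallback
keeps the package importable without JIT); the package and the test
oracles share definitions but not code paths. Velocity exactly at the
I-VT threshold is a saccade (≥ rule). Zero-power spectra yield missing
relative powers/ratios rather than infinities. MI values are clipped at
0 against rounding noise.

The test and acceptance simulations use reduced sizes chosen as the
package's own defaults for quick runs: null-cohort checks at 30/30
subjects with 13 s EEG / 30 s ET over 20 seeds; the strong-effect
multimodal comparison at 150/150 subjects (1.5 SD shifts) over 10
seeds; `scripts/acceptance.py` uses 60/60 subjects over 3 seeds with
the default effect sizes. Larger cohorts are a `CohortSpec` parameter
away.

## Known limitations

* EDF input is available via `read_eeg_edf` (mne-backed) but only the
  CSV dialect is exercised by tests.
* The plug-in MI estimator is positively biased at small n; rankings
  are consistent but Θ/Δ values should not be read as unbiased
  information estimates.
* With strong class imbalance the SVM decision threshold (0) is not
  recalibrated; sensitivity/specificity trade-offs should be read from
  the ROC.
* The MsEn tolerance r is fixed from the original series; comparing
  MsEn across signals with very different spectra inherits the usual
  caveats of that convention.
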
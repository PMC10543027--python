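"""Synthetic inputs with known ground truth for every pipeline stage.

The study cohorts these generators emulate are longitudinal infant EEG
datasets (2-44 months, repeated visits, four contributing studies) and a
smaller anesthesia cohort with end-tidal sevoflurane recordings.  Each
generator returns its ground truth alongside the data so recovery tests
can consume only the returned pair.  All randomness flows from an
explicit seed; there is no hidden global state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .spectral_estimation import PowerSpectrum, SegmentedEEG

__all__ = [
    "SpectrumGenSpec",
    "CohortGenSpec",
    "AnesthesiaGenSpec",
    "SyntheticAnesthesiaRecording",
    "gen_spectrum",
    "gen_timeseries",
    "gen_cohort",
    "gen_anesthesia_cohort",
    "default_age_functions",
]


# --------------------------------------------------------------------------
# spectra
# --------------------------------------------------------------------------

@dataclass
class SpectrumGenSpec:
    """Ground truth for one synthetic power spectrum.

    log10 P(f) = b - chi*log10(f) + sum of Gaussians + N(0, noise_sd).
    """

    b: float = 1.5
    chi: float = 1.0
    peaks: list[tuple[float, float, float]] = field(default_factory=list)
    noise_sd: float = 0.02
    freqs: np.ndarray = field(default_factory=lambda: np.arange(0.5, 100.01, 0.5))
    seed: int = 0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if np.any(self.freqs <= 0):
            raise ValueError("frequency grid must be positive")


def gen_spectrum(spec: SpectrumGenSpec) -> tuple[PowerSpectrum, SpectrumGenSpec]:
    """Synthesize a linear-power spectrum from aperiodic + Gaussian truth."""
    rng = np.random.default_rng(spec.seed)
    log_p = spec.b - spec.chi * np.log10(spec.freqs)
    for c, h, w in spec.peaks:
        log_p = log_p + h * np.exp(-((spec.freqs - c) ** 2) / (2 * w**2))
    if spec.noise_sd > 0:
        log_p = log_p + rng.normal(0.0, spec.noise_sd, size=len(spec.freqs))
    return PowerSpectrum(spec.freqs.copy(), 10.0**log_p, label="synthetic"), spec


def gen_timeseries(
    target: PowerSpectrum,
    duration: float,
    fs: float,
    seed: int = 0,
    segment_length: float = 2.0,
    channel_labels: list[str] | None = None,
) -> SegmentedEEG:
    """Gaussian process realization of a target one-sided PSD.

    Each segment is synthesized independently in the frequency domain:
    rFFT coefficients are drawn as circular complex Gaussians with
    variance matched to the target PSD (interpolated onto the segment's
    rFFT grid), so the multitaper PSD of the output matches the target in
    expectation.
    """
    if duration < 2 * segment_length:
        raise ValueError("duration must cover at least 2 segments")
    rng = np.random.default_rng(seed)
    n = int(round(segment_length * fs))
    n_seg = int(duration // segment_length)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    psd = np.interp(freqs, target.freqs, target.power, left=target.power[0], right=0.0)
    # one-sided PSD -> rFFT amplitude scale: E|X_k|^2 = psd * fs * n / 2
    amp = np.sqrt(np.maximum(psd, 0.0) * fs * n / 2.0)
    amp[0] = 0.0  # zero-mean process
    labels = channel_labels or ["synth"]
    data = np.empty((len(labels), n_seg, n))
    for c in range(len(labels)):
        re = rng.standard_normal((n_seg, len(freqs)))
        im = rng.standard_normal((n_seg, len(freqs)))
        coeff = amp * (re + 1j * im) / np.sqrt(2.0)
        coeff[:, 0] = 0.0
        if n % 2 == 0:
            coeff[:, -1] = amp[-1] * re[:, -1]  # Nyquist bin is real
        data[c] = np.fft.irfft(coeff, n=n, axis=-1)
    return SegmentedEEG(data, fs=fs, channel_labels=labels)


# --------------------------------------------------------------------------
# longitudinal cohort
# --------------------------------------------------------------------------

def _logistic(x: np.ndarray, lo: float, hi: float, mid: float, scale: float) -> np.ndarray:
    return lo + (hi - lo) / (1.0 + np.exp(-(x - mid) / scale))


def default_age_functions() -> dict[str, Callable[[np.ndarray], np.ndarray]]:
    """Shipped developmental truth shapes used as recovery targets.

    Qualitative shapes: aperiodic offset rises steeply in the first year
    then plateaus; the dominant theta/alpha peak drifts from ~5.5 toward
    ~8 Hz; high-beta peak amplitude is unimodal with a maximum near day
    229.  These are synthetic recovery targets, not measured data.
    """
    return {
        "aperiodic_offset": lambda a: _logistic(np.asarray(a, float), 0.0, 0.8, 180.0, 70.0),
        "theta_alpha_peak_freq": lambda a: _logistic(np.asarray(a, float), 5.5, 8.0, 400.0, 150.0),
        "high_beta_peak_amp": lambda a: 0.5 * np.exp(-((np.asarray(a, float) - 229.0) ** 2) / (2 * 180.0**2)),
    }


@dataclass
class CohortGenSpec:
    """Generator settings for a longitudinal feature cohort.

    Visit schedule echoes the contributing studies (nominal visits at 2,
    6, 9, 12, 18, 24 and 36 months with jitter); each subject completes a
    random subset of at least ``min_visits`` visits.  Feature values are
    truth(age) + sex effects + study offset + subject random effects +
    residual noise.
    """

    n_subjects: int = 200
    visit_days: tuple[float, ...] = (75.0, 180.0, 270.0, 365.0, 550.0, 730.0, 1095.0)
    visit_jitter_sd: float = 15.0
    min_visits: int = 2
    max_visits: int = 5
    age_functions: dict[str, Callable] | None = None
    sex_main: float = 0.05          # additive female-minus-male shift
    sex_age_shift_days: float = 0.0  # shifts females' age function (interaction)
    n_studies: int = 3
    study_offset_sd: float = 0.05
    subject_intercept_sd: float = 0.08
    subject_slope_sd: float = 0.05   # per year of age
    residual_sd: float = 0.08
    low_beta_presence: tuple[float, float, float, float] = (0.1, 0.7, 500.0, 150.0)
    rois: tuple[str, ...] = ("whole",)
    roi_offsets: dict[str, float] | None = None
    seed: int = 0


def gen_cohort(spec: CohortGenSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate a longitudinal cohort table plus its generating truth.

    Returns a long-format DataFrame with columns (subject_id, age_days,
    sex, study, roi, measure, value) and a truth dict holding the age
    functions, the per-study and per-subject effects actually drawn, and
    the low-beta presence probability function.
    """
    rng = np.random.default_rng(spec.seed)
    age_funcs = spec.age_functions or default_age_functions()
    study_offsets = np.concatenate([[0.0], rng.normal(0, spec.study_offset_sd, spec.n_studies - 1)])
    p_lo, p_hi, p_mid, p_scale = spec.low_beta_presence
    rows = []
    subj_effects = {}
    for i in range(spec.n_subjects):
        sid = f"S{i:04d}"
        sex = "F" if rng.random() < 0.463 else "M"
        sex_c = 0.5 if sex == "F" else -0.5
        study = int(rng.integers(spec.n_studies))
        b0 = rng.normal(0, spec.subject_intercept_sd)
        b1 = rng.normal(0, spec.subject_slope_sd)
        subj_effects[sid] = (b0, b1)
        n_vis = int(rng.integers(spec.min_visits, spec.max_visits + 1))
        picks = rng.choice(len(spec.visit_days), size=n_vis, replace=False)
        ages = np.sort(
            np.asarray(spec.visit_days)[picks]
            + rng.normal(0, spec.visit_jitter_sd, n_vis)
        )
        ages = np.clip(ages, 40.0, None)
        for age in ages:
            eff_age = age - spec.sex_age_shift_days * sex_c  # shifts by-sex trajectory
            for roi in spec.rois:
                roi_off = (spec.roi_offsets or {}).get(roi, 0.0)
                for name, f in age_funcs.items():
                    val = (
                        float(f(np.asarray([eff_age]))[0])
                        + spec.sex_main * sex_c
                        + study_offsets[study]
                        + roi_off
                        + b0
                        + b1 * age / 365.0
                        + rng.normal(0, spec.residual_sd)
                    )
                    rows.append((sid, float(age), sex, f"study{study}", roi, name, val))
                p = _logistic(np.asarray([age]), p_lo, p_hi, p_mid, p_scale)[0]
                rows.append(
                    (sid, float(age), sex, f"study{study}", roi,
                     "low_beta_peak_present", float(rng.random() < p))
                )
    table = pd.DataFrame(
        rows,
        columns=["subject_id", "age_days", "sex", "study", "roi", "measure", "value"],
    )
    truth = {
        "age_functions": age_funcs,
        "study_offsets": study_offsets,
        "subject_effects": subj_effects,
        "low_beta_presence": lambda a: _logistic(np.asarray(a, float), p_lo, p_hi, p_mid, p_scale),
        "sex_main": spec.sex_main,
        "sex_age_shift_days": spec.sex_age_shift_days,
    }
    return table, truth


# --------------------------------------------------------------------------
# anesthesia cohort
# --------------------------------------------------------------------------

@dataclass
class SyntheticAnesthesiaRecording:
    """Four frontal channels plus a time-locked sevoflurane series."""

    channels: dict[str, np.ndarray]
    fs: float
    sevo: np.ndarray          # % at ``sevo_fs`` samples/s
    sevo_fs: float
    age_months: float
    low_beta_peak_present: bool
    subject_id: str = ""


@dataclass
class AnesthesiaGenSpec:
    """Generator settings for the anesthesia coherence arm.

    ``snr_*`` is the in-alpha-band power ratio between the shared alpha
    source and the summed independent noise of a bipolar derivation; the
    expected magnitude-squared coherence of the two derivations is
    (snr / (1 + snr))^2.
    """

    n_with_peak: int = 11
    n_without_peak: int = 10
    snr_with_peak: float = 1.45
    snr_without_peak: float = 0.8
    duration: float = 300.0
    fs: float = 250.0
    alpha_band: tuple[float, float] = (8.0, 12.0)
    noise_psd: float = 1.0     # flat channel-noise PSD, µV²/Hz
    sevo_mean: float = 2.5
    sevo_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr_with_peak < 0 or self.snr_without_peak < 0:
            raise ValueError("SNR must be >= 0")


def _band_noise(rng, n, fs, band, psd_level):
    """Gaussian noise with flat one-sided PSD ``psd_level`` inside ``band``."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    psd = np.where((freqs >= band[0]) & (freqs <= band[1]), psd_level, 0.0)
    amp = np.sqrt(psd * fs * n / 2.0)
    coeff = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))) / np.sqrt(2)
    coeff[0] = 0.0
    return np.fft.irfft(coeff, n=n)


def gen_anesthesia_cohort(
    spec: AnesthesiaGenSpec,
) -> tuple[list[SyntheticAnesthesiaRecording], dict]:
    """Simulate paired frontal recordings with controllable alpha coherence.

    A shared narrowband alpha source is injected into F7 and F8 while
    Fp1/Fp2 carry independent noise, so the bipolar pairs F7-Fp1 and
    F8-Fp2 share exactly the alpha source.  Sevoflurane is a slowly
    drifting step series with long stable stretches.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    recs = []
    groups = [(True, spec.n_with_peak, spec.snr_with_peak),
              (False, spec.n_without_peak, spec.snr_without_peak)]
    idx = 0
    for present, count, snr in groups:
        for _ in range(count):
            # bipolar noise power in band is 2*noise_psd -> source PSD = snr*2*noise_psd
            src_psd = snr * 2.0 * spec.noise_psd
            s = _band_noise(rng, n, spec.fs, spec.alpha_band, src_psd)
            noise = {
                ch: _band_noise(rng, n, spec.fs, (0.5, spec.fs / 2 * 0.9), spec.noise_psd)
                for ch in ("Fp1", "Fp2", "F7", "F8")
            }
            channels = {
                "Fp1": noise["Fp1"],
                "Fp2": noise["Fp2"],
                "F7": s + noise["F7"],
                "F8": s + noise["F8"],
            }
            # sevo: stable plateaus of 2-4 min with occasional 0.3-0.5% steps
            sevo_fs = 1.0
            t = np.arange(int(spec.duration * sevo_fs))
            level = rng.normal(spec.sevo_mean, spec.sevo_sd)
            sevo = np.full(len(t), level)
            pos = int(rng.integers(120, max(121, len(t))))
            if pos < len(t) and rng.random() < 0.3:
                sevo[pos:] += rng.choice([-0.4, 0.4])
            recs.append(
                SyntheticAnesthesiaRecording(
                    channels=channels,
                    fs=spec.fs,
                    sevo=sevo,
                    sevo_fs=sevo_fs,
                    age_months=float(rng.uniform(7, 12)),
                    low_beta_peak_present=present,
                    subject_id=f"A{idx:03d}",
                )
            )
            idx += 1
    truth = {
        "expected_coherence": {
            True: (spec.snr_with_peak / (1 + spec.snr_with_peak)) ** 2,
            False: (spec.snr_without_peak / (1 + spec.snr_without_peak)) ** 2,
        }
    }
    return recs, truth
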
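"""Anesthesia-induced frontal alpha coherence vs. low-beta-peak presence.

Frontal EEG recorded during sevoflurane anesthesia is re-referenced to a
bipolar montage (F7-Fp1, F8-Fp2), band-pass filtered 0.1-30 Hz, screened
for high-amplitude epochs by an SD rule, and restricted to epochs
preceded by two minutes of stable end-tidal sevoflurane (within 0.2%).
Magnitude-squared coherence between the two derivations is estimated by
the multitaper method (6-s windows, TW=3, K=5 tapers, no overlap) and
summarized as the median over the alpha band.  An ANCOVA with
sevoflurane level as covariate tests whether infants with a baseline
low-beta peak show higher anesthesia-induced alpha coherence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.signal import butter, sosfiltfilt
from scipy.signal.windows import dpss

__all__ = [
    "CoherenceRecord",
    "AncovaResult",
    "bipolar_montage",
    "bandpass_0p1_30",
    "reject_epochs_by_sd",
    "stable_sevo_mask",
    "multitaper_coherence",
    "median_alpha_coherence",
    "analyze_recording",
    "ancova_group_effect",
]

BIPOLAR_PAIRS = (("F7", "Fp1"), ("F8", "Fp2"))


@dataclass(frozen=True)
class CoherenceRecord:
    """Per-infant summary entering the group comparison."""

    median_alpha_coherence: float
    sevo_level: float
    low_beta_peak_present: bool
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.median_alpha_coherence <= 1:
            raise ValueError("coherence must lie in [0, 1]")


def bipolar_montage(channels: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Sample-wise F7-Fp1 and F8-Fp2 derivations."""
    for a, b in BIPOLAR_PAIRS:
        if a not in channels or b not in channels:
            raise KeyError(f"missing channel for bipolar pair {a}-{b}")
    return (
        np.asarray(channels["F7"], float) - np.asarray(channels["Fp1"], float),
        np.asarray(channels["F8"], float) - np.asarray(channels["Fp2"], float),
    )


def bandpass_0p1_30(signal: np.ndarray, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass, 0.1-30 Hz."""
    if fs <= 60:
        raise ValueError("sampling rate must exceed 60 Hz")
    sos = butter(order, [0.1, 30.0], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(signal, dtype=float))


def reject_epochs_by_sd(
    signal: np.ndarray, fs: float, epoch_length: float = 30.0, k_sd: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Exclude epochs whose SD exceeds ``k_sd`` x the median epoch SD.

    Returns (indices of retained epochs, per-epoch SDs).  Epochs are
    consecutive non-overlapping ``epoch_length``-second windows.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    n = int(round(epoch_length * fs))
    x = np.asarray(signal, dtype=float)
    n_epochs = len(x) // n
    sds = np.array([x[i * n : (i + 1) * n].std() for i in range(n_epochs)])
    if n_epochs == 0:
        warnings.warn("signal shorter than one epoch; nothing retained", stacklevel=2)
        return np.array([], dtype=int), sds
    keep = np.flatnonzero(sds <= k_sd * np.median(sds))
    if len(keep) == 0:
        warnings.warn("all epochs rejected by the SD screen", stacklevel=2)
    return keep, sds


def stable_sevo_mask(
    sevo: np.ndarray, sevo_fs: float = 1.0, window: float = 120.0, tol: float = 0.2
) -> np.ndarray:
    """Times preceded by ``window`` seconds of sevoflurane within ``tol`` %.

    Element ``t`` is True iff max - min of the series over
    ``[t - window, t]`` is <= ``tol``; the first ``window`` seconds are
    ineligible, and a recording shorter than the window is entirely
    ineligible.
    """
    x = np.asarray(sevo, dtype=float)
    w = int(round(window * sevo_fs))
    mask = np.zeros(len(x), dtype=bool)
    if len(x) <= w:
        return mask
    s = pd.Series(x)
    roll_max = s.rolling(w + 1).max().to_numpy()
    roll_min = s.rolling(w + 1).min().to_numpy()
    ok = (roll_max - roll_min) <= tol
    mask[w:] = ok[w:]
    return mask


def multitaper_coherence(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    window_length: float = 6.0,
    time_bandwidth: float = 3.0,
    n_tapers: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Multitaper magnitude-squared coherence on non-overlapping windows.

    Cross- and auto-spectra are averaged over all windows and tapers
    (spectral resolution 2W = 2*TW/T, i.e. 1 Hz at the defaults), then
    coh(f) = |Sxy|² / (Sxx Syy) in [0, 1].  Returns (freqs, coherence).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    n = int(round(window_length * fs))
    n_win = len(x) // n
    if n_win < 1:
        raise ValueError("signals shorter than one analysis window")
    tapers = dpss(n, time_bandwidth, Kmax=n_tapers)  # (K, n)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    xw = x[: n_win * n].reshape(n_win, 1, n) * tapers
    yw = y[: n_win * n].reshape(n_win, 1, n) * tapers
    X = np.fft.rfft(xw, axis=-1)
    Y = np.fft.rfft(yw, axis=-1)
    sxx = np.mean(X.real**2 + X.imag**2, axis=(0, 1))
    syy = np.mean(Y.real**2 + Y.imag**2, axis=(0, 1))
    sxy = np.mean(X * np.conj(Y), axis=(0, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(sxy) ** 2 / (sxx * syy)
    coh = np.nan_to_num(coh, nan=0.0)
    return freqs, np.clip(coh, 0.0, 1.0)


def median_alpha_coherence(
    freqs: np.ndarray, coh: np.ndarray, alpha_band: tuple[float, float] = (8.0, 13.0)
) -> float:
    """Median coherence within the alpha band."""
    m = (freqs >= alpha_band[0]) & (freqs <= alpha_band[1])
    if not m.any():
        raise ValueError("alpha band outside the coherence spectrum")
    return float(np.median(coh[m]))


def analyze_recording(
    channels: dict[str, np.ndarray],
    fs: float,
    sevo: np.ndarray,
    sevo_fs: float = 1.0,
    low_beta_peak_present: bool = False,
    subject_id: str = "",
    epoch_length: float = 30.0,
    k_sd: float = 3.0,
    alpha_band: tuple[float, float] = (8.0, 13.0),
    sevo_window: float = 120.0,
    sevo_tol: float = 0.2,
) -> CoherenceRecord | None:
    """Full per-subject pipeline from raw frontal channels to a record.

    Returns None when no epoch survives the stability and SD screens.
    """
    d1, d2 = bipolar_montage(channels)
    d1 = bandpass_0p1_30(d1, fs)
    d2 = bandpass_0p1_30(d2, fs)
    mask = stable_sevo_mask(sevo, sevo_fs, window=sevo_window, tol=sevo_tol)
    n = int(round(epoch_length * fs))
    n_epochs = len(d1) // n
    # epoch eligible if its start time has stable preceding sevoflurane
    eligible = []
    for i in range(n_epochs):
        t_start = i * epoch_length
        j = int(round(t_start * sevo_fs))
        if j < len(mask) and mask[j]:
            eligible.append(i)
    if not eligible:
        return None
    keep1, sds1 = reject_epochs_by_sd(d1, fs, epoch_length, k_sd)
    keep2, sds2 = reject_epochs_by_sd(d2, fs, epoch_length, k_sd)
    good = sorted(set(eligible) & set(keep1.tolist()) & set(keep2.tolist()))
    if not good:
        return None
    seg1 = np.concatenate([d1[i * n : (i + 1) * n] for i in good])
    seg2 = np.concatenate([d2[i * n : (i + 1) * n] for i in good])
    freqs, coh = multitaper_coherence(seg1, seg2, fs)
    mac = median_alpha_coherence(freqs, coh, alpha_band)
    sevo_used = float(
        np.mean([sevo[int(round(i * epoch_length * sevo_fs))] for i in good])
    )
    return CoherenceRecord(mac, sevo_used, low_beta_peak_present, subject_id)


@dataclass(frozen=True)
class AncovaResult:
    group_effect: float
    pvalue: float
    sevo_coef: float
    n_with_peak: int
    n_without_peak: int


def ancova_group_effect(records: list[CoherenceRecord]) -> AncovaResult:
    """ANCOVA: coherence ~ low_beta_peak_present + sevoflurane level.

    The reported effect is the adjusted with-peak minus without-peak
    difference in median alpha coherence.
    """
    if not records:
        raise ValueError("no coherence records")
    g = np.array([1.0 if r.low_beta_peak_present else 0.0 for r in records])
    sevo = np.array([r.sevo_level for r in records])
    coh = np.array([r.median_alpha_coherence for r in records])
    n1, n0 = int(g.sum()), int(len(g) - g.sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both groups (with/without low-beta peak) must be non-empty")
    X = np.column_stack([np.ones_like(g), g, sevo])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "degenerate ANCOVA design: group and sevoflurane columns are collinear"
        )
    res = sm.OLS(coh, X).fit()
    return AncovaResult(
        group_effect=float(res.params[1]),
        pvalue=float(res.pvalues[1]),
        sevo_coef=float(res.params[2]),
        n_with_peak=n1,
        n_without_peak=n0,
    )
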
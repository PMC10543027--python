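"""Delimited-table readers and writers for every pipeline artifact.

Spectra travel as CSV with a ``freq_hz`` column plus one column per
channel or ROI; QC metrics, cohort tables, and multichannel time series
are plain CSV with fixed column orders.  EDF recordings are read through
mne when available (optional dependency); everything the pipeline writes
is text.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .periodic_features import PEAK_BANDS, POWER_BANDS, PeriodicFeatures
from .spectral_estimation import PowerSpectrum, QCMetrics, SegmentedEEG
from .specparam import SpectralModel

__all__ = [
    "read_spectra_csv",
    "write_spectra_csv",
    "read_qc_csv",
    "read_channels_csv",
    "write_channels_csv",
    "read_sevo_csv",
    "read_eeg",
    "model_row",
    "features_row",
]

QC_COLUMNS = [
    "n_segments",
    "pct_good_channels",
    "pct_ics_rejected",
    "mean_artifact_prob",
    "pct_variance_retained",
]


def read_spectra_csv(path: str | Path) -> list[PowerSpectrum]:
    """CSV with columns freq_hz, <label1>, <label2>, ... -> spectra."""
    df = pd.read_csv(path)
    if "freq_hz" not in df.columns:
        raise ValueError(f"{path}: missing 'freq_hz' column")
    freqs = df["freq_hz"].to_numpy(dtype=float)
    return [
        PowerSpectrum(freqs, df[c].to_numpy(dtype=float), label=c)
        for c in df.columns
        if c != "freq_hz"
    ]


def write_spectra_csv(path: str | Path, spectra: list[PowerSpectrum]) -> None:
    base = spectra[0].freqs
    data = {"freq_hz": base}
    for s in spectra:
        if not np.array_equal(s.freqs, base):
            raise ValueError("spectra must share one frequency grid")
        data[s.label or f"ch{len(data)}"] = s.power
    pd.DataFrame(data).to_csv(path, index=False)


def read_qc_csv(path: str | Path) -> list[QCMetrics]:
    df = pd.read_csv(path)
    missing = set(QC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing QC columns {sorted(missing)}")
    return [
        QCMetrics(
            n_segments=int(row.n_segments),
            pct_good_channels=float(row.pct_good_channels),
            pct_ics_rejected=float(row.pct_ics_rejected),
            mean_artifact_prob=float(row.mean_artifact_prob),
            pct_variance_retained=float(row.pct_variance_retained),
        )
        for row in df.itertuples()
    ]


def read_channels_csv(path: str | Path) -> tuple[dict[str, np.ndarray], float]:
    """CSV with a time_s column plus one column per channel."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing 'time_s' column")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples")
    fs = 1.0 / float(np.mean(np.diff(t)))
    channels = {
        c: df[c].to_numpy(dtype=float) for c in df.columns if c != "time_s"
    }
    return channels, fs


def write_channels_csv(path: str | Path, channels: dict[str, np.ndarray], fs: float) -> None:
    n = len(next(iter(channels.values())))
    data = {"time_s": np.arange(n) / fs}
    data.update(channels)
    pd.DataFrame(data).to_csv(path, index=False)


def read_sevo_csv(path: str | Path) -> tuple[np.ndarray, float]:
    """CSV with columns time_s, sevo_pct -> (series, sampling rate)."""
    df = pd.read_csv(path)
    for col in ("time_s", "sevo_pct"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing '{col}' column")
    t = df["time_s"].to_numpy(dtype=float)
    fs = 1.0 / float(np.mean(np.diff(t))) if len(t) > 1 else 1.0
    return df["sevo_pct"].to_numpy(dtype=float), fs


def read_eeg(path: str | Path, segment_length: float = 2.0) -> SegmentedEEG:
    """Read an EDF recording (via mne) or a channels CSV into segments."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne  # optional dependency, only needed for EDF input

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # volts -> microvolts
        fs = float(raw.info["sfreq"])
        labels = list(raw.ch_names)
    else:
        channels, fs = read_channels_csv(path)
        labels = list(channels)
        data = np.vstack([channels[c] for c in labels])
    n = int(round(segment_length * fs))
    n_seg = data.shape[1] // n
    if n_seg == 0:
        raise ValueError(f"{path}: recording shorter than one segment")
    segs = data[:, : n_seg * n].reshape(data.shape[0], n_seg, n)
    return SegmentedEEG(segs, fs=fs, channel_labels=labels)


def model_row(label: str, model: SpectralModel) -> dict:
    """Flatten a SpectralModel into one CSV row (peak triplets appended)."""
    row = {
        "label": label,
        "b": model.aperiodic.b,
        "chi": model.aperiodic.chi,
        "offset_at_2p5": model.offset_at_2p5,
        "r_squared": model.r_squared,
        "mean_abs_error": model.mean_abs_error,
        "n_peaks": len(model.peaks),
    }
    for i, p in enumerate(model.peaks):
        row[f"peak{i}_center_hz"] = p.center
        row[f"peak{i}_height"] = p.height
        row[f"peak{i}_width_hz"] = p.width
    return row


def features_row(label: str, feats: PeriodicFeatures) -> dict:
    """Flatten PeriodicFeatures into one CSV row with fixed columns."""
    row: dict = {"label": label}
    for band in PEAK_BANDS:
        pk = feats.peaks.get(band)
        row[f"{band}_peak_hz"] = pk.frequency if pk else np.nan
        row[f"{band}_peak_amp"] = pk.amplitude if pk else np.nan
    tr = feats.low_beta_trough
    row["trough_hz"] = tr.frequency if tr else np.nan
    row["trough_amp"] = tr.amplitude if tr else np.nan
    row["dual_peak_4_12"] = bool(feats.dual_peak_4_12)
    for band in POWER_BANDS:
        row[f"{band}_periodic_power"] = feats.band_powers_periodic[band]
        row[f"{band}_aperiodic_power"] = feats.band_powers_aperiodic[band]
    return row
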
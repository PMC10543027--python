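"""Multitaper power spectral density estimation and recording-level QC.

Segmented, artifact-free EEG (2-s segments at 250 Hz in the cohorts this
package targets) is turned into one-sided power spectral densities per
channel using discrete prolate spheroidal sequence (DPSS) tapers, averaged
first across tapers and then across segments.  Channel spectra are combined
into region-of-interest (ROI) spectra by arithmetic averaging of linear
power.  A five-predicate quality gate decides whether a recording enters
further analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import dpss

__all__ = [
    "SegmentedEEG",
    "QCMetrics",
    "PowerSpectrum",
    "RoiMap",
    "QCDecision",
    "DEFAULT_ROIS",
    "compute_multitaper_psd",
    "average_spectra",
    "filter_eeg_quality",
]


@dataclass
class SegmentedEEG:
    """Artifact-free EEG cut into equal-length segments.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_segments, n_samples)
        Voltage in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Electrode names, one per channel.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 and self.data.ndim != 3:
            raise ValueError("data must be (channel, segment, sample)")
        if self.data.ndim == 2:  # single channel convenience
            self.data = self.data[np.newaxis]
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_segments(self) -> int:
        return self.data.shape[1]

    @property
    def segment_length(self) -> float:
        """Segment duration in seconds."""
        return self.data.shape[2] / self.fs


@dataclass(frozen=True)
class QCMetrics:
    """HAPPE-style data quality metrics for one recording."""

    n_segments: int
    pct_good_channels: float
    pct_ics_rejected: float
    mean_artifact_prob: float
    pct_variance_retained: float

    def __post_init__(self) -> None:
        # NaN marks a missing metric; filter_eeg_quality errors on it
        for name in ("pct_good_channels", "pct_ics_rejected", "pct_variance_retained"):
            v = getattr(self, name)
            if not np.isnan(v) and not 0 <= v <= 100:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if not np.isnan(self.mean_artifact_prob) and not 0 <= self.mean_artifact_prob <= 1:
            raise ValueError("mean_artifact_prob outside [0, 1]")


@dataclass
class PowerSpectrum:
    """One-sided PSD on a uniform frequency grid (linear power, µV²/Hz)."""

    freqs: np.ndarray
    power: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have equal length")
        d = np.diff(self.freqs)
        if len(d) and (np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-6)):
            raise ValueError("frequency grid must be strictly increasing and uniform")

    def restrict(self, f_lo: float, f_hi: float) -> "PowerSpectrum":
        """Return a copy limited to ``f_lo <= f <= f_hi``."""
        m = (self.freqs >= f_lo) & (self.freqs <= f_hi)
        return PowerSpectrum(self.freqs[m], self.power[m], self.label)


#: 10-20 system ROI membership used when no map is supplied.
DEFAULT_ROIS: dict[str, list[str]] = {
    "frontal": ["Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz"],
    "central": ["C3", "C4", "Cz"],
    "temporal": ["T3", "T4", "T5", "T6"],
    "posterior": ["P3", "P4", "Pz", "O1", "O2"],
}


@dataclass
class RoiMap:
    """Mapping roi_name -> member channel labels.

    A ``whole`` ROI spanning every channel of the recording is added
    automatically by :func:`average_spectra` unless already present.
    """

    rois: dict[str, list[str]] = field(default_factory=lambda: dict(DEFAULT_ROIS))

    def __post_init__(self) -> None:
        for name, chans in self.rois.items():
            if not chans:
                raise ValueError(f"ROI '{name}' is empty")


def compute_multitaper_psd(
    eeg: SegmentedEEG,
    n_tapers: int = 3,
    time_half_bandwidth: float = 2.0,
) -> list[PowerSpectrum]:
    """Per-channel multitaper PSD, averaged over tapers then segments.

    Uses ``n_tapers`` orthogonal DPSS tapers with time-half-bandwidth
    product ``NW = time_half_bandwidth`` (default NW=2, K=3 tapers).  The
    one-sided PSD integrates to the signal variance (Parseval, within
    taper bias).  The frequency grid spans 0 to fs/2 with spacing
    1/segment_length.
    """
    if n_tapers < 1:
        raise ValueError("n_tapers must be >= 1")
    if eeg.n_segments == 0:
        raise ValueError("no segments")
    n = eeg.data.shape[2]
    if n < 2:
        raise ValueError("segments must contain at least 2 samples")
    if np.isnan(eeg.data).any():
        raise ValueError("NaN samples in EEG data")

    tapers = dpss(n, time_half_bandwidth, Kmax=n_tapers)  # (K, n), unit energy
    freqs = np.fft.rfftfreq(n, d=1.0 / eeg.fs)
    # (channel, segment, taper, freq)
    spec = np.fft.rfft(eeg.data[:, :, np.newaxis, :] * tapers, axis=-1)
    pxx = (spec.real**2 + spec.imag**2) / eeg.fs
    # one-sided: double everything except DC and (for even n) Nyquist
    pxx *= 2.0
    pxx[..., 0] /= 2.0
    if n % 2 == 0:
        pxx[..., -1] /= 2.0
    mean_pxx = pxx.mean(axis=(1, 2))  # over segments and tapers (equal weights)
    return [
        PowerSpectrum(freqs, mean_pxx[c], label=eeg.channel_labels[c])
        for c in range(eeg.n_channels)
    ]


def average_spectra(
    spectra: list[PowerSpectrum], roi: RoiMap | None = None
) -> dict[str, PowerSpectrum]:
    """Average linear power of member channels per ROI (plus whole brain)."""
    if not spectra:
        raise ValueError("no spectra to average")
    base = spectra[0].freqs
    for s in spectra[1:]:
        if s.freqs.shape != base.shape or not np.array_equal(s.freqs, base):
            raise ValueError("frequency grid mismatch between spectra")
    by_label = {s.label: s for s in spectra}
    roi = roi or RoiMap()
    rois = dict(roi.rois)
    rois.setdefault("whole", [s.label for s in spectra])
    out: dict[str, PowerSpectrum] = {}
    for name, chans in rois.items():
        missing = [c for c in chans if c not in by_label]
        if missing:
            raise KeyError(f"ROI '{name}' references missing channels: {missing}")
        stack = np.vstack([by_label[c].power for c in chans])
        out[name] = PowerSpectrum(base.copy(), stack.mean(axis=0), label=name)
    return out


@dataclass(frozen=True)
class QCDecision:
    accept: bool
    violations: tuple[str, ...]


# (field, comparator, threshold, human-readable reason); rejection uses
# strict inequalities, so a recording sitting exactly on every threshold
# is accepted.
_QC_RULES = (
    ("n_segments", "lt", 20, "fewer than 20 segments"),
    ("pct_good_channels", "lt", 80.0, "percent good channels < 80%"),
    ("pct_ics_rejected", "gt", 80.0, "percent independent components rejected > 80%"),
    ("mean_artifact_prob", "gt", 0.3, "mean artifact probability > 0.3"),
    ("pct_variance_retained", "lt", 25.0, "percent variance retained < 25%"),
)


def filter_eeg_quality(qc: QCMetrics) -> QCDecision:
    """Accept/reject a recording on the five HAPPE quality predicates.

    Rejects iff n_segments < 20, percent good channels < 80, percent ICs
    rejected > 80, mean artifact probability of kept components > 0.3, or
    percent variance retained < 25; every violated criterion is listed.
    """
    violations = []
    for name, op, thresh, reason in _QC_RULES:
        value = getattr(qc, name)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise ValueError(f"QC metric '{name}' is missing")
        if (op == "lt" and value < thresh) or (op == "gt" and value > thresh):
            violations.append(reason)
    return QCDecision(accept=not violations, violations=tuple(violations))
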
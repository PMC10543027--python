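"""Spectral parameterization: robust aperiodic fit with baseline elevation.

The EEG power spectrum is decomposed, in log10 space, into an aperiodic
1/f component ``L(f) = b - chi * log10(f)`` (fixed mode, no knee) plus up
to seven Gaussian peaks.  Infant spectra between roughly 2 and 7 months
show a pronounced trough in the 10-20 Hz range that dips *below* the
aperiodic line; the classic robust-fit step clips such negative points of
the initial flattened spectrum to zero, which discards exactly the data
that define the trough and biases the aperiodic estimate upward.

The ``modified`` variant implemented here instead *shifts* the initial
flattened spectrum so its minimum is zero (keeping the trough shape), and
additionally clips the second flattened spectrum to zero before peak
fitting.  The ``original`` variant reproduces the classic behaviour
(clip during the robust stage, no clip before peak fitting).  In both
variants the aperiodic component is refit a third and final time on the
peak-removed spectrum, and the reported offset is the modeled aperiodic
log-power at 2.5 Hz rather than the 0 Hz extrapolation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .spectral_estimation import PowerSpectrum

__all__ = [
    "AperiodicParams",
    "GaussianPeak",
    "SpectralModel",
    "SpecparamOptions",
    "simple_aperiodic_fit",
    "robust_aperiodic_fit_modified",
    "flatten_and_clip",
    "fit_peaks",
    "fit_spectrum",
    "aperiodic_curve",
    "gaussian",
    "peak_model",
]

logger = logging.getLogger(__name__)

DEFAULT_FIT_RANGE = (2.5, 50.0)


@dataclass(frozen=True)
class AperiodicParams:
    """Fixed-mode aperiodic component: log10 P(f) = b - chi * log10(f)."""

    b: float
    chi: float

    def curve(self, freqs: np.ndarray) -> np.ndarray:
        return self.b - self.chi * np.log10(freqs)

    def at(self, freq: float) -> float:
        """Aperiodic log10 power at a single frequency."""
        return self.b - self.chi * np.log10(freq)


def aperiodic_curve(freqs: np.ndarray, ap: AperiodicParams) -> np.ndarray:
    return ap.curve(np.asarray(freqs, dtype=float))


@dataclass(frozen=True)
class GaussianPeak:
    """One periodic peak: Gaussian in log10-power over linear frequency.

    ``width`` is the Gaussian standard deviation in Hz; the reported
    bandwidth convention is 2*width.
    """

    center: float
    height: float
    width: float

    def curve(self, freqs: np.ndarray) -> np.ndarray:
        return self.height * np.exp(-((freqs - self.center) ** 2) / (2 * self.width**2))


def gaussian(freqs: np.ndarray, center: float, height: float, width: float) -> np.ndarray:
    return height * np.exp(-((np.asarray(freqs) - center) ** 2) / (2 * width**2))


def peak_model(freqs: np.ndarray, peaks: list[GaussianPeak]) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    out = np.zeros_like(freqs)
    for p in peaks:
        out += p.curve(freqs)
    return out


@dataclass(frozen=True)
class SpecparamOptions:
    """Tunable parameters of the parameterization."""

    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE
    max_n_peaks: int = 7
    peak_threshold: float = 2.0
    peak_width_limits: tuple[float, float] = (0.5, 18.0)
    min_peak_height: float = 0.0
    robust_percentile: float = 2.5
    variant: str = "modified"  # or "original"

    @property
    def gauss_std_limits(self) -> tuple[float, float]:
        # peak_width_limits bound 2*SD of the Gaussian
        return (self.peak_width_limits[0] / 2, self.peak_width_limits[1] / 2)


@dataclass
class SpectralModel:
    """Fitted decomposition of one power spectrum."""

    aperiodic: AperiodicParams
    peaks: list[GaussianPeak]
    fit_range: tuple[float, float]
    r_squared: float
    mean_abs_error: float
    offset_at_2p5: float
    freqs: np.ndarray = field(repr=False, default=None)
    model_log_power: np.ndarray = field(repr=False, default=None)

    def aperiodic_curve(self, freqs: np.ndarray) -> np.ndarray:
        return self.aperiodic.curve(np.asarray(freqs, dtype=float))

    def full_curve(self, freqs: np.ndarray) -> np.ndarray:
        return self.aperiodic_curve(freqs) + peak_model(freqs, self.peaks)


def simple_aperiodic_fit(log_power: np.ndarray, freqs: np.ndarray) -> AperiodicParams:
    """Least-squares fit of log10 P(f) = b - chi*log10(f).

    The model is linear in (b, chi), so the exact least-squares solution
    is used; its residual sum of squares can never exceed that of the
    endpoints-based initial guess.
    """
    log_power = np.asarray(log_power, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if log_power.shape != freqs.shape:
        raise ValueError("log_power and freqs must have equal length")
    if len(freqs) < 3:
        raise ValueError("need at least 3 points for an aperiodic fit")
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")
    lf = np.log10(freqs)
    design = np.column_stack([np.ones_like(lf), -lf])
    (b, chi), *_ = np.linalg.lstsq(design, log_power, rcond=None)
    return AperiodicParams(float(b), float(chi))


def robust_aperiodic_fit_modified(
    log_power: np.ndarray,
    freqs: np.ndarray,
    percentile: float = 2.5,
    variant: str = "modified",
    initial: AperiodicParams | None = None,
) -> AperiodicParams:
    """Robust aperiodic fit with elevated (or clipped) initial flatspec.

    Stages: (i) initial simple fit; (ii) flatspec = log_power - fit;
    ``modified``: if min(flatspec) < 0 the whole flatspec is shifted up so
    its minimum is 0 (no data discarded); ``original``: negative flatspec
    values are set to 0; (iii) points with flatspec at or below its
    ``percentile``-th percentile are retained; (iv) the aperiodic model is
    refit on the retained points of the *original* log spectrum.

    ``initial`` overrides the stage-(i) simple fit (useful for probing
    the shift/clip branch with a known flattened spectrum).
    """
    log_power = np.asarray(log_power, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if initial is None:
        initial = simple_aperiodic_fit(log_power, freqs)
    flatspec = log_power - initial.curve(freqs)
    if variant == "modified":
        m = flatspec.min()
        if m < 0:
            flatspec = flatspec - m
    elif variant == "original":
        flatspec = np.where(flatspec < 0, 0.0, flatspec)
    else:
        raise ValueError(f"unknown variant '{variant}'")
    thresh = np.percentile(flatspec, percentile)
    mask = flatspec <= thresh
    if mask.sum() < 3:
        # keep the smallest 3 so the 2-parameter refit is determined
        mask = np.zeros_like(mask)
        mask[np.argsort(flatspec, kind="stable")[:3]] = True
    if not mask.any():
        raise ValueError("empty robust mask")
    return simple_aperiodic_fit(log_power[mask], freqs[mask])


def flatten_and_clip(
    log_power: np.ndarray, ap: AperiodicParams, freqs: np.ndarray
) -> np.ndarray:
    """Element-wise max(0, log_power - aperiodic curve)."""
    log_power = np.asarray(log_power, dtype=float)
    if not (np.isfinite(ap.b) and np.isfinite(ap.chi)):
        raise ValueError("aperiodic parameters must be finite")
    return np.maximum(0.0, log_power - ap.curve(np.asarray(freqs, dtype=float)))


def _half_height_std(flat: np.ndarray, freqs: np.ndarray, idx: int, height: float) -> float:
    """Estimate a Gaussian SD from the half-height extent around ``idx``."""
    half = 0.5 * height
    le = idx
    while le > 0 and flat[le - 1] > half:
        le -= 1
    ri = idx
    n = len(flat)
    while ri < n - 1 and flat[ri + 1] > half:
        ri += 1
    # distance in Hz from the peak to the closest half-height crossing
    sides = []
    if le > 0:
        sides.append(freqs[idx] - freqs[le])
    if ri < n - 1:
        sides.append(freqs[ri] - freqs[idx])
    if not sides:
        sides = [freqs[1] - freqs[0]]
    short = min(s for s in sides if s > 0) if any(s > 0 for s in sides) else freqs[1] - freqs[0]
    fwhm = 2.0 * short
    return fwhm / (2 * np.sqrt(2 * np.log(2)))


def fit_peaks(
    flattened: np.ndarray,
    freqs: np.ndarray,
    max_n_peaks: int = 7,
    peak_threshold: float = 2.0,
    peak_width_limits: tuple[float, float] = (0.5, 18.0),
    min_peak_height: float = 0.0,
) -> list[GaussianPeak]:
    """Iteratively extract Gaussian peaks from a flattened spectrum.

    Repeatedly takes the global maximum of the residual flattened
    spectrum, stops when its height falls below
    ``peak_threshold * SD(residual)`` (or ``min_peak_height``), estimates
    the SD from the half-height extent clamped to
    ``peak_width_limits / 2``, subtracts the guess, and finally refits all
    retained Gaussians jointly by bounded least squares.  Peaks whose
    center lies within one SD of the frequency range edge are dropped.
    """
    flat = np.asarray(flattened, dtype=float).copy()
    freqs = np.asarray(freqs, dtype=float)
    std_lo, std_hi = peak_width_limits[0] / 2, peak_width_limits[1] / 2
    # the stop threshold is fixed from the input flattened spectrum; 1e-8
    # log10-units is a numerical floor for noise-free spectra
    stop = max(peak_threshold * float(np.std(flat)), min_peak_height, 1e-8)
    guesses: list[tuple[float, float, float]] = []
    for _ in range(max_n_peaks):
        idx = int(np.argmax(flat))
        height = flat[idx]
        if height <= stop:
            break
        center = freqs[idx]
        g_std = float(np.clip(_half_height_std(flat, freqs, idx, height), std_lo, std_hi))
        guesses.append((center, float(height), g_std))
        flat = flat - gaussian(freqs, center, height, g_std)
    # drop guesses too close to the fit-range edge to be resolvable
    guesses = [
        g for g in guesses
        if g[0] - g[2] >= freqs[0] and g[0] + g[2] <= freqs[-1]
    ]
    if not guesses:
        return []
    peaks = _joint_refit(np.asarray(flattened, dtype=float), freqs, guesses, (std_lo, std_hi))
    return sorted(peaks, key=lambda p: p.center)


def _joint_refit(
    flat: np.ndarray,
    freqs: np.ndarray,
    guesses: list[tuple[float, float, float]],
    std_limits: tuple[float, float],
    cf_bound: float = 1.5,
) -> list[GaussianPeak]:
    """Joint bounded least-squares refit of all peak guesses."""

    def model(f, *params):
        out = np.zeros_like(f)
        for i in range(0, len(params), 3):
            out += gaussian(f, params[i], params[i + 1], params[i + 2])
        return out

    guesses = list(guesses)
    while guesses:
        p0, lo, hi = [], [], []
        for c, h, s in guesses:
            p0 += [c, h, s]
            lo += [max(c - cf_bound * s, freqs[0]), 0.0, std_limits[0]]
            hi += [min(c + cf_bound * s, freqs[-1]), np.inf, std_limits[1]]
        p0 = [float(np.clip(v, l, u)) for v, l, u in zip(p0, lo, hi)]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    model, freqs, flat, p0=p0, bounds=(lo, hi), maxfev=5000
                )
        except (RuntimeError, ValueError):
            dropped = min(range(len(guesses)), key=lambda i: guesses[i][1])
            logger.warning(
                "joint peak refit failed to converge; dropping smallest peak "
                "near %.2f Hz", guesses[dropped][0],
            )
            guesses.pop(dropped)
            continue
        return [
            GaussianPeak(float(popt[i]), float(popt[i + 1]), float(popt[i + 2]))
            for i in range(0, len(popt), 3)
        ]
    return []


def fit_spectrum(
    spec: PowerSpectrum, options: SpecparamOptions | None = None
) -> SpectralModel:
    """Full parameterization pipeline for one power spectrum.

    Trims to the fit range (default 2.5-50 Hz), log10-transforms, runs the
    robust aperiodic fit, flattens (clipping negatives in the ``modified``
    variant), extracts peaks, then refits the aperiodic component a third
    time on the peak-removed spectrum.  Reported offset is the aperiodic
    log10 power at 2.5 Hz.
    """
    opt = options or SpecparamOptions()
    sub = spec.restrict(*opt.fit_range)
    if len(sub.freqs) < 3:
        raise ValueError(
            f"spectrum does not cover the fit range {opt.fit_range}"
        )
    if np.any(sub.power <= 0):
        raise ValueError("power must be positive within the fit range")
    freqs = sub.freqs
    log_power = np.log10(sub.power)

    try:
        ap_robust = robust_aperiodic_fit_modified(
            log_power, freqs, percentile=opt.robust_percentile, variant=opt.variant
        )
    except ValueError as err:
        raise ValueError(f"robust aperiodic stage: {err}") from err

    flat = log_power - ap_robust.curve(freqs)
    if opt.variant == "modified":
        flat = np.maximum(0.0, flat)

    try:
        peaks = fit_peaks(
            flat,
            freqs,
            max_n_peaks=opt.max_n_peaks,
            peak_threshold=opt.peak_threshold,
            peak_width_limits=opt.peak_width_limits,
            min_peak_height=opt.min_peak_height,
        )
    except ValueError as err:
        raise ValueError(f"peak fitting stage: {err}") from err

    peak_fit = peak_model(freqs, peaks)
    ap_final = simple_aperiodic_fit(log_power - peak_fit, freqs)
    model = ap_final.curve(freqs) + peak_fit
    resid = log_power - model
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((log_power - log_power.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    mae = float(np.mean(np.abs(resid)))
    return SpectralModel(
        aperiodic=ap_final,
        peaks=peaks,
        fit_range=opt.fit_range,
        r_squared=r2,
        mean_abs_error=mae,
        offset_at_2p5=ap_final.at(2.5),
        freqs=freqs,
        model_log_power=model,
    )
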
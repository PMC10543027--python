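"""Periodic spectrum construction, smoothing, and band feature extraction."""

import numpy as np
import pytest

from infantspec.periodic_features import (
    PeriodicSpectrum,
    band_power,
    detect_features,
    extract_features,
    periodic_spectrum,
    smooth_periodic,
)
from infantspec.specparam import SpecparamOptions, fit_spectrum, gaussian
from infantspec.spectral_estimation import PowerSpectrum
from infantspec.synthetic_data import SpectrumGenSpec, gen_spectrum


def make_periodic(freqs, periodic, smoothed=None):
    return PeriodicSpectrum(freqs, periodic, np.zeros_like(freqs), smoothed=smoothed)


@pytest.fixture
def fitted_pair():
    spec, _ = gen_spectrum(SpectrumGenSpec(
        b=1.5, chi=1.0, peaks=[(9.5, 0.5, 1.2)], noise_sd=0.0, seed=0))
    return spec, fit_spectrum(spec)


class TestPeriodicSpectrum:
    def test_aperiodic_only_gives_zero(self):
        spec, _ = gen_spectrum(SpectrumGenSpec(b=1.2, chi=0.9, noise_sd=0.0))
        model = fit_spectrum(spec)
        ps = periodic_spectrum(spec, model)
        assert np.all(np.abs(ps.periodic_power) < 1e-6)

    def test_injected_peak_amplitude_preserved(self, fitted_pair):
        spec, model = fitted_pair
        ps = periodic_spectrum(spec, model)
        i = np.argmin(np.abs(ps.freqs - 9.5))
        assert ps.periodic_power[i] == pytest.approx(0.5, abs=0.02)

    def test_interpolation_order_equivalence(self, fitted_pair):
        """Subtract-then-interpolate equals interpolate-then-subtract when
        both orders use the same linear interpolant (linearity)."""
        spec, model = fitted_pair
        ps = periodic_spectrum(spec, model, target_resolution=0.1)
        sub = spec.restrict(*model.fit_range)
        log_p_i = np.interp(ps.freqs, sub.freqs, np.log10(sub.power))
        ap_i = np.interp(ps.freqs, sub.freqs, model.aperiodic_curve(sub.freqs))
        np.testing.assert_allclose(ps.periodic_power, log_p_i - ap_i, atol=1e-6)

    def test_grid_outside_fit_range_rejected(self, fitted_pair):
        spec, model = fitted_pair
        with pytest.raises(ValueError, match="fit range"):
            periodic_spectrum(spec.restrict(5.0, 30.0), model)


class TestSmoothing:
    GRID = np.arange(2.5, 50.001, 0.1)

    def test_polynomial_reproduction(self):
        """Savitzky-Golay with polyorder 8 reproduces polynomials up to its
        order (to float conditioning of the order-8 design at window 101)."""
        x = (self.GRID - 25) / 25
        # the order-8, 101-point coefficient solve is ill-conditioned, so
        # reproduction is exact only to ~1e-3 in float64 for any degree
        cubic = 2 * x**3 - x + 0.1
        out = smooth_periodic(make_periodic(self.GRID, cubic), 101, 8)
        np.testing.assert_allclose(out.smoothed, cubic, atol=5e-3)
        deg8 = 0.3 * x**8 - x**5 + 2 * x**2 + 0.1
        out8 = smooth_periodic(make_periodic(self.GRID, deg8), 101, 8)
        np.testing.assert_allclose(out8.smoothed, deg8, atol=5e-3)
        # a short low-order window is numerically exact
        out3 = smooth_periodic(make_periodic(self.GRID, cubic), 11, 3)
        np.testing.assert_allclose(out3.smoothed, cubic, atol=1e-10)

    def test_zero_input_zero_output(self):
        out = smooth_periodic(make_periodic(self.GRID, np.zeros_like(self.GRID)))
        np.testing.assert_array_equal(out.smoothed, 0.0)

    def test_noisy_peak_location_preserved(self):
        rng = np.random.default_rng(6)
        clean = gaussian(self.GRID, 20.0, 1.0, 2.0)
        noisy = clean + rng.normal(0, 0.05, len(self.GRID))
        out = smooth_periodic(make_periodic(self.GRID, noisy))
        f_max = self.GRID[np.argmax(out.smoothed)]
        assert abs(f_max - 20.0) < 0.3

    def test_window_preconditions(self):
        ps = make_periodic(self.GRID, np.zeros_like(self.GRID))
        with pytest.raises(ValueError, match="odd"):
            smooth_periodic(ps, window=100)
        with pytest.raises(ValueError, match="polyorder"):
            smooth_periodic(ps, window=7, polyorder=8)
        coarse = make_periodic(self.GRID[::10], np.zeros(len(self.GRID[::10])))
        with pytest.raises(ValueError, match="finer target_resolution"):
            smooth_periodic(coarse, window=101)


class TestDetectFeatures:
    GRID = np.arange(2.5, 50.001, 0.1)

    def smoothed_ps(self, curve):
        ps = make_periodic(self.GRID, curve)
        return smooth_periodic(ps)

    def test_dual_theta_alpha_peaks(self):
        """The 2-4 month phenotype: peaks near 5.5 and 9.5 Hz produce a
        dual-peak flag, a theta peak, and the taller peak wins theta/alpha."""
        curve = gaussian(self.GRID, 5.5, 0.4, 0.8) + gaussian(self.GRID, 9.5, 0.45, 1.0)
        feats = detect_features(self.smoothed_ps(curve))
        assert feats.dual_peak_4_12
        assert feats.peaks["theta"].frequency == pytest.approx(5.5, abs=0.2)
        assert feats.peaks["theta_alpha"].frequency == pytest.approx(9.5, abs=0.2)

    def test_monotone_low_beta_band_has_no_peak(self):
        curve = -0.02 * self.GRID  # strictly decreasing everywhere
        feats = detect_features(self.smoothed_ps(curve))
        assert feats.peaks["low_beta"] is None
        assert not feats.dual_peak_4_12

    def test_matches_bruteforce_scan(self):
        """Detected band maxima equal an exhaustive interior-point scan."""
        rng = np.random.default_rng(13)
        bands = {"theta": (4.0, 6.5), "theta_alpha": (4.0, 12.0),
                 "low_beta": (12.0, 20.0), "high_beta": (20.0, 35.0)}
        for _ in range(100):
            # smooth random curve: a few random Gaussians
            curve = np.zeros_like(self.GRID)
            for _ in range(rng.integers(1, 5)):
                curve += gaussian(self.GRID, rng.uniform(3, 45),
                                  rng.uniform(-0.5, 0.8), rng.uniform(0.5, 5))
            ps = self.smoothed_ps(curve)
            feats = detect_features(ps)
            y, f = ps.smoothed, ps.freqs
            for name, (lo, hi) in bands.items():
                best = None
                for i in range(1, len(f) - 1):
                    if lo < f[i] < hi and y[i] > y[i - 1] and y[i] > y[i + 1]:
                        if best is None or y[i] > y[best]:
                            best = i
                got = feats.peaks[name]
                if best is None:
                    assert got is None
                else:
                    assert got.frequency == pytest.approx(f[best])
                    assert got.amplitude == pytest.approx(y[best])
            # trough oracle
            tm = (f >= 10) & (f <= 20)
            ti = np.flatnonzero(tm)[np.argmin(y[tm])]
            assert feats.low_beta_trough.frequency == pytest.approx(f[ti])

    def test_trough_no_higher_than_flanking_peaks(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            curve = (gaussian(self.GRID, rng.uniform(5, 10), rng.uniform(0.2, 0.6), 1.0)
                     + gaussian(self.GRID, rng.uniform(13, 19), rng.uniform(0.1, 0.4), 1.0))
            feats = detect_features(self.smoothed_ps(curve))
            tr = feats.low_beta_trough
            for band in ("theta_alpha", "low_beta"):
                pk = feats.peaks[band]
                if pk is not None and tr is not None:
                    assert tr.amplitude <= pk.amplitude + 1e-12

    def test_deterministic_under_reordering(self):
        curve = gaussian(self.GRID, 8.0, 0.5, 1.0)
        f1 = detect_features(self.smoothed_ps(curve))
        f2 = detect_features(self.smoothed_ps(curve.copy()))
        assert f1.peaks["theta_alpha"] == f2.peaks["theta_alpha"]
        assert f1.band_powers_periodic == f2.band_powers_periodic


class TestBandPower:
    GRID = np.arange(2.5, 50.001, 0.1)

    def test_zero_periodic_zero_integrals(self):
        bp, _ = band_power(make_periodic(self.GRID, np.zeros_like(self.GRID)))
        assert all(v == 0.0 for v in bp.values())

    def test_gaussian_closed_form(self):
        """A Gaussian fully inside 6-9 Hz integrates to ~h*w*sqrt(2*pi)."""
        h, w = 0.4, 0.3
        curve = gaussian(self.GRID, 7.5, h, w)
        bp, _ = band_power(make_periodic(self.GRID, curve))
        assert bp["low_alpha"] == pytest.approx(h * w * np.sqrt(2 * np.pi), rel=0.01)

    def test_band_additivity(self):
        rng = np.random.default_rng(17)
        curve = rng.normal(0, 0.2, len(self.GRID))
        ps = make_periodic(self.GRID, curve)
        from scipy.integrate import trapezoid

        eps = 1e-9  # band-edge tolerance, as used by band_power
        m_theta = (ps.freqs >= 4 - eps) & (ps.freqs <= 6 + eps)
        m_la = (ps.freqs >= 6 - eps) & (ps.freqs <= 9 + eps)
        m_all = (ps.freqs >= 4 - eps) & (ps.freqs <= 9 + eps)
        lhs = trapezoid(curve[m_theta], ps.freqs[m_theta]) + trapezoid(curve[m_la], ps.freqs[m_la])
        rhs = trapezoid(curve[m_all], ps.freqs[m_all])
        assert lhs == pytest.approx(rhs, abs=1e-9)
        bp, _ = band_power(ps)
        assert bp["theta"] == pytest.approx(trapezoid(curve[m_theta], ps.freqs[m_theta]), abs=1e-12)

    def test_band_outside_grid_rejected(self):
        short = np.arange(2.5, 20.0, 0.1)
        with pytest.raises(ValueError, match="outside"):
            band_power(make_periodic(short, np.zeros_like(short)))


def test_end_to_end_feature_extraction():
    """Generated dual peaks propagate through fit + features."""
    spec, _ = gen_spectrum(SpectrumGenSpec(
        b=1.5, chi=1.0, peaks=[(5.5, 0.4, 1.0), (9.5, 0.35, 1.2)],
        noise_sd=0.01, seed=3))
    model = fit_spectrum(spec)
    feats = extract_features(spec, model)
    assert feats.dual_peak_4_12
    assert feats.peaks["theta"] is not None
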
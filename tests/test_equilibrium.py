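"""Spectral integration, temperature series, melt fits and relative activity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from trelax import (
    SpectrumRecord,
    fit_melt,
    generate_activity_trace,
    generate_melt_curve,
    integrate_band,
    integrate_full_peak,
    normalize_spectrum_max,
    percent_of_apo,
    relative_activity,
    sum_spectra,
    temperature_series,
)


def gaussian_spectrum(center=340.0, sigma=6.0, amp=50.0, lo=300.0, hi=420.0,
                      step=1.0, label=""):
    wl = np.arange(lo, hi + step / 2, step)
    return SpectrumRecord(wavelength=wl,
                          intensity=amp * np.exp(-0.5 * ((wl - center) / sigma) ** 2),
                          complex_label=label)


class TestIntegration:
    def test_constant_band_is_rectangle_area(self):
        s = SpectrumRecord(wavelength=np.arange(300.0, 401.0),
                           intensity=np.ones(101))
        assert integrate_band(s, 327.0, 353.0) == pytest.approx(26.0, rel=1e-12)

    def test_linearity_in_intensity(self):
        s = gaussian_spectrum()
        half = SpectrumRecord(wavelength=s.wavelength, intensity=0.5 * s.intensity)
        assert integrate_band(half, 320, 360) == pytest.approx(
            0.5 * integrate_band(s, 320, 360), rel=1e-12)

    def test_gaussian_band_matches_dense_quadrature(self):
        amp, sigma = 50.0, 3.0
        s = gaussian_spectrum(sigma=sigma, amp=amp)
        exact, _ = quad(lambda w: amp * np.exp(-0.5 * ((w - 340) / sigma) ** 2),
                        300, 420)
        assert integrate_band(s, 320, 360) == pytest.approx(exact, rel=5e-3)
        assert exact == pytest.approx(amp * sigma * np.sqrt(2 * np.pi), rel=1e-9)

    def test_band_edges_interpolated(self):
        s = SpectrumRecord(wavelength=np.arange(300.0, 401.0, 2.0),
                           intensity=np.ones(51))
        assert integrate_band(s, 327.0, 353.0) == pytest.approx(26.0, rel=1e-12)

    def test_band_outside_range_raises(self):
        s = gaussian_spectrum()
        with pytest.raises(ValueError):
            integrate_band(s, 500.0, 600.0)
        with pytest.raises(ValueError):
            integrate_band(s, 360.0, 320.0)

    @given(split=st.floats(310.0, 410.0))
    @settings(max_examples=50, deadline=None)
    def test_additivity_over_adjacent_bands(self, split):
        s = gaussian_spectrum()
        total = integrate_band(s, 305.0, 415.0)
        assert (integrate_band(s, 305.0, split) + integrate_band(s, split, 415.0)
                == pytest.approx(total, rel=1e-9))

    def test_full_peak_equals_full_range_band(self):
        s = gaussian_spectrum()
        assert integrate_full_peak(s) == pytest.approx(
            integrate_band(s, s.wavelength[0], s.wavelength[-1]), rel=1e-12)


class TestPercentOfApo:
    def test_self_is_100(self):
        assert percent_of_apo(12.3, 12.3) == pytest.approx(100.0)

    def test_example_71_percent(self):
        assert percent_of_apo(71.0, 100.0) == pytest.approx(71.0)

    def test_scale_invariance(self):
        assert percent_of_apo(3.0 * 71.0, 3.0 * 100.0) == pytest.approx(71.0)

    def test_nonpositive_apo_raises(self):
        with pytest.raises(ValueError):
            percent_of_apo(1.0, 0.0)


class TestNormalizeAndSum:
    def test_normalized_max_is_one(self):
        s = normalize_spectrum_max(gaussian_spectrum(amp=37.0))
        assert np.max(s.intensity) == pytest.approx(1.0)

    def test_sum_of_identical_spectra_keeps_shape(self):
        s = gaussian_spectrum()
        total = sum_spectra([s, s])
        a = normalize_spectrum_max(total)
        b = normalize_spectrum_max(s)
        np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-12)

    def test_sum_of_blue_shifted_bands_peaks_blue_of_red_reference(self):
        # five bands at/below 341 nm: their sum peaks blue of a 350 nm band
        parts = [gaussian_spectrum(center=c) for c in (332, 334, 340, 340, 341)]
        total = sum_spectra(parts)
        ref = gaussian_spectrum(center=350.0)
        peak_sum = total.wavelength[np.argmax(total.intensity)]
        peak_ref = ref.wavelength[np.argmax(ref.intensity)]
        assert peak_sum <= peak_ref

    def test_all_zero_spectrum_rejected(self):
        z = SpectrumRecord(wavelength=np.arange(300.0, 320.0),
                           intensity=np.zeros(20))
        with pytest.raises(ValueError):
            normalize_spectrum_max(z)


class TestTemperatureSeries:
    def setup_method(self):
        self.T = np.arange(12.0, 45.1, 3.0)

    def test_sample_equal_reference_is_flat_zero(self):
        s = 100.0 - 0.5 * self.T
        out = temperature_series(self.T, s, s)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_flat_reference_gives_normalized_minus_one(self):
        s = 50.0 + self.T
        out = temperature_series(self.T, s, np.full_like(self.T, 7.0))
        np.testing.assert_allclose(out, s / s[0] - 1.0, rtol=1e-12)

    def test_rising_sample_falling_reference_is_monotone_increasing(self):
        s = 100.0 * (1 + 0.01 * (self.T - 12.0))   # complex brightens
        r = 100.0 * (1 - 0.008 * (self.T - 12.0))  # free Trp dims
        out = temperature_series(self.T, s, r)
        assert out[0] == 0.0
        assert np.all(np.diff(out) > 0)

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError):
            temperature_series(self.T, np.ones_like(self.T), np.ones(3))

    def test_alternative_order_also_zero_at_lowest(self):
        s = 100.0 + self.T
        r = 80.0 - self.T
        out = temperature_series(self.T, s, r, order="subtract_then_normalize")
        assert out[0] == pytest.approx(0.0, abs=1e-12)


class TestFitMelt:
    @pytest.mark.parametrize("tm", [48.0, 42.0])
    def test_noiseless_tm_recovered_to_0p1_deg(self, tm):
        df = generate_melt_curve(Tm=tm, width=2.5)
        res = fit_melt(df.temperature_C, df.ellipticity)
        assert res.converged
        assert res.Tm == pytest.approx(tm, abs=0.1)

    def test_flat_input_flagged(self):
        T = np.arange(10.0, 91.0, 5.0)
        res = fit_melt(T, np.full_like(T, -10.0))
        assert not res.converged

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            fit_melt([10, 20, 30, 40, 50], [1, 1, 0, 0, 0])

    def test_noisy_recovery_within_one_degree(self):
        """2% noise, 5 degC steps: Tm within +-1 degC in >= 95% of 100 runs."""
        hits = 0
        for seed in range(100):
            df = generate_melt_curve(Tm=48.0, width=2.5, noise_sd=0.02, seed=seed)
            res = fit_melt(df.temperature_C, df.ellipticity)
            if res.converged and abs(res.Tm - 48.0) <= 1.0:
                hits += 1
        assert hits >= 95


class TestRelativeActivity:
    def test_identical_traces_100_percent(self):
        df = generate_activity_trace(2e-3)
        assert relative_activity(df.time_s, df.A340, df.time_s, df.A340) \
            == pytest.approx(100.0)

    def test_zero_slope_sample_is_zero_percent(self):
        wt = generate_activity_trace(2e-3)
        flat = generate_activity_trace(0.0)
        assert relative_activity(flat.time_s, flat.A340, wt.time_s, wt.A340,
                                 window=5) == pytest.approx(0.0, abs=1e-9)

    def test_zero_wildtype_rate_raises(self):
        flat = generate_activity_trace(0.0)
        with pytest.raises(ValueError):
            relative_activity(flat.time_s, flat.A340, flat.time_s, flat.A340)
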
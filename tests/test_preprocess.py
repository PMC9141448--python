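"""Scatter fitting, bound-dye extraction and inner-filter correction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thtbind.preprocess import (
    NO_SCATTER, ChamberPairError, ScatterFit, bound_dye_spectrum,
    estimate_noise_sigma, fit_scatter, inner_filter_correct, subtract_scatter,
)
from thtbind.simulate import lognormal_band
from thtbind.spectra import Spectrum

WL = np.arange(300.0, 701.0)


def scatter_spectrum(a, m, noise=0.0, rng=None):
    vals = a * WL ** (-float(m))
    if noise and rng is not None:
        vals = vals + rng.normal(0, noise, WL.size)
    return Spectrum(WL, vals, "absorption")


class TestFitScatter:
    def test_exact_recovery_on_power_law(self):
        fit = fit_scatter(scatter_spectrum(1.25e9, 4.0), (500, 600))
        assert fit.exponent == pytest.approx(4.0, abs=1e-10)
        assert fit.amplitude == pytest.approx(1.25e9, rel=1e-10)

    def test_flat_spectrum_gives_zero_exponent(self, flat_spectrum):
        fit = fit_scatter(flat_spectrum, (550, 650))
        assert fit.exponent == pytest.approx(0.0, abs=1e-9)
        assert fit.amplitude == pytest.approx(0.05, rel=1e-9)

    def test_noisy_recovery_within_tolerance(self):
        # m recovered within 0.1 of truth across 100 noise realizations
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            s = scatter_spectrum(2.0e8, 3.5, noise=1e-4, rng=rng)
            errs.append(abs(fit_scatter(s, (550, 650)).exponent - 3.5))
        assert max(errs) < 0.1

    def test_too_few_points_raises(self):
        s = Spectrum([540, 560, 580, 600], [0.1] * 4, "absorption")
        with pytest.raises(ValueError, match="at least 5"):
            fit_scatter(s, (550, 650))

    def test_non_positive_values_raise(self):
        s = Spectrum(WL, np.zeros(WL.size), "absorption")
        with pytest.raises(ValueError, match="non-positive"):
            fit_scatter(s, (550, 650))


class TestSubtractScatter:
    def test_zero_amplitude_is_identity(self, flat_spectrum):
        out = subtract_scatter(flat_spectrum, NO_SCATTER)
        np.testing.assert_array_equal(out.values, flat_spectrum.values)

    def test_own_fit_leaves_residuals_below_3rms(self):
        rng = np.random.default_rng(1)
        s = scatter_spectrum(2.0e8, 3.5, noise=5e-5, rng=rng)
        fit = fit_scatter(s, (550, 650))
        resid = subtract_scatter(s, fit).values
        window = (WL >= 550) & (WL <= 650)
        # residuals in the fit window are pure noise: the bulk sits within
        # 3 RMS (the extreme of ~100 Gaussian draws can graze past it)
        assert np.percentile(np.abs(resid[window]), 95) \
            < 3 * max(fit.residual_rms, 5e-5)

    def test_recovers_injected_band_under_scatter(self):
        rng = np.random.default_rng(2)
        sigma = 5e-5
        band = 0.3 * lognormal_band(WL, 412.0, 0.045)
        vals = band + 2.0e8 * WL ** (-3.5) + rng.normal(0, sigma, WL.size)
        s = Spectrum(WL, vals, "absorption")
        fit = fit_scatter(s, (550, 650))
        recovered = subtract_scatter(s, fit).values
        dye = (WL > 380) & (WL < 450)
        # recovery error: photometric noise plus the systematic uncertainty
        # of extrapolating the baseline from the 550-650 nm window
        allowance = 2 * sigma + 3 * np.max(fit.prediction_sigma(WL[dye]))
        assert np.max(np.abs(recovered - band)[dye]) < allowance


class TestBoundDyeSpectrum:
    def test_identity_pair_gives_zero(self, flat_spectrum):
        d = bound_dye_spectrum(flat_spectrum, flat_spectrum, NO_SCATTER,
                               noise_sigma=0.0)
        np.testing.assert_array_equal(d.values, 0.0)

    def test_injected_band_recovered(self):
        rng = np.random.default_rng(3)
        sigma = 1e-4
        band = 0.2 * lognormal_band(WL, 450.0, 0.05)
        ref = Spectrum(WL, 0.1 * lognormal_band(WL, 412.0, 0.045)
                       + rng.normal(0, sigma, WL.size), "absorption")
        sample = ref.with_values(ref.values + band
                                 + rng.normal(0, sigma, WL.size))
        d = bound_dye_spectrum(sample, ref, NO_SCATTER, noise_sigma=sigma)
        assert np.max(np.abs(d.values - band)) < 5 * sigma

    def test_mispaired_chambers_detected(self, flat_spectrum):
        sigma = 1e-4
        dip = np.where((WL >= 420) & (WL <= 470), 10 * sigma, 0.0)
        sample = flat_spectrum.with_values(flat_spectrum.values - dip)
        with pytest.raises(ChamberPairError, match="mispaired"):
            bound_dye_spectrum(sample, flat_spectrum, NO_SCATTER,
                               noise_sigma=sigma)

    def test_different_grids_rejected(self, flat_spectrum):
        other = Spectrum(WL[:-1], flat_spectrum.values[:-1], "absorption")
        with pytest.raises(ValueError, match="grid"):
            bound_dye_spectrum(flat_spectrum, other, NO_SCATTER)

    def test_linearity_in_sample(self):
        # D(s1 + delta) - D(s1) equals delta where no clipping occurs
        base = 0.3 * lognormal_band(WL, 450.0, 0.05) + 0.2
        delta = 0.1 * lognormal_band(WL, 460.0, 0.06)
        ref = Spectrum(WL, np.full(WL.size, 0.1), "absorption")
        s1 = Spectrum(WL, base, "absorption")
        s2 = Spectrum(WL, base + delta, "absorption")
        d1 = bound_dye_spectrum(s1, ref, NO_SCATTER, noise_sigma=0.0)
        d2 = bound_dye_spectrum(s2, ref, NO_SCATTER, noise_sigma=0.0)
        np.testing.assert_allclose(d2.values - d1.values, delta, atol=1e-12)


class TestInnerFilter:
    def test_zero_absorbance_returns_input(self):
        assert inner_filter_correct(1.7, 0.0) == pytest.approx(1.7)

    def test_closed_form_at_unit_absorbance(self):
        # A ln10 / (1 - 10^-A) at A=1 -> 2.302585/0.9 = 2.5584
        assert inner_filter_correct(1.0, 1.0) == pytest.approx(2.5584, abs=2e-4)

    def test_negative_absorbance_rejected(self):
        with pytest.raises(ValueError):
            inner_filter_correct(1.0, -0.1)

    @settings(max_examples=50, derandomize=True)
    @given(a=st.floats(1e-6, 4.0), b=st.floats(1e-6, 4.0))
    def test_factor_monotone_and_at_least_one(self, a, b):
        fa = inner_filter_correct(1.0, a)
        fb = inner_filter_correct(1.0, b)
        assert fa >= 1.0
        if a < b:
            assert fa < fb

    def test_large_absorbance_limit(self):
        # F_corr/F -> A ln10 as A -> infinity
        a = 8.0
        assert inner_filter_correct(1.0, a) == pytest.approx(a * np.log(10),
                                                             rel=1e-7)


def test_noise_sigma_estimates_mad_scale():
    rng = np.random.default_rng(4)
    sigma = 3e-4
    s = Spectrum(WL, rng.normal(0, sigma, WL.size), "absorption")
    est = estimate_noise_sigma(s)
    assert est == pytest.approx(sigma, rel=0.4)
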
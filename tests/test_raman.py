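import numpy as np
import pytest

from lignoquant.io_core import Spectrum, ValidationError
from lignoquant.raman import (
    BandDefinition,
    BaselineParams,
    align_to_reference,
    als_baseline,
    band_intensity,
    compute_ratios,
    default_band_config,
    scale_to_band,
)
from lignoquant.synthetic import gen_raman_spectrum

from oracles import asls_dense


def _spec(y, wn0=100.0, spacing=2.0):
    y = np.asarray(y, dtype=float)
    return Spectrum(wn0 + spacing * np.arange(len(y)), y)


class TestAlsBaseline:
    def test_zero_signal(self):
        b, c = als_baseline(_spec(np.zeros(32)))
        np.testing.assert_allclose(b.intensities, 0.0, atol=1e-12)
        np.testing.assert_allclose(c.intensities, 0.0, atol=1e-12)

    def test_constant_is_fixed_point(self):
        b, c = als_baseline(_spec(np.full(64, 7.5)))
        np.testing.assert_allclose(b.intensities, 7.5, atol=1e-6)
        np.testing.assert_allclose(c.intensities, 0.0, atol=1e-6)

    @pytest.mark.parametrize("n", [16, 32, 64])
    def test_sparse_matches_dense_oracle(self, rng, n):
        """Small-instance equivalence with a brute-force dense solve."""
        y = 3 + 0.05 * np.arange(n) + rng.normal(0, 0.02, n)
        y[n // 2] += 2.0  # one peak
        y = np.maximum(y, 0)
        params = BaselineParams()
        b, _ = als_baseline(_spec(y), params)
        z = asls_dense(y, params.lambda_smooth, params.p_asym, params.max_iter, params.tol)
        np.testing.assert_allclose(b.intensities, z, atol=1e-8)

    def test_peak_heights_recovered_on_full_grid(self):
        """Quadratic baseline + Gaussian peaks on the 851-bin grid: corrected
        heights match the injected signal within 5%."""
        spec, truth = gen_raman_spectrum(11, baseline_coeffs=(20.0, -10.0, 30.0))
        _, corrected = als_baseline(spec)
        wn = spec.wavenumbers
        # oracle: dense evaluation of the generating Gaussians
        clean = np.zeros_like(wn)
        for _, row in truth.iterrows():
            clean += row.amplitude * np.exp(-0.5 * ((wn - row.center) / row.sigma) ** 2)
        for _, row in truth.iterrows():
            m = np.abs(wn - row.center) <= 4
            rec, ref = corrected.intensities[m].max(), clean[m].max()
            assert abs(rec - ref) / ref < 0.05

    def test_baseline_under_peaks(self):
        """At peak-free bins the corrected residual stays within 1% of the
        peak amplitude (asymmetry pins the baseline to the background)."""
        spec, truth = gen_raman_spectrum(5)
        _, corrected = als_baseline(spec)
        wn = spec.wavenumbers
        free = np.ones(len(wn), dtype=bool)
        for _, row in truth.iterrows():
            free &= np.abs(wn - row.center) > 5 * row.sigma
        amp = truth.amplitude.max()
        assert abs(corrected.intensities[free].mean()) < 0.01 * amp

    def test_nonuniform_axis_rejected(self):
        with pytest.raises(ValidationError):
            Spectrum(np.array([1.0, 2.0, 4.0, 8.0]), np.zeros(4))


class TestAlignment:
    def test_identity(self):
        spec, _ = gen_raman_spectrum(0)
        _, corrected = als_baseline(spec)
        aligned, shift = align_to_reference(corrected)
        assert abs(shift) < 0.5

    def test_integer_bin_displacement_exact(self):
        spec, _ = gen_raman_spectrum(0)
        _, corrected = als_baseline(spec)
        displaced = corrected.copy(wavenumbers=corrected.wavenumbers + 4.0)
        _, shift = align_to_reference(displaced)
        base_shift = align_to_reference(corrected)[1]
        np.testing.assert_allclose(shift - base_shift, -4.0, atol=1e-9)

    def test_calibration_drift_recovered(self):
        """Peaks displaced 2 bins against a fixed baseline: shift ~ -4 cm^-1
        and the apex lands at 378 +/- 0.5 after refinement."""
        spec, truth = gen_raman_spectrum(5, shift_bins=2)
        _, corrected = als_baseline(spec)
        aligned, shift = align_to_reference(corrected)
        assert abs(shift - (-4.0)) < 0.5
        m = np.abs(aligned.wavenumbers - 378) < 12
        apex = aligned.wavenumbers[m][np.argmax(aligned.intensities[m])]
        assert abs(apex - 378.0) <= 0.5

    def test_no_peak_errors(self):
        flat = _spec(np.linspace(5, 4, 851))
        with pytest.raises(ValidationError, match="local maximum"):
            align_to_reference(flat)


class TestBands:
    def test_single_gaussian_height(self):
        wn = np.arange(100.0, 1801.0, 2.0)
        y = 1.0 * np.exp(-0.5 * ((wn - 1600) / 8) ** 2)
        s = Spectrum(wn, y, baseline_corrected=True)
        bi = band_intensity(s, BandDefinition("lignin", 1600, 4))
        assert bi.value == pytest.approx(1.0, abs=1e-3)

    def test_flat_zero_flagged(self):
        s = _spec(np.zeros(851))
        bi = band_intensity(s, BandDefinition("b", 500, 4))
        assert bi.value == 0.0 and bi.zero_signal

    def test_negative_max_clamped(self):
        s = _spec(np.full(851, -0.5))
        bi = band_intensity(s, BandDefinition("b", 500, 4))
        assert bi.value == 0.0 and bi.clamped

    def test_window_outside_range(self):
        s = _spec(np.zeros(100))
        with pytest.raises(ValidationError):
            band_intensity(s, BandDefinition("b", 2000, 4))

    def test_overlapping_peaks_windowed_max(self):
        wn = np.arange(100.0, 1801.0, 2.0)
        f = lambda c, s_, a: a * np.exp(-0.5 * ((wn - c) / s_) ** 2)
        y = f(1600, 9, 1.0) + f(1612, 6, 0.8)
        s = Spectrum(wn, y, baseline_corrected=True)
        bi = band_intensity(s, BandDefinition("b", 1604, 6))
        m = np.abs(wn - 1604) <= 6
        assert bi.value == pytest.approx(y[m].max())


class TestRatios:
    def test_simple_ratio(self):
        wn = np.arange(100.0, 1801.0, 2.0)
        y = 2.0 * np.exp(-0.5 * ((wn - 378) / 6) ** 2) + 1.0 * np.exp(-0.5 * ((wn - 1600) / 8) ** 2)
        s = Spectrum(wn, y, baseline_corrected=True)
        rs = compute_ratios(s, default_band_config())
        assert rs.ratios["lignin_over_cellulose"] == pytest.approx(0.5, abs=0.01)

    def test_equal_bands_give_one(self):
        wn = np.arange(100.0, 1801.0, 2.0)
        y = np.exp(-0.5 * ((wn - 378) / 6) ** 2) + np.exp(-0.5 * ((wn - 1600) / 6) ** 2)
        rs = compute_ratios(Spectrum(wn, y), default_band_config())
        assert rs.ratios["lignin_over_cellulose"] == pytest.approx(1.0, abs=0.01)

    def test_zero_denominator_flagged_not_raised(self):
        wn = np.arange(100.0, 1801.0, 2.0)
        rs = compute_ratios(Spectrum(wn, np.zeros_like(wn)), default_band_config())
        assert "lignin_over_cellulose" in rs.undefined
        assert np.isnan(rs.ratios["lignin_over_cellulose"])

    def test_scale_invariance(self):
        spec, _ = gen_raman_spectrum(9)
        _, c1 = als_baseline(spec)
        scaled = spec.copy(intensities=spec.intensities * 7.3)
        _, c2 = als_baseline(scaled)
        r1 = compute_ratios(c1, default_band_config()).ratios
        r2 = compute_ratios(c2, default_band_config()).ratios
        for k in r1:
            np.testing.assert_allclose(r1[k], r2[k], rtol=1e-3)

    def test_end_to_end_sg_recovery(self):
        """Injected S/G-proxy amplitudes 0.3/0.6 on a curved baseline recover
        a ratio of 0.5 within 5% after baseline correction and alignment."""
        spec, _ = gen_raman_spectrum(21, shift_bins=1)
        _, corrected = als_baseline(spec)
        aligned, _ = align_to_reference(corrected)
        rs = compute_ratios(aligned, default_band_config())
        assert abs(rs.ratios["s_over_g"] - 0.5) / 0.5 < 0.05

    def test_display_scaling(self):
        spec, _ = gen_raman_spectrum(2)
        _, corrected = als_baseline(spec)
        scaled = scale_to_band(corrected, default_band_config())
        bi = band_intensity(scaled, BandDefinition("cellulose_378", 378, 4))
        assert bi.value == pytest.approx(1.0)
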
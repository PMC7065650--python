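"""Preprocessing chain: calibrations, spike repair, denoising, the four
background-correction methods, and the ordered full chain."""

import numpy as np
import pytest

from ramangrade import preprocess as pp
from ramangrade import synthetic_data as sd
from ramangrade.types import HyperspectralMap, Spectrum, WavenumberAxis


def gaussian_peaks(axis_values, centers, sigma=3.0):
    out = np.zeros_like(axis_values)
    for c in centers:
        out += np.exp(-0.5 * ((axis_values - c) / sigma) ** 2)
    return out


@pytest.fixture(scope="module")
def wide_axis():
    return WavenumberAxis(np.linspace(300.0, 3200.0, 1400))


class TestWavenumberCalibration:
    def test_identity_when_peaks_already_correct(self, wide_axis):
        refs = pp.ACETAMINOPHEN.reference_peak_positions
        spec = Spectrum(wide_axis, gaussian_peaks(wide_axis.values, refs))
        _, res = pp.calibrate_wavenumber(spec)
        corrected = res.apply(wide_axis)
        assert np.abs(corrected.values - wide_axis.values).max() < 1e-6

    def test_constant_shift_recovered(self, wide_axis):
        refs = pp.ACETAMINOPHEN.reference_peak_positions
        spec = Spectrum(wide_axis, gaussian_peaks(wide_axis.values, [r + 2.0 for r in refs]))
        _, res = pp.calibrate_wavenumber(spec)
        corrected = res.apply(wide_axis)
        assert np.abs((corrected.values - wide_axis.values) + 2.0).max() < 0.05

    def test_quadratic_distortion_five_peaks(self, wide_axis):
        refs = (651.6, 1168.5, 1648.4, 2931.1, 3064.6)
        standard = pp.CalibrationStandard(reference_peak_positions=refs)
        distorted = [r + 1.5 + 2e-7 * (r - 300) ** 2 for r in refs]
        spec = Spectrum(wide_axis, gaussian_peaks(wide_axis.values, distorted))
        _, res = pp.calibrate_wavenumber(spec, standard)
        assert res.matched_reference.size == 5
        assert np.abs(res.residuals).max() < 0.1

    def test_too_few_matches_reports_count(self, wide_axis):
        spec = Spectrum(wide_axis, gaussian_peaks(wide_axis.values, [1500.0]))
        with pytest.raises(ValueError, match="standard\\s+peaks matched|peaks matched"):
            pp.calibrate_wavenumber(spec)


class TestIntensityCalibrationAndDark:
    def test_equal_whites_leave_spectrum_unchanged(self, axis):
        y = Spectrum(axis, np.linspace(1, 2, len(axis)))
        white = Spectrum(axis, np.full(len(axis), 3.0))
        out = pp.calibrate_intensity(y, white, white)
        np.testing.assert_allclose(out.intensity, y.intensity)

    def test_half_white_doubles(self, axis):
        y = Spectrum(axis, np.ones(len(axis)))
        ref = Spectrum(axis, np.full(len(axis), 2.0))
        meas = Spectrum(axis, np.ones(len(axis)))
        out = pp.calibrate_intensity(y, meas, ref)
        np.testing.assert_allclose(out.intensity, 2.0)

    def test_known_response_inverted(self, axis):
        rng = np.random.default_rng(5)
        truth = np.abs(rng.normal(1, 0.2, len(axis))) + 0.5
        response = 0.5 + 0.4 * np.sin(axis.values / 400.0) ** 2
        ref = Spectrum(axis, np.ones(len(axis)))
        meas = Spectrum(axis, 1.0 / response)
        distorted = Spectrum(axis, truth / response)
        out = pp.calibrate_intensity(distorted, meas, ref)
        np.testing.assert_allclose(out.intensity, truth, rtol=1e-10)

    def test_nonpositive_white_rejected(self, axis):
        y = Spectrum(axis, np.ones(len(axis)))
        bad = np.ones(len(axis))
        bad[10] = 0.0
        with pytest.raises(ValueError, match="positive"):
            pp.calibrate_intensity(y, Spectrum(axis, bad), y)

    def test_dark_subtraction(self, axis):
        y = Spectrum(axis, np.full(len(axis), 5.0))
        dark = Spectrum(axis, np.full(len(axis), 0.2))
        np.testing.assert_allclose(pp.subtract_dark(y, dark).intensity, 4.8)
        np.testing.assert_allclose(pp.subtract_dark(y, y).intensity, 0.0)


class TestCosmicSpikes:
    @pytest.fixture()
    def clean_map(self):
        cfg = sd.TissuePhantomConfig(grid_shape=(6, 6), spike_rate=0.0)
        hsmap, _ = sd.generate_biopsy(cfg, "NT", rng_seed=13)
        return hsmap

    def test_clean_map_untouched(self, clean_map):
        out, log = pp.remove_cosmic_spikes(clean_map)
        assert log == []
        np.testing.assert_array_equal(out.intensities, clean_map.intensities)

    def test_injected_spike_flagged_and_repaired(self, clean_map):
        cfg = sd.TissuePhantomConfig(grid_shape=(6, 6), spike_rate=0.0)
        noise_sd = cfg.noise_shot_scale * np.sqrt(clean_map.intensities.max())
        spiked = clean_map.intensities.copy()
        px, ch = 14, 700
        spiked[px, ch] += 30.0 * noise_sd
        hsmap = clean_map.with_intensities(spiked)
        out, log = pp.remove_cosmic_spikes(hsmap)
        assert [(p, round(w)) for p, w, _ in log] == [
            (px, round(clean_map.axis.values[ch]))
        ]
        assert abs(out.intensities[px, ch] - clean_map.intensities[px, ch]) < 3 * noise_sd

    def test_adjacent_channel_spikes_both_flagged(self, clean_map):
        noise_sd = 0.03 * np.sqrt(clean_map.intensities.max())
        spiked = clean_map.intensities.copy()
        spiked[5, 300] += 40.0 * noise_sd
        spiked[5, 301] += 25.0 * noise_sd
        out, log = pp.remove_cosmic_spikes(clean_map.with_intensities(spiked))
        flagged = {(p, round(w)) for p, w, _ in log}
        ax = clean_map.axis.values
        assert (5, round(ax[300])) in flagged and (5, round(ax[301])) in flagged

    def test_single_pixel_map_rejected(self, axis):
        hsmap = HyperspectralMap(axis, np.ones((1, len(axis))), [[0, 0]])
        with pytest.raises(ValueError, match="2 pixels"):
            pp.remove_cosmic_spikes(hsmap)


class TestPcaDenoise:
    def test_full_rank_reconstruction_is_identity(self):
        rng = np.random.default_rng(0)
        D = rng.normal(size=(12, 30))
        out = pp.pca_denoise(D, 12)
        np.testing.assert_allclose(out, D, atol=1e-8)

    def test_rank3_matrix_exact_at_three_components(self):
        rng = np.random.default_rng(1)
        D = rng.normal(size=(20, 3)) @ rng.normal(size=(3, 40))
        out = pp.pca_denoise(D, 3)
        np.testing.assert_allclose(out, D, atol=1e-8)

    def test_denoising_reduces_error_vs_clean_truth(self):
        rng = np.random.default_rng(2)
        clean = rng.normal(size=(30, 3)) @ rng.normal(size=(3, 50))
        noisy = clean + rng.normal(0, 0.3, clean.shape)
        out = pp.pca_denoise(noisy, 3)
        assert np.mean((out - clean) ** 2) < np.mean((noisy - clean) ** 2)

    def test_rank_bound_enforced(self):
        with pytest.raises(ValueError, match="rank"):
            pp.pca_denoise(np.ones((4, 10)), 5)


class TestSavitzkyGolay:
    def test_cubic_polynomial_reproduced(self, axis):
        v = axis.values / 1000.0
        y = Spectrum(axis, 1.0 + v - 0.5 * v**2 + 0.1 * v**3)
        out = pp.savitzky_golay(y, 11, 3)
        np.testing.assert_allclose(out.intensity[5:-5], y.intensity[5:-5], atol=1e-10)

    def test_constant_preserved(self, axis):
        y = Spectrum(axis, np.full(len(axis), 4.2))
        np.testing.assert_allclose(pp.savitzky_golay(y, 11, 3).intensity, 4.2)

    def test_noise_reduced_on_sinusoid(self, axis):
        rng = np.random.default_rng(3)
        clean = np.sin(axis.values / 150.0)
        noisy = clean + rng.normal(0, 0.1, clean.size)
        out = pp.savitzky_golay(Spectrum(axis, noisy), 11, 3)
        assert np.sqrt(np.mean((out.intensity - clean) ** 2)) < np.sqrt(
            np.mean((noisy - clean) ** 2)
        )

    @pytest.mark.parametrize("window,order", [(10, 3), (5, 5), (5, 7)])
    def test_invalid_window_order(self, axis, window, order):
        with pytest.raises(ValueError):
            pp.savitzky_golay(Spectrum(axis, np.ones(len(axis))), window, order)


def emsc_normal_equations_oracle(basis, y):
    """Independent least-squares route: explicit normal equations on the
    same design, polynomial part converted to the power basis."""
    from numpy.polynomial import Legendre, Polynomial

    A = basis.design_matrix()
    x = np.linalg.solve(A.T @ A, A.T @ y)
    v = basis.reference.axis.values
    n_int = len(basis.interferents)
    poly = Legendre(x[1 + n_int :], domain=[v[0], v[-1]]).convert(kind=Polynomial).coef
    poly = np.pad(poly, (0, basis.poly_order + 1 - poly.size))
    return x[0], x[1 : 1 + n_int], poly


class TestEmsc:
    @pytest.fixture()
    def basis(self, axis, library):
        ref = Spectrum(axis, library.spectra[0] + 0.5)
        fiber = Spectrum(axis, sd.fiber_background_shape(axis))
        return pp.EMSCBasis(ref, [fiber], poly_order=5)

    def test_reference_input_maps_to_itself(self, basis):
        corrected, coef = pp.emsc_correct(basis.reference, basis)
        b_ref, b_int, b_poly = coef.single()
        assert abs(b_ref - 1.0) < 1e-10
        np.testing.assert_allclose(b_int, 0.0, atol=1e-10)
        np.testing.assert_allclose(b_poly, 0.0, atol=1e-10)
        np.testing.assert_allclose(corrected.intensity, basis.reference.intensity, atol=1e-10)

    def test_planted_composition_recovered(self, axis, basis):
        v = axis.values
        y = Spectrum(
            axis,
            1.0 * basis.reference.intensity
            + 0.7 * basis.interferents[0].intensity
            + 0.3
            + 0.002 * v,
        )
        corrected, coef = pp.emsc_correct(y, basis)
        b_ref, b_int, b_poly = coef.single()
        assert abs(b_ref - 1.0) < 1e-8
        np.testing.assert_allclose(b_int, [0.7], atol=1e-8)
        np.testing.assert_allclose(b_poly[:2], [0.3, 0.002], atol=1e-8)
        np.testing.assert_allclose(corrected.intensity, basis.reference.intensity, atol=1e-8)

    def test_scale_absorbed_by_reference_coefficient(self, basis):
        doubled = basis.reference.with_intensity(2.0 * basis.reference.intensity)
        corrected, coef = pp.emsc_correct(doubled, basis)
        assert abs(coef.single()[0] - 2.0) < 1e-10
        np.testing.assert_allclose(corrected.intensity, basis.reference.intensity, atol=1e-9)

    def test_matches_independent_normal_equations(self, axis, basis):
        rng = np.random.default_rng(7)
        L = basis.legendre_columns()
        for _ in range(10):
            b_ref = rng.uniform(0.5, 2.0)
            b_fib = rng.normal()
            leg = rng.normal(size=6) * 0.5
            y = b_ref * basis.reference.intensity + b_fib * basis.interferents[
                0
            ].intensity + L @ leg
            o_ref, o_int, o_poly = emsc_normal_equations_oracle(basis, y)
            corrected, coef = pp.emsc_correct(Spectrum(axis, y), basis)
            g_ref, g_int, g_poly = coef.single()
            assert abs(g_ref - o_ref) < 1e-8
            np.testing.assert_allclose(g_int, o_int, atol=1e-8)
            np.testing.assert_allclose(g_poly, o_poly, atol=1e-8)
            np.testing.assert_allclose(
                corrected.intensity, basis.reference.intensity, atol=1e-8
            )

    def test_degenerate_fit_rejected(self, axis, basis):
        flat = Spectrum(axis, 0.1 + 0.0 * axis.values)  # representable without reference
        with pytest.raises(ValueError, match="degenerate"):
            pp.emsc_correct(flat, basis)

    def test_rank_deficient_basis_rejected(self, axis, library):
        ref = Spectrum(axis, library.spectra[0] + 0.5)
        with pytest.raises(ValueError, match="rank"):
            pp.EMSCBasis(ref, [ref], poly_order=2)


BASELINE_METHODS = {
    "als": lambda s: pp.als_baseline(s),
    "lieber": lambda s: pp.lieber_polyfit(s),
    "snip": lambda s: pp.snip_baseline(s),
}


@pytest.mark.parametrize("method", sorted(BASELINE_METHODS))
class TestBaselineEstimators:
    def test_zero_spectrum_zero_baseline(self, axis, method):
        z = Spectrum(axis, np.zeros(len(axis)))
        baseline, _ = BASELINE_METHODS[method](z)
        np.testing.assert_allclose(baseline.intensity, 0.0, atol=1e-10)

    def test_pure_smooth_baseline_removed(self, axis, method):
        base = Spectrum(axis, 10.0 * sd.fluorescence_shape(axis))
        baseline, _ = BASELINE_METHODS[method](base)
        resid = base.intensity - baseline.intensity
        assert np.abs(resid).max() < 0.02 * base.intensity.max()

    def test_band_area_preserved(self, axis, method):
        v = axis.values
        band = np.exp(-0.5 * ((v - 1440.0) / 6.0) ** 2)
        y = Spectrum(axis, 10.0 * sd.fluorescence_shape(axis) + band)
        baseline, _ = BASELINE_METHODS[method](y)
        corrected = y.intensity - baseline.intensity
        w = axis.window(1400.0, 1480.0)

        def net_area(sig):
            x, s = v[w], sig[w]
            lin = s[0] + (s[-1] - s[0]) * (x - x[0]) / (x[-1] - x[0])
            return np.trapezoid(s - lin, x)

        assert abs(net_area(corrected) / net_area(band) - 1.0) < 0.10


class TestCropAndNormalize:
    def test_crop_retains_closed_interval(self):
        ax = WavenumberAxis(np.linspace(400.0, 3200.0, 1500))
        y = Spectrum(ax, np.ones(1500))
        out = pp.crop(y)
        assert out.axis.values[0] >= 600.0 and out.axis.values[-1] <= 3100.0

    def test_crop_noop_when_within_range(self, axis):
        y = Spectrum(axis, np.ones(len(axis)))
        out = pp.crop(y)
        np.testing.assert_array_equal(out.axis.values, axis.values)

    def test_crop_empty_range_rejected(self, axis):
        with pytest.raises(ValueError):
            pp.crop(Spectrum(axis, np.ones(len(axis))), 2000.0, 1000.0)

    @pytest.mark.parametrize("kind", ["l2", "l1", "area", "max"])
    def test_unit_norm(self, axis, kind):
        y = Spectrum(axis, np.abs(np.sin(axis.values / 300.0)) + 0.1)
        out = pp.normalize_unity(y, kind)
        if kind == "l2":
            assert abs(np.linalg.norm(out.intensity) - 1.0) < 1e-12
        out2 = pp.normalize_unity(out, kind)
        np.testing.assert_allclose(out2.intensity, out.intensity, atol=1e-12)

    def test_scale_invariance(self, axis):
        y = Spectrum(axis, np.abs(np.cos(axis.values / 500.0)) + 0.2)
        a = pp.normalize_unity(y)
        b = pp.normalize_unity(y.with_intensity(7.0 * y.intensity))
        np.testing.assert_allclose(a.intensity, b.intensity, atol=1e-12)

    def test_zero_spectrum_rejected(self, axis):
        with pytest.raises(ValueError, match="zero"):
            pp.normalize_unity(Spectrum(axis, np.zeros(len(axis))))


class TestFullChain:
    def test_identity_chain_on_clean_phantom(self, clean_config, library):
        hsmap, truth = sd.generate_biopsy(clean_config, "NT", rng_seed=31)
        cfg = pp.PreprocessConfig(
            subtract_dark=False,
            remove_spikes=False,
            denoise=False,
            smooth=False,
            correct_background=False,
        )
        out, logs = pp.run_preprocessing([hsmap], cfg)
        pure = truth.concentrations @ library.spectra
        expected = pure / np.linalg.norm(pure, axis=1, keepdims=True)
        np.testing.assert_allclose(out[0].intensities, expected, atol=1e-12)

    def test_provenance_lists_steps_in_execution_order(self, small_cohort):
        cfg = pp.PreprocessConfig()
        _, logs = pp.run_preprocessing(
            small_cohort.maps[:1], cfg, dark=small_cohort.dark, fiber=small_cohort.fiber
        )
        steps = [entry["step"] for entry in logs[0]]
        assert steps == [
            "subtract_dark",
            "remove_cosmic_spikes",
            "pca_denoise",
            "savitzky_golay",
            "crop",
            "emsc_correct",
            "normalize_unity",
        ]

    def test_corrected_nt_exceeds_tumor_at_collagen_band(self, small_cohort):
        maps, _ = pp.run_preprocessing(
            small_cohort.maps, dark=small_cohort.dark, fiber=small_cohort.fiber
        )
        axis = maps[0].axis
        i = axis.index_of(1265.0)
        truths = small_cohort.truths
        nt_vals, tumor_vals = [], []
        for m in maps:
            mask = truths[m.biopsy_id].tumor_mask
            nt_vals.append(m.intensities[~mask, i])
            if mask.any():
                tumor_vals.append(m.intensities[mask, i])
        assert np.concatenate(nt_vals).mean() > np.concatenate(tumor_vals).mean()
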
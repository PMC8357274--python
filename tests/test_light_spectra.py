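"""Spectral smoothing, attenuation, pigment quantification and HSI mapping."""

import numpy as np
import pytest

from matprofiler import (
    BandDefinition,
    SpectralStack,
    attenuation_depth,
    attenuation_spectra,
    channel_profiles,
    generate_spectral_stack,
    hyperspectral_pigment_map,
    normalize_stack,
    pigment_abundance,
    smooth_spectrum,
)
from matprofiler.synthetic import MatScenario, PigmentBand

WL = np.arange(400.0, 801.0, 1.0)


def _exp_stack(k=0.5, depths=None, e0=None):
    depths = np.arange(0.0, 4.01, 0.4) if depths is None else depths
    e0 = 1.0 + 0.001 * (WL - 400.0) if e0 is None else e0
    irr = e0[:, None] * np.exp(-k * depths)[None, :]
    return SpectralStack(WL, depths, irr)


class TestSmoothing:
    def test_constant_spectrum_is_unchanged_exactly(self):
        out = smooth_spectrum(WL, np.full_like(WL, 3.7))
        np.testing.assert_array_equal(out, np.full_like(WL, 3.7))

    def test_linear_spectrum_preserved_to_machine_precision(self):
        y = 2.0 + 0.01 * WL
        np.testing.assert_allclose(smooth_spectrum(WL, y), y, rtol=1e-13)

    def test_noise_variance_is_contracted(self):
        rng = np.random.default_rng(1)
        smooth = np.exp(-((WL - 600) ** 2) / 5000.0)
        noisy = smooth + rng.normal(0, 0.05, WL.shape)
        out = smooth_spectrum(WL, noisy)
        assert np.var(out - smooth) < np.var(noisy - smooth)

    def test_window_wider_than_spectrum_is_rejected(self):
        with pytest.raises(ValueError, match="wider"):
            smooth_spectrum(WL[:5], np.ones(5), window_nm=100.0)


class TestNormalization:
    def test_reference_row_becomes_ones_and_idempotent(self):
        stack = _exp_stack()
        norm = normalize_stack(stack)
        np.testing.assert_array_equal(norm.irradiance[:, 0], np.ones(len(WL)))
        again = normalize_stack(norm)
        np.testing.assert_allclose(again.irradiance, norm.irradiance, rtol=1e-14)

    def test_normalized_stack_is_source_spectrum_independent(self):
        k = 0.7
        n1 = normalize_stack(_exp_stack(k=k))
        n2 = normalize_stack(_exp_stack(k=k, e0=5.0 + np.sin(WL / 40.0) ** 2))
        np.testing.assert_allclose(n1.irradiance, n2.irradiance, rtol=1e-12)
        np.testing.assert_allclose(
            n1.irradiance[0, :], np.exp(-k * n1.depth_mm), rtol=1e-12
        )


class TestAttenuation:
    def test_exponential_stack_gives_constant_k(self):
        att = attenuation_spectra(_exp_stack(k=0.8))
        np.testing.assert_allclose(att.attenuation, 0.8, rtol=1e-10)

    def test_gaussian_band_peaks_at_its_wavelength_and_depth(self):
        band = PigmentBand("chl", 674.0, 8.0, 0.6, 2.0, 0.5)
        sc = MatScenario(
            layer_boundaries_mm=[0.0, 4.0],
            true_rates={"O2": [0.0]},
            diffusivity={"O2": 1.5e-9},
            boundary_conditions={"O2": (0.2, 0.2)},
            matrix_attenuation_per_mm=[0.4],
            salt_thickness_mm=0.0,
            pigment_bands=(band,),
        )
        stack = generate_spectral_stack(sc, wavelengths_nm=WL, depth_step_mm=0.4)
        att = attenuation_spectra(stack)
        abundance = pigment_abundance(att, BandDefinition("chl", 674.0))
        peak_depth = abundance.depth_mm[int(np.argmax(abundance.value))]
        assert abs(peak_depth - 2.0) <= 0.4
        col = int(np.argmin(np.abs(att.depth_mm - 2.0)))
        assert abs(att.wavelength_nm[int(np.argmax(att.attenuation[:, col]))] - 674.0) <= 1.0

    def test_nonpositive_irradiance_is_rejected_before_log(self):
        with pytest.raises(ValueError, match="positive"):
            SpectralStack(WL, np.array([0.0, 0.4]), np.zeros((len(WL), 2)))


class TestPigmentAbundance:
    def _att_from(self, curve_fn):
        depths = np.array([0.0, 0.4])
        alpha = curve_fn(WL)[:, None]
        irr = np.exp(-alpha * depths[None, :])
        return attenuation_spectra(SpectralStack(WL, depths, irr))

    def test_flat_and_linear_attenuation_score_zero(self):
        band = BandDefinition("chl", 674.0)
        flat = self._att_from(lambda wl: np.full_like(wl, 0.3))
        assert np.all(pigment_abundance(flat, band).value == 0)
        sloped = self._att_from(lambda wl: 0.1 + 0.002 * wl)
        np.testing.assert_allclose(pigment_abundance(sloped, band).value, 0.0, atol=1e-12)

    def test_gaussian_amplitude_matches_numeric_oracle_and_is_linear(self):
        band = BandDefinition("chl", 674.0)
        sigma = 6.0

        def gauss(wl, amp):
            return 0.2 + amp * np.exp(-0.5 * ((wl - 674.0) / sigma) ** 2)

        # numeric oracle: chord-subtracted area over the window on a fine grid
        fine = np.linspace(669.0, 679.0, 2001)
        values = []
        for amp in (0.3, 0.6):
            curve = gauss(fine, amp)
            chord = np.linspace(curve[0], curve[-1], len(fine))
            oracle = np.trapezoid(curve - chord, fine)
            result = pigment_abundance(self._att_from(lambda wl: gauss(wl, amp)), band)
            assert result.value[0] == pytest.approx(oracle, rel=0.02)
            values.append(result.value[0])
        assert values[1] == pytest.approx(2 * values[0], rel=1e-6)

    def test_window_outside_grid_is_rejected(self):
        att = self._att_from(lambda wl: np.full_like(wl, 0.3))
        with pytest.raises(ValueError, match="outside"):
            pigment_abundance(att, BandDefinition("uv", 399.0))


class TestChannels:
    def test_flat_stack_gives_proportional_channels(self):
        wl = np.arange(200.0, 951.0, 1.0)
        depths = np.arange(0.0, 2.01, 0.4)
        irr = np.ones((len(wl), 1)) * np.exp(-0.9 * depths)[None, :]
        stack = SpectralStack(wl, depths, irr)
        ch = channel_profiles(stack, normalize=True)
        assert set(ch) == {"UV", "PAR", "NIR"}
        for prof in ch.values():
            np.testing.assert_allclose(prof.value, np.exp(-0.9 * depths), rtol=1e-12)

    def test_disjoint_support_omits_channels(self):
        wl = np.arange(500.0, 601.0, 1.0)
        stack = SpectralStack(wl, np.array([0.0, 0.4]), np.ones((len(wl), 2)))
        ch = channel_profiles(stack)
        assert "UV" not in ch and "NIR" not in ch and "PAR" in ch

    def test_no_overlap_at_all_is_an_error(self):
        wl = np.arange(500.0, 601.0, 1.0)
        stack = SpectralStack(wl, np.array([0.0, 0.4]), np.ones((len(wl), 2)))
        with pytest.raises(ValueError, match="overlaps"):
            channel_profiles(stack, channels={"X": (1000.0, 1100.0)})


class TestAttenuationDepth:
    def _exp_profile(self, k):
        from matprofiler import DepthProfile

        depth = np.arange(0.0, 6.01, 0.4)
        return DepthProfile(depth, np.exp(-k * depth), "PAR", unit="fraction")

    def test_full_fraction_is_surface(self):
        assert attenuation_depth(self._exp_profile(1.0), 1.0) == 0.0

    def test_one_percent_depth_of_matched_exponential(self):
        k = np.log(100.0) / 3.5
        assert attenuation_depth(self._exp_profile(k), 0.01) == pytest.approx(3.5, rel=1e-9)

    def test_monotone_in_fraction_and_sentinel_beyond_range(self):
        p = self._exp_profile(0.5)
        d10 = attenuation_depth(p, 0.10)
        d01 = attenuation_depth(p, 0.01)
        assert d01 >= d10
        assert attenuation_depth(self._exp_profile(0.01), 0.01) == float("inf")


class TestHyperspectralMap:
    def _cube(self, dips):
        """dips: list of (row, center_nm, strength). 8x4 pixel cube."""
        wl = np.arange(600.0, 801.0, 2.0)
        cube = np.ones((8, 4, len(wl)))
        for row, center, strength in dips:
            dip = strength * np.exp(-0.5 * ((wl - center) / 6.0) ** 2)
            cube[row, :, :] *= 1.0 - dip
        return cube, wl

    def test_flat_cube_maps_to_zero(self):
        cube, wl = self._cube([])
        band = BandDefinition("chl", 674.0)
        np.testing.assert_allclose(hyperspectral_pigment_map(cube, wl, band), 0.0, atol=1e-15)

    def test_dip_position_and_monotone_strength(self):
        band = BandDefinition("chl", 674.0)
        cube_w, wl = self._cube([(2, 674.0, 0.3)])
        weak = hyperspectral_pigment_map(cube_w, wl, band)
        assert np.unravel_index(np.argmax(weak), weak.shape)[0] == 2
        cube_s, _ = self._cube([(2, 674.0, 0.6)])
        strong = hyperspectral_pigment_map(cube_s, wl, band)
        assert strong[2].min() > weak[2].max()

    def test_two_bands_map_to_their_rows(self):
        cube, wl = self._cube([(1, 674.0, 0.4), (6, 745.0, 0.4)])
        chl = hyperspectral_pigment_map(cube, wl, BandDefinition("chl", 674.0))
        bchl = hyperspectral_pigment_map(cube, wl, BandDefinition("bchl_c", 745.0))
        assert np.unravel_index(np.argmax(chl), chl.shape)[0] == 1
        assert np.unravel_index(np.argmax(bchl), bchl.shape)[0] == 6


class TestForwardInverseInvariants:
    def test_matrix_attenuation_recovered_where_no_band_active(self, scenario):
        import dataclasses

        sc = dataclasses.replace(scenario, pigment_bands=())
        stack = generate_spectral_stack(sc)
        att = attenuation_spectra(stack)
        # inside the first mat layer (matrix attenuation 1.05 / mm)
        cols = (att.depth_mm > 0.1) & (att.depth_mm < 0.9)
        np.testing.assert_allclose(att.attenuation[:, cols], 1.05, rtol=0.01)

    def test_interface_channel_value_is_one_after_normalization(self, scenario):
        norm = normalize_stack(generate_spectral_stack(scenario))
        ch = channel_profiles(norm)
        for prof in ch.values():
            i0 = int(np.argmin(np.abs(prof.depth_mm)))
            assert prof.value[i0] == pytest.approx(1.0, rel=1e-12)
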
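"""Flux/rate inversion operations against hand-derived Fickian oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matprofiler import (
    DepthProfile,
    DiffusionSpec,
    areal_rate,
    avg_volumetric,
    diffusive_flux,
    fold_change,
    format_fold,
    interfacial_sulfide_flux,
    local_rates,
    pool,
    smooth_profile,
    solve_steady_state,
    stot_diffusivity,
    total_sulfide,
    true_rate_profile,
    turnover_days,
    turnover_time,
)
from matprofiler.synthetic import MatScenario

SPEC = DiffusionSpec("O2", 1.5e-9, porosity=0.3)


def _profile(depth, value, quantity="O2", **kw):
    return DepthProfile(np.asarray(depth, float), np.asarray(value, float), quantity, **kw)


class TestStotDiffusivity:
    def test_published_o2_value_rounds_to_1e9(self):
        d = stot_diffusivity(1.5e-9)
        assert d == pytest.approx(9.6e-10, rel=1e-12)
        # one significant figure
        assert float(f"{d:.0e}") == 1e-9

    def test_unit_input_and_homogeneity(self):
        assert stot_diffusivity(1.0) == 0.64
        assert stot_diffusivity(2 * 1.7e-9) == pytest.approx(2 * stot_diffusivity(1.7e-9))

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            stot_diffusivity(0.0)


class TestTotalSulfide:
    def test_acid_limit_approaches_h2s(self):
        depth = [0.0, 1.0, 2.0]
        h2s = _profile(depth, [0.1, 0.2, 0.3], "H2S")
        ph = _profile(depth, [3.0, 3.0, 3.0], "pH")
        stot = total_sulfide(h2s, ph, pk1=7.0)
        np.testing.assert_allclose(stot.value, h2s.value, rtol=1e-4)

    def test_at_pk_exactly_twice_h2s(self):
        depth = [0.0, 1.0]
        h2s = _profile(depth, [0.1, 0.25], "H2S")
        ph = _profile(depth, [7.0, 7.0], "pH")
        stot = total_sulfide(h2s, ph, pk1=7.0)
        np.testing.assert_allclose(stot.value, 2 * h2s.value, rtol=1e-14)

    def test_zero_h2s_gives_zero_stot(self):
        h2s = _profile([0, 1], [0.0, 0.0], "H2S")
        ph = _profile([0, 1], [8.0, 8.5], "pH")
        assert np.all(total_sulfide(h2s, ph).value == 0)

    def test_mismatched_grids_need_explicit_interpolation(self):
        h2s = _profile([0, 1], [0.1, 0.1], "H2S")
        ph = _profile([0, 0.5, 1], [7, 7, 7], "pH")
        with pytest.raises(ValueError, match="interpolate"):
            total_sulfide(h2s, ph)
        stot = total_sulfide(h2s, ph, interpolate=True)
        assert len(stot) == 3


class TestDiffusiveFlux:
    def test_uniform_profile_has_zero_flux(self):
        p = _profile([0, 1, 2, 3], [0.2] * 4)
        assert np.all(diffusive_flux(p, SPEC).flux == 0)

    def test_linear_profile_flux_by_ficks_law(self):
        # slope -1000 mol m^-3 per m over 2 mm; J = -phi*D0*s = 4.5e-7
        depth = np.linspace(0, 2, 21)
        p = _profile(depth, 2.5 - 1000.0 * depth / 1000.0)
        flux = diffusive_flux(p, SPEC)
        np.testing.assert_allclose(flux.flux, 4.5e-7, rtol=1e-12)

    def test_parabolic_profile_matches_analytic_derivative(self, single_layer_consumption):
        p = solve_steady_state(single_layer_consumption, "O2", grid_step_mm=0.05)
        flux = diffusive_flux(p, SPEC)
        d_eff, r, length = 0.3 * 1.5e-9, 1.0e-4, 2.0e-3
        z = flux.depth_mm * 1e-3
        exact = -d_eff * (-(r / d_eff) * (length - z))
        np.testing.assert_allclose(flux.flux, exact, rtol=1e-3)

    def test_fitted_slope_equals_finite_difference_on_linear_data(self):
        depth = np.linspace(0, 3, 16)
        p = _profile(depth, 0.5 - 0.1 * depth)
        fd = diffusive_flux(p, SPEC, mode="finite_difference")
        fit = diffusive_flux(p, SPEC, mode="fitted_slope", window=5)
        np.testing.assert_allclose(fit.flux, fd.flux[0], rtol=1e-9)

    def test_single_point_and_duplicate_depths_rejected(self):
        with pytest.raises(ValueError):
            diffusive_flux(_profile([1.0], [0.1]), SPEC)
        with pytest.raises(ValueError, match="strictly increasing"):
            _profile([0.0, 0.0, 1.0], [0.1, 0.1, 0.1])


class TestLocalRates:
    def test_constant_flux_means_no_conversion(self):
        p = _profile(np.linspace(0, 2, 11), 0.3 - 0.05 * np.linspace(0, 2, 11))
        r = local_rates(diffusive_flux(p, SPEC))
        np.testing.assert_allclose(r.rate, 0.0, atol=1e-18)

    def test_parabola_recovers_uniform_consumption(self):
        # C = a z^2 -> R = -2 a D_eff (consumption, negative)
        a = 1e4  # mol m^-3 per m^2
        depth = np.linspace(0, 2, 41)
        z = depth / 1000.0
        p = _profile(depth, 0.5 + a * z**2)
        r = local_rates(diffusive_flux(p, SPEC))
        np.testing.assert_allclose(r.rate, -2 * a * SPEC.d_eff, rtol=1e-9)

    def test_three_layer_sign_pattern_and_layer_means(self):
        sc = MatScenario(
            layer_boundaries_mm=[0.0, 1.0, 2.0, 3.0],
            true_rates={"O2": [-8e-5, 2e-4, -8e-5]},
            diffusivity={"O2": 1.5e-9},
            boundary_conditions={"O2": (0.3, "zero_flux")},
            porosity=0.3,
        )
        p = solve_steady_state(sc, "O2", grid_step_mm=0.05)
        r = local_rates(diffusive_flux(p, SPEC))
        truth = true_rate_profile(sc, "O2", 0.05)
        tv = np.interp(r.depth_mm, truth.depth_mm, truth.rate)
        away = np.all(
            np.abs(r.depth_mm[:, None] - sc.layer_boundaries_mm[None, :]) > 0.1, axis=1
        )
        for lo, hi, expected in [(0, 1, -8e-5), (1, 2, 2e-4), (2, 3, -8e-5)]:
            m = away & (r.depth_mm > lo) & (r.depth_mm < hi)
            mean = r.rate[m].mean()
            assert np.sign(mean) == np.sign(expected)
            assert abs(mean - expected) / abs(expected) < 0.05
        assert np.max(np.abs((r.rate - tv)[away])) < 5e-2 * np.max(np.abs(tv))


class TestArealAndAverageRates:
    def test_uniform_production_integrates_to_r_times_span(self):
        r = 2e-4
        depth = np.linspace(0, 2, 41)
        # C with curvature -r/D_eff everywhere -> uniform production r
        p = _profile(depth, 1.0 - r / (2 * SPEC.d_eff) * (depth / 1000.0) ** 2)
        rates = local_rates(diffusive_flux(p, SPEC))
        # rate cells tile [0.025, 1.975] mm (outermost flux midpoints)
        assert areal_rate(rates) == pytest.approx(r * 1.95e-3, rel=1e-9)
        assert areal_rate(rates, zone=(0.975, 1.025)) == pytest.approx(r * 0.05e-3, rel=1e-9)

    def test_net_equals_boundary_flux_difference(self, scenario):
        p = solve_steady_state(scenario, "O2_light", grid_step_mm=0.05)
        spec = DiffusionSpec("O2", 1.5e-9, porosity=scenario.porosity)
        flux = diffusive_flux(p, spec)
        rates = local_rates(flux)
        net = areal_rate(rates)
        assert net == pytest.approx(flux.flux[-1] - flux.flux[0], rel=1e-10)

    def test_zero_rates_integrate_to_zero(self):
        from matprofiler.profiles import RateDepthProfile

        rates = RateDepthProfile([0.5, 1.0, 1.5], [0.0, 0.0, 0.0], "O2")
        assert areal_rate(rates) == 0.0

    def test_empty_zone_is_rejected(self):
        from matprofiler.profiles import RateDepthProfile

        rates = RateDepthProfile([0.5, 1.0], [1e-5, 1e-5], "O2")
        with pytest.raises(ValueError):
            areal_rate(rates, zone=(5.0, 6.0))

    def test_avg_volumetric_masks_anoxic_depths(self):
        from matprofiler.profiles import RateDepthProfile

        depth = np.linspace(0.1, 3.9, 20)
        rate = np.where(depth < 2.0, 1e-4, -7e-4)
        rates = RateDepthProfile(depth, rate, "O2")
        o2 = _profile([0, 2, 2.01, 4], [0.3, 0.05, 0.0, 0.0])
        assert avg_volumetric(rates, o2) == pytest.approx(1e-4, rel=1e-9)

    def test_avg_volumetric_without_oxic_depths_errors(self):
        from matprofiler.profiles import RateDepthProfile

        rates = RateDepthProfile([0.5, 1.0], [1e-5, 1e-5], "O2")
        o2 = _profile([0, 2], [0.0, 0.0])
        with pytest.raises(ValueError, match="threshold"):
            avg_volumetric(rates, o2)


class TestSulfideBudget:
    def test_linear_gradient_interfacial_flux(self):
        g = 50.0  # mol m^-3 per mm -> 5e4 per m
        depth = np.linspace(2.0, 6.0, 41)
        stot = _profile(depth, g * (depth - 2.0), "Stot")
        spec = DiffusionSpec("Stot", stot_diffusivity(1.5e-9), porosity=0.3)
        flux = interfacial_sulfide_flux(stot, spec, oxic_lower_bound_mm=2.0)
        assert flux == pytest.approx(spec.d_eff * g * 1000.0, rel=1e-9)

    def test_flat_stot_has_no_flux(self):
        stot = _profile(np.linspace(2, 4, 11), np.full(11, 0.2), "Stot")
        spec = DiffusionSpec("Stot", 9.6e-10, porosity=0.3)
        assert interfacial_sulfide_flux(stot, spec, 2.0) == pytest.approx(0.0, abs=1e-18)

    def test_pool_of_uniform_and_linear_profiles(self):
        uniform = _profile([0, 1, 2], [0.2, 0.2, 0.2], "Stot")
        assert pool(uniform) == pytest.approx(0.2, rel=1e-12)
        linear = _profile([0, 4], [0.0, 0.4], "Stot")
        assert pool(linear) == pytest.approx(0.2, rel=1e-12)
        assert pool(linear, mode="depth_integrated") == pytest.approx(0.2 * 4e-3, rel=1e-12)
        zero = _profile([0, 1], [0.0, 0.0], "Stot")
        assert pool(zero) == 0.0

    def test_turnover_time_and_days(self):
        assert turnover_time(0.2, 2.4e-6) == pytest.approx(83333.33, rel=1e-4)
        assert turnover_days(0.0, 1e-6) == 0.0
        assert turnover_time(0.2, 2e-6) == pytest.approx(2 * turnover_time(0.2, 4e-6))
        with pytest.raises(ValueError):
            turnover_time(0.2, 0.0)

    def test_fold_change_and_formatter(self):
        assert fold_change(3.0, 3.0) == 1.0
        assert format_fold(fold_change(1.9e-7, 2.1e-8)) == "9-fold"
        assert format_fold(fold_change(1.1e-6, 6.2e-8)) == "18-fold"
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)


class TestConservationAndLinearity:
    def test_rate_integral_telescopes_over_subintervals(self, scenario):
        p = solve_steady_state(scenario, "O2_light", grid_step_mm=0.05)
        spec = DiffusionSpec("O2", 1.5e-9, porosity=scenario.porosity)
        flux = diffusive_flux(p, spec)
        rates = local_rates(flux)
        # any aligned subinterval: rate integral == flux difference across it
        for i, j in [(0, 10), (5, 40), (20, len(flux) - 1)]:
            zone = (flux.depth_mm[i], flux.depth_mm[j])
            integral = areal_rate(rates, zone=zone)
            assert integral == pytest.approx(flux.flux[j] - flux.flux[i], rel=1e-10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(min_value=0.1, max_value=50.0))
    def test_operations_are_linear_in_concentration(self, scale):
        depth = np.linspace(0, 3, 31)
        values = 0.3 * np.exp(-depth) + 0.01 * depth
        p1 = _profile(depth, values)
        p2 = _profile(depth, scale * values)
        f1, f2 = diffusive_flux(p1, SPEC), diffusive_flux(p2, SPEC)
        np.testing.assert_allclose(f2.flux, scale * f1.flux, rtol=1e-12)
        r1, r2 = local_rates(f1), local_rates(f2)
        np.testing.assert_allclose(r2.rate, scale * r1.rate, rtol=1e-12)
        assert areal_rate(r2) == pytest.approx(scale * areal_rate(r1), rel=1e-12)
        assert pool(p2) == pytest.approx(scale * pool(p1), rel=1e-12)

    def test_grid_refinement_changes_layer_means_below_one_percent(self, scenario):
        spec = DiffusionSpec("O2", 1.5e-9, porosity=scenario.porosity)
        means = {}
        for h in (0.05, 0.025):
            p = solve_steady_state(scenario, "O2_light", grid_step_mm=h)
            r = local_rates(diffusive_flux(p, spec))
            m = (r.depth_mm > 1.2) & (r.depth_mm < 1.8)  # inside the green layer
            means[h] = r.rate[m].mean()
        assert abs(means[0.025] - means[0.05]) / abs(means[0.05]) < 0.01


class TestSmoothing:
    def test_smoothing_preserves_linear_profiles(self):
        depth = np.linspace(0, 2, 21)
        p = _profile(depth, 0.4 - 0.1 * depth)
        np.testing.assert_allclose(smooth_profile(p, 5).value, p.value, rtol=1e-13)

    def test_smoothing_reduces_noise_variance(self):
        rng = np.random.default_rng(0)
        depth = np.linspace(0, 5, 101)
        noise = rng.normal(0, 0.01, size=101)
        p = _profile(depth, 0.3 + noise + 1, "other")
        smoothed = smooth_profile(p, 7)
        assert smoothed.value.var() < p.value.var()
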
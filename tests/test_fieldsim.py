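"""Microscale static-dephasing simulation: stacking, dipole field,
line shapes, soma masking and derived relaxivities."""

import numpy as np
import pytest

from swmrelax import (
    IronConcentrationMap,
    LarmorFieldMap,
    PhysicalConstants,
    dipole_field,
    fit_line_shape,
    frequency_histogram,
    micro_relaxivity,
    orientation_sweep,
    simulate_line_width,
    soma_iron_fraction,
    soma_mask,
    stack_sections,
)
from swmrelax.fieldsim import LineShape, dipole_kernel, masked_map

GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


def section(values, thickness=10.0, pixel=1.0):
    return IronConcentrationMap(values, (pixel, pixel), thickness)


class TestStackSections:
    def test_uniform_sections_give_uniform_volume(self):
        secs = [section(np.full((8, 8), 5.0))] * 3
        vol = stack_sections(secs, repeats=3)
        assert vol.values.ndim == 3
        assert np.all(vol.values == 5.0)

    def test_z_extent_is_repeats_times_total_thickness(self):
        secs = [section(np.ones((4, 4)), thickness=12.0)] * 3
        vol = stack_sections(secs, repeats=3)
        # 3 sections x 3 repeats x 12 um at 1 um spacing
        assert vol.values.shape[2] == 3 * 3 * 12
        assert vol.pixel_size == (1.0, 1.0, 1.0)

    def test_single_section_extrusion_preserves_values(self, rng):
        values = rng.uniform(0, 50, (6, 6))
        vol = stack_sections([section(values, thickness=5.0)], repeats=1)
        assert vol.values.shape == (6, 6, 5)
        for k in range(5):
            np.testing.assert_array_equal(vol.values[:, :, k], values)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            stack_sections([section(np.ones((4, 4))), section(np.ones((5, 4)))])


class TestDipoleField:
    def test_kernel_range_and_zero_frequency(self):
        D = dipole_kernel((16, 16, 16), (1.0, 1.0, 1.0), "z")
        assert D[0, 0, 0] == 0.0
        assert D.min() >= -2.0 / 3.0 - 1e-12
        assert D.max() <= 1.0 / 3.0 + 1e-12

    def test_uniform_map_gives_zero_field(self, constants):
        fm = dipole_field(np.full((8, 8, 8), 1e-7), (1, 1, 1), "z", constants)
        assert np.abs(fm.values).max() == 0.0

    def test_field_is_demeaned(self, rng, constants):
        chi = rng.uniform(0, 1e-7, (12, 12, 12))
        fm = dipole_field(chi, (1, 1, 1), "z", constants)
        assert abs(fm.values.mean()) < 1e-12 * np.abs(fm.values).max()

    def test_linearity_of_convolution(self, rng, constants):
        chi1 = rng.uniform(0, 1e-7, (10, 10, 10))
        chi2 = rng.uniform(0, 1e-7, (10, 10, 10))
        a, b = 2.0, -0.5
        combined = dipole_field(a * chi1 + b * chi2, (1, 1, 1), "z", constants)
        separate = (
            a * dipole_field(chi1, (1, 1, 1), "z", constants).values
            + b * dipole_field(chi2, (1, 1, 1), "z", constants).values
        )
        np.testing.assert_allclose(combined.values, separate, atol=1e-8)

    def test_point_source_matches_analytic_dipole_off_axis(self, constants):
        # median agreement of a single-voxel source with the analytic
        # point dipole away from the axis-aligned ringing of the
        # band-limited kernel
        n = 64
        chi0 = 1e-7
        chi = np.zeros((n, n, n))
        chi[n // 2, n // 2, n // 2] = chi0
        fm = dipole_field(chi, (1, 1, 1), "z", constants)
        ax = np.arange(n) - n // 2
        xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
        r = np.sqrt(xx**2 + yy**2 + zz**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            cosb = zz / r
            analytic = (
                constants.gamma * constants.B0 * chi0
                / (4 * np.pi * r**3) * (3 * cosb**2 - 1)
            )
        shell = (r >= 5) & (r <= 12) & (np.abs(3 * cosb**2 - 1) > 0.3)
        rel = np.abs(fm.values[shell] - analytic[shell]) / np.abs(analytic[shell])
        assert np.median(rel) < 0.02

    def test_nonunit_direction_normalized_with_warning(self, constants):
        chi = np.zeros((8, 8, 8))
        chi[4, 4, 4] = 1e-7
        with pytest.warns(UserWarning, match="normaliz"):
            fm = dipole_field(chi, (1, 1, 1), (0, 0, 2.0), constants)
        ref = dipole_field(chi, (1, 1, 1), "z", constants)
        np.testing.assert_allclose(fm.values, ref.values)


class TestLineShape:
    def test_histogram_normalization_and_symmetric_range(self, rng):
        fm = LarmorFieldMap(rng.normal(0, 3, 5000), np.array([0, 0, 1.0]))
        hist = frequency_histogram(fm, n_bins=101)
        assert np.trapezoid(hist.density, hist.bin_centers) == pytest.approx(1.0, abs=0.02)
        assert hist.bin_centers[0] == pytest.approx(-hist.bin_centers[-1])

    def test_constant_field_occupies_single_bin_and_zero_fwhm(self):
        fm = LarmorFieldMap(np.zeros(100), np.array([0, 0, 1.0]))
        hist = frequency_histogram(fm, n_bins=21)
        assert np.count_nonzero(hist.density) == 1
        fit = fit_line_shape(hist)
        assert fit.degenerate and fit.fwhm == 0.0

    def test_empty_mask_rejected(self):
        fm = LarmorFieldMap(np.zeros((4, 4)), np.array([0, 0, 1.0]))
        with pytest.raises(ValueError, match="mask"):
            frequency_histogram(fm, mask=np.zeros((4, 4), dtype=bool))

    def test_gaussian_samples_recover_configured_fwhm(self, rng):
        sigma = 3.397  # FWHM = 2.3548 sigma = 8.0 rad/s
        fm = LarmorFieldMap(rng.normal(0, sigma, 400_000), np.array([0, 0, 1.0]))
        fit = fit_line_shape(frequency_histogram(fm))
        assert fit.model == "gaussian"
        assert fit.fwhm == pytest.approx(GAUSS_FWHM * sigma, rel=0.03)

    def test_lorentzian_density_selected_and_width_recovered(self):
        x = np.linspace(-50, 50, 201)
        hwhm = 2.5
        density = (1 / (np.pi * hwhm)) / (1 + (x / hwhm) ** 2)
        fit = fit_line_shape(LineShape(x, density))
        assert fit.model == "lorentzian"
        assert fit.fwhm == pytest.approx(2 * hwhm, rel=1e-3)
        assert set(fit.candidates) == {"gaussian", "lorentzian"}


class TestSomaOperations:
    def test_threshold_selects_voxels_at_or_above(self):
        iron = IronConcentrationMap(np.array([[60.0, 80.0]]), (1, 1), 10.0)
        mask = soma_mask(iron, 70.0)
        np.testing.assert_array_equal(mask, [[False, True]])

    def test_zero_threshold_full_support(self):
        iron = IronConcentrationMap(np.array([[1.0, 2.0]]), (1, 1), 10.0)
        assert soma_mask(iron, 0.0).all()

    def test_fraction_uniform_half_and_full(self):
        iron = IronConcentrationMap(np.full((4, 4), 3.0), (1, 1), 10.0)
        half = np.zeros((4, 4), dtype=bool)
        half[:2] = True
        assert soma_iron_fraction(iron, half) == pytest.approx(0.5)
        assert soma_iron_fraction(iron, np.ones((4, 4), bool)) == pytest.approx(1.0)

    def test_generated_scene_fraction_matches_target(self, default_cellular_scene):
        iron, truth = default_cellular_scene
        frac = soma_iron_fraction(iron, truth["soma_mask"])
        assert frac == pytest.approx(0.12, abs=0.02)

    def test_zero_total_iron_rejected(self):
        iron = IronConcentrationMap(np.zeros((3, 3)), (1, 1), 10.0)
        with pytest.raises(ValueError, match="zero total"):
            soma_iron_fraction(iron, np.ones((3, 3), bool))


class TestMicroRelaxivity:
    def test_reported_linewidth_over_concentration(self):
        # 8 rad/s line width over 37 ug/g gives ~0.216 s^-1 per ug/g
        assert micro_relaxivity(8.0, 37.0) == pytest.approx(0.216, abs=0.001)

    def test_zero_linewidth_and_linearity(self):
        assert micro_relaxivity(0.0, 10.0) == 0.0
        assert micro_relaxivity(6.0, 10.0) == pytest.approx(
            3 * micro_relaxivity(2.0, 10.0)
        )

    def test_zero_concentration_rejected(self):
        with pytest.raises(ValueError):
            micro_relaxivity(8.0, 0.0)


class TestSimulationProperties:
    def test_fwhm_scales_linearly_with_iron(self, small_cellular_scene):
        iron, _ = small_cellular_scene
        base = simulate_line_width(iron).fwhm
        for k in (0.5, 2.0):
            scaled = simulate_line_width(iron.scaled(k)).fwhm
            assert scaled == pytest.approx(k * base, rel=0.01)

    def test_soma_restricted_linewidth_smaller(self, small_cellular_scene):
        iron, _ = small_cellular_scene
        full = simulate_line_width(iron).fwhm
        soma_only = masked_map(iron, soma_mask(iron, 70.0))
        assert simulate_line_width(soma_only).fwhm < full

    def test_orientation_sweep_deterministic(self, small_cellular_scene):
        iron, _ = small_cellular_scene
        sweep = orientation_sweep(iron, ["z", "z"])
        assert sweep["fwhm"][0] == sweep["fwhm"][1]

    def test_aligned_rods_more_orientation_dependent_than_isotropic(self, rng):
        from scipy.ndimage import gaussian_filter

        # isotropic 3D texture vs the same texture smeared along x (rods)
        noise = rng.standard_normal((48, 48, 48))
        iso_tex = gaussian_filter(noise, 2.0)
        rod_tex = gaussian_filter(noise, (8.0, 1.0, 1.0))
        maps = []
        for tex in (iso_tex, rod_tex):
            tex = tex - tex.min()
            tex *= 30.0 / tex.mean()
            maps.append(IronConcentrationMap(tex, (1.0, 1.0, 1.0)))
        iso = orientation_sweep(maps[0], ["x", "y", "z"])
        rods = orientation_sweep(maps[1], ["x", "y", "z"])
        assert iso["relative_spread"] < rods["relative_spread"]
        assert iso["relative_spread"] < 0.1
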
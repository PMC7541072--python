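"""Cortical profile extraction, band statistics and the linear contrast fit."""

import numpy as np
import pytest

from swmrelax import (
    BoundaryPolyline,
    band_average,
    extract_profiles,
    fit_linear_contrast_model,
    gen_ribbon_phantom,
    paired_map_difference,
)
from swmrelax.synthetic import RibbonPhantomConfig


def horizontal_boundary(row, n_cols, n_points=20):
    # ordered so that +90deg normals point toward increasing rows (WM)
    cols = np.linspace(n_cols - 3.0, 2.0, n_points)
    return BoundaryPolyline(np.column_stack([np.full_like(cols, row), cols]))


class TestBoundaryPolyline:
    def test_repeated_points_rejected(self):
        with pytest.raises(ValueError, match="repeated"):
            BoundaryPolyline(np.array([[0, 0], [0, 0], [1, 1]]))

    def test_arclength_resample_is_equidistant(self):
        poly = BoundaryPolyline(np.array([[0.0, 0.0], [0.0, 10.0], [0.0, 30.0]]))
        pts = poly.arclength_resample(7)
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        np.testing.assert_allclose(steps, steps[0])


class TestExtractProfiles:
    def test_linear_ramp_recovered_exactly_with_zero_se(self):
        grid = np.tile(np.arange(100.0)[:, None], (1, 60))  # varies along rows only
        boundary = horizontal_boundary(50, 60)
        prof = extract_profiles(grid, boundary, cortical_depth=30.0, n_samples=40)
        expected = 50.0 + prof.depth * 30.0
        np.testing.assert_allclose(prof.mean, expected, atol=1e-9)
        np.testing.assert_allclose(prof.se, 0.0, atol=1e-9)

    def test_default_sampling_counts(self):
        grid = np.ones((100, 60))
        prof = extract_profiles(grid, horizontal_boundary(50, 60), 20.0)
        assert prof.profiles.shape == (20, 40)

    def test_profiles_exiting_map_are_flagged_and_excluded(self):
        grid = np.ones((100, 60))
        # sloped boundary: anchors near row 90 exit the bottom edge,
        # anchors near row 50 stay inside
        rows = np.linspace(90.0, 50.0, 20)
        cols = np.linspace(57.0, 2.0, 20)
        boundary = BoundaryPolyline(np.column_stack([rows, cols]))
        prof = extract_profiles(grid, boundary, 30.0)
        assert prof.n_excluded == 20 - len(prof.profiles)
        assert 0 < prof.n_excluded < 20

    def test_rotation_equivariance(self, rng):
        # smooth map sampled across a rotated copy of map+boundary
        from scipy.ndimage import gaussian_filter, rotate

        base = gaussian_filter(rng.standard_normal((120, 120)), 8.0)
        boundary = horizontal_boundary(60, 120, n_points=10)
        prof = extract_profiles(base, boundary, 20.0, n_profiles=8)
        rotated = rotate(base, 90, reshape=False, order=3)
        # (row, col) -> (119 - col, row) under this proper rotation, so
        # tangents and normals transform consistently
        pts = boundary.points
        rot_pts = np.column_stack([119 - pts[:, 1], pts[:, 0]])
        prof_rot = extract_profiles(
            rotated, BoundaryPolyline(rot_pts), 20.0, n_profiles=8
        )
        np.testing.assert_allclose(prof.mean, prof_rot.mean, atol=0.02)


class TestBandAverage:
    def test_constant_map_band_mean(self):
        grid = np.full((100, 60), 7.0)
        prof = extract_profiles(grid, horizontal_boundary(50, 60), 20.0)
        mean, sd = band_average(prof, "swm")
        assert mean == pytest.approx(7.0)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_piecewise_bands_recovered_exactly(self):
        phantom = gen_ribbon_phantom(RibbonPhantomConfig(noise_sd=0.0))
        prof = extract_profiles(
            phantom["iron"], phantom["boundary"], phantom["cortical_depth"]
        )
        expected = phantom["truth"]["iron_bands"]
        for band in ("cortex-upper", "cortex-middle", "swm", "dwm"):
            mean, sd = band_average(prof, band)
            assert mean == pytest.approx(expected[band], abs=1e-9)
            assert sd == pytest.approx(0.0, abs=1e-9)

    def test_unknown_and_empty_bands_rejected(self):
        grid = np.ones((100, 60))
        prof = extract_profiles(grid, horizontal_boundary(50, 60), 20.0)
        with pytest.raises(ValueError, match="unknown band"):
            band_average(prof, "layer-IV")
        with pytest.raises(ValueError, match="no sampled depths"):
            band_average(prof, (5.0, 6.0))


class TestPairedDifference:
    def test_identical_maps_give_zero(self):
        grid = np.random.default_rng(0).uniform(10, 20, (100, 60))
        boundary = horizontal_boundary(50, 60)
        result = paired_map_difference(grid, grid, boundary, 20.0)
        assert np.all(result["difference_map"] == 0)
        assert result["bands"]["swm"]["difference"] == pytest.approx(0.0)

    def test_constant_offset_recovered_in_swm_band(self):
        rng = np.random.default_rng(1)
        before = rng.uniform(20, 40, (100, 60))
        after = before - 12.0
        result = paired_map_difference(
            before, after, horizontal_boundary(50, 60), 20.0
        )
        assert result["bands"]["swm"]["difference"] == pytest.approx(12.0)
        assert result["bands"]["dwm"]["difference"] == pytest.approx(12.0)

    def test_band_specific_offsets_recovered(self):
        phantom = gen_ribbon_phantom(RibbonPhantomConfig(noise_sd=0.0))
        before = phantom["r2s"]
        # subtract a map proportional to iron: SWM drops more than DWM
        after = before - 0.1 * phantom["iron"]
        result = paired_map_difference(
            before, after, phantom["boundary"], phantom["cortical_depth"]
        )
        assert result["bands"]["swm"]["difference"] == pytest.approx(5.5, abs=1e-6)
        assert result["bands"]["dwm"]["difference"] == pytest.approx(3.3, abs=1e-6)


class TestLinearContrastFit:
    def test_exact_recovery_without_noise(self):
        phantom = gen_ribbon_phantom(RibbonPhantomConfig(noise_sd=0.0))
        prof = {
            k: extract_profiles(
                phantom[k], phantom["boundary"], phantom["cortical_depth"]
            )
            for k in ("r2s", "iron", "myelin")
        }
        fit = fit_linear_contrast_model(
            prof["r2s"].mean, prof["iron"].mean, prof["myelin"].mean
        )
        truth = phantom["truth"]["coefficients"]
        assert fit.coefficients == pytest.approx(truth, rel=1e-9)
        assert fit.variance_explained == pytest.approx(1.0)

    def test_noisy_recovery_within_two_stderr(self):
        phantom = gen_ribbon_phantom(RibbonPhantomConfig(seed=5))
        prof = {
            k: extract_profiles(
                phantom[k], phantom["boundary"], phantom["cortical_depth"]
            )
            for k in ("r2s", "iron", "myelin")
        }
        fit = fit_linear_contrast_model(
            prof["r2s"].mean, prof["iron"].mean, prof["myelin"].mean
        )
        truth = dict(zip(
            ("iron_relaxivity", "myelin_coefficient", "offset"),
            phantom["truth"]["coefficients"],
        ))
        for name in truth:
            assert abs(getattr(fit, name) - truth[name]) < 2 * fit.stderr[name]

    def test_full_model_never_below_reduced(self, rng):
        for _ in range(10):
            iron = rng.uniform(10, 60, 40)
            myelin = rng.uniform(0.1, 0.5, 40)
            y = rng.normal(20, 5, 40)
            fit = fit_linear_contrast_model(y, iron, myelin)
            assert fit.variance_explained >= fit.variance_explained_reduced - 1e-12

    def test_zero_iron_profile_makes_models_coincide(self, rng):
        myelin = rng.uniform(0.1, 0.5, 40)
        y = 47 * myelin + 13.7 + rng.normal(0, 0.5, 40)
        fit = fit_linear_contrast_model(y, np.zeros(40), myelin)
        assert fit.variance_explained == pytest.approx(
            fit.variance_explained_reduced, abs=1e-9
        )

    def test_profile_se_shrinks_with_profile_count(self, rng):
        # i.i.d. noise: SE of the mean profile ~ 1/sqrt(n_profiles)
        grid = rng.standard_normal((200, 400))
        small = extract_profiles(
            grid, horizontal_boundary(100, 400, 10), 30.0, n_profiles=10
        )
        large = extract_profiles(
            grid, horizontal_boundary(100, 400, 40), 30.0, n_profiles=40
        )
        ratio = np.median(small.se) / np.median(large.se)
        assert ratio == pytest.approx(2.0, rel=0.5)
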
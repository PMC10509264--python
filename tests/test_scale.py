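"""Local-scale estimation: filters, normalizer, invariances, utilities."""

import numpy as np
import pytest

from occuscale import (
    Blob,
    PhantomSpec,
    ScaleMap,
    VolumeGrid,
    build_spherical_kernel,
    calibrate_tau_effective,
    clamp,
    estimate_local_scale,
    estimate_occupancy_scale,
    full_scale_normalizer,
    lowpass,
    make_phantom,
    max_filter,
    place_tiles,
    recalibrate_zero_point,
    rms_scale_difference,
    targeted_scale_estimate,
)


def brute_force_max_filter(data, kernel):
    """Per-voxel loop with edge replication; the independent oracle."""
    nz, ny, nx = data.shape
    out = np.empty_like(data)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                best = -np.inf
                for dz, dy, dx in kernel.offsets:
                    zz = min(max(z + dz, 0), nz - 1)
                    yy = min(max(y + dy, 0), ny - 1)
                    xx = min(max(x + dx, 0), nx - 1)
                    best = max(best, data[zz, yy, xx])
                out[z, y, x] = best
    return out


class TestMaxFilter:
    def test_constant_volume_unchanged(self, kernel5):
        grid = VolumeGrid(np.full((12, 12, 12), 3.5, dtype=np.float32))
        assert np.array_equal(max_filter(grid, kernel5), grid.data)

    def test_impulse_dilates_to_cross(self):
        kernel = build_spherical_kernel(3, 1.0)
        data = np.zeros((9, 9, 9), dtype=np.float32)
        data[4, 4, 4] = 1.0
        out = max_filter(VolumeGrid(data), kernel)
        assert out.sum() == 7  # center + 6 face neighbors
        assert out[4, 4, 4] == 1.0 and out[4, 4, 5] == 1.0 and out[4, 5, 4] == 1.0
        assert out[3, 3, 4] == 0.0  # edge neighbor outside radius 1

    @pytest.mark.parametrize("k,radius", [(3, 1.0), (3, 1.6), (5, 2.5)])
    def test_matches_brute_force_on_random_volume(self, rng, k, radius):
        kernel = build_spherical_kernel(k, radius)
        data = rng.normal(size=(8, 8, 8)).astype(np.float32)
        out = max_filter(VolumeGrid(data), kernel)
        assert np.array_equal(out, brute_force_max_filter(data, kernel))

    def test_kernel_larger_than_volume(self, kernel5):
        with pytest.raises(ValueError):
            max_filter(VolumeGrid(np.zeros((4, 4, 4), dtype=np.float32)), kernel5)


class TestNormalizer:
    def test_single_tile_percentile_against_sort_oracle(self):
        values = np.arange(1, 1001, dtype=np.float32).reshape(10, 10, 10)
        tiling = place_tiles((10, 10, 10), tile_edge=10, grid_count=1)
        got = full_scale_normalizer(VolumeGrid(values), tiling, 0.9)
        # linear-interpolation percentile oracle on sorted values
        expected = np.percentile(np.sort(values.ravel()), 90.0)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(900.1)  # 0.9 * (n-1) = 899.1 -> 900.1

    def test_max_over_tiles_picks_strongest(self):
        data = np.ones((24, 12, 12), dtype=np.float32)
        data[12:] = 2.0
        tiling = place_tiles((24, 12, 12), tile_edge=12, grid_count=2)
        assert full_scale_normalizer(VolumeGrid(data), tiling, 0.5) == 2.0

    def test_uniform_volume_gives_the_constant(self):
        grid = VolumeGrid(np.full((16, 16, 16), 2.5, dtype=np.float32))
        tiling = place_tiles((16, 16, 16), tile_edge=8, grid_count=2)
        for tau in (0.3, 0.7, 0.95):
            assert full_scale_normalizer(grid, tiling, tau) == 2.5

    def test_random_tiles_match_brute_force(self, rng):
        data = rng.normal(size=(16, 16, 16)).astype(np.float32) + 2.0
        tiling = place_tiles((16, 16, 16), tile_edge=6, grid_count=3)
        tau = 0.8
        expected = max(
            np.percentile(
                data[o[0]:o[0]+6, o[1]:o[1]+6, o[2]:o[2]+6].ravel(), 100 * tau
            )
            for o in tiling.tile_origins
        )
        got = full_scale_normalizer(VolumeGrid(data), tiling, tau)
        assert got == pytest.approx(expected)

    def test_all_negative_map_errors(self):
        grid = VolumeGrid(np.full((16, 16, 16), -1.0, dtype=np.float32))
        tiling = place_tiles((16, 16, 16), tile_edge=8, grid_count=2)
        with pytest.raises(ValueError, match="full-scale"):
            full_scale_normalizer(grid, tiling, 0.9)


def test_clamp():
    assert clamp(1.3, 0, 1) == 1.0
    assert clamp(-0.2, 0, 1) == 0.0
    assert clamp(0.5, 0, 1) == 0.5
    with pytest.raises(ValueError):
        clamp(0.5, 1, 0)


class TestEstimateLocalScale:
    def test_half_scale_region_recovered(self, two_blob_phantom, kernel5):
        est = estimate_local_scale(two_blob_phantom["f"], kernel5)
        half = est.values[two_blob_phantom["half_region"]]
        assert abs(half.mean() - 0.5) <= 0.05
        full = est.values[two_blob_phantom["full_region"]]
        assert abs(full.mean() - 1.0) <= 0.02

    def test_uniform_positive_volume_is_full_scale(self, kernel5):
        grid = VolumeGrid(np.full((32, 32, 32), 1.7, dtype=np.float32))
        est = estimate_local_scale(grid, kernel5, place_tiles((32,) * 3, 8, 3))
        assert np.all(est.values == 1.0)

    def test_invariant_under_global_rescaling(self, two_blob_phantom, kernel5):
        f = two_blob_phantom["f"]
        est1 = estimate_local_scale(f, kernel5)
        est10 = estimate_local_scale(f.with_data(10.0 * f.data), kernel5)
        assert np.allclose(est1.values, est10.values, atol=1e-6)
        assert est10.normalizer == pytest.approx(10 * est1.normalizer, rel=1e-6)

    def test_values_always_in_unit_interval(self, rng, kernel5):
        data = rng.normal(2.0, 1.0, size=(32, 32, 32)).astype(np.float32)
        est = estimate_local_scale(VolumeGrid(data), kernel5, place_tiles((32,) * 3, 8, 4))
        assert est.values.min() >= 0.0 and est.values.max() <= 1.0

    def test_overestimation_bounded_by_one_minus_tau(self, two_blob_phantom, kernel5):
        """On a noise-free piecewise phantom with an exactly full-scale
        tile, the half-scale region can be over-estimated by at most
        1 - tau in normalized units."""
        est = estimate_local_scale(two_blob_phantom["f"], kernel5)
        half = est.values[two_blob_phantom["half_region"]]
        assert half.max() - 0.5 <= (1.0 - kernel5.tau) + 1e-6


class TestLowpass:
    def test_passband_identity_on_band_limited_input(self, rng):
        """A filter whose passband covers the input spectrum changes
        nothing: filtering an 8 A-limited map at 4 A is the identity."""
        data = rng.normal(size=(32, 32, 32)).astype(np.float32)
        limited = lowpass(VolumeGrid(data), cutoff=8.0)
        out = lowpass(limited, cutoff=4.0)
        assert np.allclose(out.data, limited.data, atol=1e-5)

    def test_sinusoid_beyond_cutoff_suppressed(self):
        n = 48
        z = np.arange(n)
        # wavelength 4 A sinusoid, cutoff 8 A -> fully in the stopband
        data = np.sin(2 * np.pi * z / 4.0)[:, None, None] * np.ones((n, n, n))
        out = lowpass(VolumeGrid(data.astype(np.float32)), cutoff=8.0)
        assert np.abs(out.data).max() <= np.abs(data).max() / 100.0

    def test_power_never_increases(self, rng):
        data = rng.normal(size=(24, 24, 24)).astype(np.float32)
        out = lowpass(VolumeGrid(data), cutoff=6.0)
        assert (out.data**2).sum() <= (data**2).sum()

    def test_mean_preserved(self, rng):
        data = (rng.normal(size=(24, 24, 24)) + 3.0).astype(np.float32)
        out = lowpass(VolumeGrid(data), cutoff=6.0)
        assert out.data.mean() == pytest.approx(data.mean(), rel=1e-5)

    def test_sub_nyquist_cutoff_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass(VolumeGrid(np.zeros((16,) * 3, dtype=np.float32)), cutoff=1.5)


class TestOccupancyMode:
    def test_full_passband_equals_plain_estimate(self, two_blob_phantom, kernel5):
        """When the low-pass filter passes the entire input spectrum,
        occupancy mode reduces to the plain estimate."""
        f = two_blob_phantom["f"]
        limited = lowpass(f, cutoff=8.0)
        plain = estimate_local_scale(limited, kernel5)
        occ = estimate_occupancy_scale(limited, cutoff=4.0, kernel=kernel5)
        assert np.allclose(occ.values, plain.values, atol=1e-3)
        assert occ.mode == "occupancy"

    def test_lowpass_slightly_underestimates_sharp_content(self, two_blob_phantom, kernel5):
        """Delocalizing detail outside the kernel window reduces the
        occupancy-mode estimate relative to plain mode on sharp input."""
        f = two_blob_phantom["f"]
        plain = estimate_local_scale(f, kernel5)
        occ = estimate_occupancy_scale(f, cutoff=6.0, kernel=kernel5)
        half = two_blob_phantom["half_region"]
        assert occ.values[half].mean() <= plain.values[half].mean() + 1e-6


class TestRecalibration:
    def test_zero_point_identity_and_fixed_points(self, rng):
        values = rng.uniform(0, 1, size=(8, 8, 8)).astype(np.float32)
        scale = ScaleMap(values)
        assert np.allclose(recalibrate_zero_point(scale, 0.0).values, values)
        out = recalibrate_zero_point(ScaleMap(np.full((8,) * 3, 0.3, np.float32)), 0.3)
        assert np.all(out.values == 0.0)
        out = recalibrate_zero_point(ScaleMap(np.ones((8,) * 3, np.float32)), 0.7)
        assert np.all(out.values == 1.0)

    def test_formula_and_clamping(self):
        scale = ScaleMap(np.array([[[0.1, 0.2, 0.6, 1.0]]], dtype=np.float32))
        out = recalibrate_zero_point(scale, 0.2)
        expected = np.clip((np.array([0.1, 0.2, 0.6, 1.0]) - 0.2) / 0.8, 0, 1)
        assert np.allclose(out.values[0, 0], expected, atol=1e-7)
        assert out.recalibrated and out.s_p == pytest.approx(0.2)

    def test_invalid_s_p(self):
        with pytest.raises(ValueError):
            recalibrate_zero_point(ScaleMap(np.zeros((4,) * 3, np.float32)), 1.0)


class TestTargetedEstimate:
    def _mask_around(self, shape, center, radius):
        grids = np.ogrid[tuple(slice(0, n) for n in shape)]
        dist = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
        return VolumeGrid((dist <= radius).astype(np.float32))

    def test_mask_on_full_scale_region_matches_global(self, two_blob_phantom, kernel5):
        f = two_blob_phantom["f"]
        mask = self._mask_around(f.shape, (20, 20, 20), 14)
        est_global = estimate_local_scale(f, kernel5)
        est_target = targeted_scale_estimate(f, mask, kernel5)
        assert est_target.normalizer == pytest.approx(est_global.normalizer)
        assert np.allclose(est_target.values, est_global.values)

    def test_half_scale_region_defines_its_own_full_scale(self, two_blob_phantom, kernel5):
        f = two_blob_phantom["f"]
        mask = self._mask_around(f.shape, (44, 44, 44), 14)
        est = targeted_scale_estimate(f, mask, kernel5)
        half = est.values[two_blob_phantom["half_region"]]
        assert half.mean() == pytest.approx(1.0, abs=0.02)
        assert est.normalizer == pytest.approx(0.5, abs=0.05)

    def test_empty_mask_errors(self, two_blob_phantom, kernel5):
        f = two_blob_phantom["f"]
        empty = VolumeGrid(np.zeros(f.shape, dtype=np.float32))
        with pytest.raises(ValueError, match="empty"):
            targeted_scale_estimate(f, empty, kernel5)


class TestTauEffective:
    def test_sharp_phantom_converges_to_auto_tau(self, two_blob_phantom, kernel5):
        tau_eff = calibrate_tau_effective(
            two_blob_phantom["f"], two_blob_phantom["true_scale"], kernel5
        )
        assert tau_eff == pytest.approx(kernel5.tau, abs=0.05)

    def test_blurred_phantom_needs_lower_tau(self, kernel5):
        spec = PhantomSpec(
            shape=(64, 64, 64),
            blobs=(
                Blob(center=(20.0, 20.0, 20.0), radius=14.0, true_scale=1.0, blur_sigma=1.5),
                Blob(center=(44.0, 44.0, 44.0), radius=14.0, true_scale=0.5, blur_sigma=1.5),
            ),
        )
        f, true_scale, _ = make_phantom(spec)
        blurred = lowpass(f, cutoff=8.0)
        tau_eff = calibrate_tau_effective(blurred, true_scale, kernel5)
        assert tau_eff < kernel5.tau

    def test_requires_half_scale_region(self, kernel5):
        grid = VolumeGrid(np.ones((32,) * 3, dtype=np.float32))
        with pytest.raises(ValueError, match="0.5"):
            calibrate_tau_effective(grid, np.ones((32,) * 3), kernel5)


class TestRmsDifference:
    def test_identical_maps_give_zero(self, rng):
        a = ScaleMap(rng.uniform(0, 1, size=(8, 8, 8)).astype(np.float32))
        assert rms_scale_difference(a, a) == 0.0

    def test_constant_offset(self, rng):
        a = rng.uniform(0, 0.9, size=(8, 8, 8)).astype(np.float32)
        b = a + 0.1
        assert rms_scale_difference(ScaleMap(a), ScaleMap(b)) == pytest.approx(0.1, abs=1e-6)

    def test_matches_direct_formula_with_mask(self, rng):
        a = rng.uniform(0, 1, size=(8, 8, 8)).astype(np.float32)
        b = rng.uniform(0, 1, size=(8, 8, 8)).astype(np.float32)
        mask = rng.uniform(size=(8, 8, 8)) > 0.5
        expected = np.sqrt(np.mean((a[mask].astype(np.float64) - b[mask]) ** 2))
        assert rms_scale_difference(ScaleMap(a), ScaleMap(b), mask) == pytest.approx(expected)

    def test_shape_mismatch(self, rng):
        a = ScaleMap(np.zeros((8, 8, 8), dtype=np.float32))
        b = ScaleMap(np.zeros((6, 6, 6), dtype=np.float32))
        with pytest.raises(ValueError):
            rms_scale_difference(a, b)
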
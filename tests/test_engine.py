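"""COF map computation: convolution correctness, invariances, point queries."""

import numpy as np
import pytest

from cutoutfactor import (
    ApertureMask,
    COFMap,
    build_kernel,
    cof_at_point,
    compute_cof_map,
    find_max_point,
    rasterize,
    synth_cutout,
    synth_of_curve,
)
from cutoutfactor.synthetic import PRESETS


def double_sum_oracle(mask, kernel):
    """Brute-force COF[x, y] = sum_{n1,n2} OK[n1,n2] * f[x-n1, y-n2]."""
    half = kernel.shape[0] // 2
    ny, nx = mask.shape
    padded = np.pad(mask.astype(float), half)
    out = np.empty((ny, nx))
    flipped = kernel[::-1, ::-1]
    for r in range(ny):
        for c in range(nx):
            out[r, c] = np.sum(flipped * padded[r : r + 2 * half + 1, c : c + 2 * half + 1])
    return out


def random_kernel(seed):
    """Kernel from a random monotone curve, 21x21 px at 1 mm."""
    rng = np.random.default_rng(seed)
    params = PRESETS["9E-like"]
    curve = synth_of_curve(
        type(params)(
            plateau=rng.uniform(0.7, 1.1),
            rise_scale_cm=rng.uniform(0.3, 1.0),
            shape_exponent=rng.uniform(1.0, 2.5),
        )
    )
    return build_kernel(curve, max_radius_cm=1.1)


def random_mask(seed, shape=(50, 50), density=0.4, padding_cm=1.1):
    rng = np.random.default_rng(seed)
    values = (rng.random(shape) < density).astype(np.uint8)
    return ApertureMask(values=values, resolution_mm=1.0, origin=(0.0, 0.0),
                        padding_cm=padding_cm)


def disk_mask(radius_px, pad_px, delta_r_px=1.0):
    """Annulus-binned disk: pixels whose center distance bins below radius_px."""
    n = radius_px + pad_px
    offs = np.arange(-n, n + 1)
    d = np.hypot(offs[:, None], offs[None, :])
    values = (np.floor(d / delta_r_px + 1e-9) < radius_px).astype(np.uint8)
    return ApertureMask(values=values, resolution_mm=1.0,
                        origin=(-n * 0.1, -n * 0.1), padding_cm=pad_px * 0.1)


class TestConvolutionCorrectness:
    @pytest.mark.parametrize("method", ["direct", "fft"])
    def test_matches_double_sum_oracle(self, method):
        kernel = random_kernel(1)
        mask = random_mask(2)
        cof = compute_cof_map(kernel, mask, method=method)
        expected = double_sum_oracle(mask.values, kernel.values)
        np.testing.assert_allclose(cof.values, expected, rtol=0, atol=1e-9)

    def test_fft_and_direct_agree(self):
        kernel = random_kernel(3)
        mask = random_mask(4)
        direct = compute_cof_map(kernel, mask, method="direct")
        fft = compute_cof_map(kernel, mask, method="fft")
        np.testing.assert_allclose(fft.values, direct.values, rtol=0, atol=1e-9)

    def test_three_by_three_opening_hand_sum(self, three_annulus_curve):
        # 3x3 open region with the hand-enumerable kernel: COF at its center
        # is 0.10 + 8 * 0.00625 = 0.15
        kernel = build_kernel(three_annulus_curve)
        values = np.zeros((9, 9), dtype=np.uint8)
        values[3:6, 3:6] = 1
        mask = ApertureMask(values=values, resolution_mm=1.0,
                            origin=(-0.4, -0.4), padding_cm=0.3)
        cof = compute_cof_map(kernel, mask)
        assert cof.values[4, 4] == pytest.approx(0.15, abs=1e-12)

    def test_empty_mask_gives_zero_map(self, three_annulus_curve):
        kernel = build_kernel(three_annulus_curve)
        mask = ApertureMask(values=np.zeros((9, 9), dtype=np.uint8),
                            resolution_mm=1.0, origin=(0.0, 0.0), padding_cm=0.3)
        cof = compute_cof_map(kernel, mask)
        np.testing.assert_array_equal(cof.values, 0.0)

    def test_disk_recovery_is_exact_under_annulus_binning(self, six_cm_curve):
        # telescoping: a disk built with the kernel's own binning returns
        # OF(K * dr) at its center to machine precision
        kernel = build_kernel(six_cm_curve, max_radius_cm=3.0)
        for radius_px in (10, 20, 30):
            mask = disk_mask(radius_px, pad_px=kernel.half_width)
            cof = compute_cof_map(kernel, mask, method="direct")
            center = mask.values.shape[0] // 2
            assert cof.values[center, center] == pytest.approx(
                six_cm_curve.evaluate(radius_px * 0.1), abs=1e-12
            )

    def test_circular_cutout_recovers_source_curve(self):
        # polygon circle -> raster -> convolution reproduces OF(r) within 0.5%
        curve = synth_of_curve(PRESETS["6E-like"])
        kernel = build_kernel(curve)
        pad = kernel.half_width * 0.1
        for r in (1.0, 3.0, 6.0):
            shape = synth_cutout("circle", radius_cm=r)
            mask = rasterize(shape, resolution_mm=1.0, padding_cm=pad)
            cof = compute_cof_map(kernel, mask, method="fft")
            assert cof_at_point(cof, 0.0, 0.0) == pytest.approx(
                curve.evaluate(r), rel=5e-3
            )

    def test_resolution_mismatch_rejected(self, three_annulus_curve):
        kernel = build_kernel(three_annulus_curve, resolution_mm=1.0)
        mask = ApertureMask(values=np.ones((5, 5), dtype=np.uint8),
                            resolution_mm=2.0, origin=(0.0, 0.0), padding_cm=1.0)
        with pytest.raises(ValueError, match="resolution mismatch"):
            compute_cof_map(kernel, mask)

    def test_insufficient_padding_names_requirement(self, six_cm_curve):
        kernel = build_kernel(six_cm_curve)
        mask = ApertureMask(values=np.ones((5, 5), dtype=np.uint8),
                            resolution_mm=1.0, origin=(0.0, 0.0), padding_cm=1.0)
        with pytest.raises(ValueError, match="5.9 cm"):
            compute_cof_map(kernel, mask)


class TestInvariances:
    def test_whole_pixel_shift_translates_map_bit_exactly(self):
        kernel = random_kernel(5)
        mask = random_mask(6, shape=(60, 60))
        # content stays >= kernel half-width + roll distance from every edge
        border = np.zeros_like(mask.values)
        border[18:40, 18:40] = 1
        mask.values *= border  # keep content clear of the roll wrap-around
        shifted = ApertureMask(values=np.roll(mask.values, (7, -3), axis=(0, 1)),
                               resolution_mm=1.0, origin=mask.origin,
                               padding_cm=mask.padding_cm)
        cof = compute_cof_map(kernel, mask, method="direct")
        cof_shifted = compute_cof_map(kernel, shifted, method="direct")
        np.testing.assert_array_equal(
            cof_shifted.values, np.roll(cof.values, (7, -3), axis=(0, 1))
        )

    def test_nested_masks_give_ordered_maps(self):
        kernel = random_kernel(7)
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            big = (rng.random((50, 50)) < 0.5).astype(np.uint8)
            small = big * (rng.random((50, 50)) < 0.7).astype(np.uint8)
            cof_small = compute_cof_map(
                kernel, ApertureMask(small, 1.0, (0.0, 0.0), 1.1))
            cof_big = compute_cof_map(
                kernel, ApertureMask(big, 1.0, (0.0, 0.0), 1.1))
            assert np.all(cof_small.values <= cof_big.values + 1e-12)

    def test_map_bounded_by_full_disk_output(self, six_cm_curve):
        kernel = build_kernel(six_cm_curve, max_radius_cm=2.0)
        mask = random_mask(8, shape=(40, 40), density=1.0, padding_cm=2.0)
        cof = compute_cof_map(kernel, mask)
        assert np.all(cof.values <= six_cm_curve.evaluate(2.0) + 1e-12)
        assert np.all(cof.values >= 0.0)


class TestPointQueries:
    @pytest.fixture
    def small_map(self):
        values = np.arange(25, dtype=float).reshape(5, 5)
        return COFMap(values=values, resolution_mm=1.0, origin=(0.0, 0.0))

    def test_query_at_pixel_center_returns_pixel(self, small_map):
        assert cof_at_point(small_map, 0.2, 0.1) == small_map.values[1, 2]

    def test_query_outside_extent_rejected(self, small_map):
        with pytest.raises(ValueError, match="outside"):
            cof_at_point(small_map, 1.0, 0.0)

    def test_bilinear_midpoint_averages_row_neighbors(self, small_map):
        a = small_map.values[2, 1]
        b = small_map.values[2, 2]
        got = cof_at_point(small_map, 0.15, 0.2, mode="bilinear")
        assert got == pytest.approx((a + b) / 2, abs=1e-12)


class TestFindMaxPoint:
    def test_single_disk_max_at_center_value_of_curve(self, six_cm_curve):
        kernel = build_kernel(six_cm_curve, max_radius_cm=2.0)
        mask = disk_mask(15, pad_px=kernel.half_width)
        cof = compute_cof_map(kernel, mask)
        mp = find_max_point(cof)
        assert mp.cof == pytest.approx(six_cm_curve.evaluate(1.5), abs=1e-12)
        # symmetric plateau about the disk center
        assert abs(mp.x_cm) <= 0.05 + 1e-9
        assert abs(mp.y_cm) <= 0.05 + 1e-9

    def test_two_disjoint_disks_max_in_larger(self, six_cm_curve):
        kernel = build_kernel(six_cm_curve, max_radius_cm=1.0)
        n = 45
        offs = np.arange(n) - (n - 1) / 2
        d_small = np.hypot(offs[:, None] + 14, offs[None, :] + 14)
        d_big = np.hypot(offs[:, None] - 10, offs[None, :] - 10)
        values = ((d_small < 5) | (d_big < 11)).astype(np.uint8)
        mask = ApertureMask(values, 1.0, (-2.2, -2.2), 1.0)
        cof = compute_cof_map(kernel, mask)
        mp = find_max_point(cof)
        # maximum sits inside the larger opening (centered at +1.0, +1.0 cm)
        assert np.hypot(mp.x_cm - 1.0, mp.y_cm - 1.0) < 1.1

    def test_uniform_plateau_tie_breaks_row_major(self):
        values = np.full((4, 4), 0.5)
        cof = COFMap(values=values, resolution_mm=1.0, origin=(0.0, 0.0))
        mp = find_max_point(cof)
        assert (mp.x_cm, mp.y_cm) == (0.0, 0.0)
        assert len(mp.plateau_points) == 16

    def test_empty_aperture_rejected(self):
        cof = COFMap(values=np.zeros((4, 4)), resolution_mm=1.0, origin=(0.0, 0.0))
        with pytest.raises(ValueError, match="empty aperture"):
            find_max_point(cof)
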
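"""Threshold segmentation, spleen removal and the manual-reference VOI rules."""

import dataclasses

import numpy as np
import pytest

from duodose import (
    BinaryMask,
    SegmentationConfig,
    VoxelGrid,
    automatic_healthy_mask,
    dice,
    gaussian_smooth,
    make_phantom,
    reference_healthy_mask,
    remove_spleen,
    simulate_spect,
)
from duodose.image import DegenerateInputError
from duodose.segmentation import equivalent_sphere_diameter_mm


class TestGaussianSmooth:
    def test_zero_fwhm_is_identity(self, rng):
        g = VoxelGrid(rng.random((10, 10, 10)), (2, 2, 2))
        out = gaussian_smooth(g, 0.0)
        np.testing.assert_array_equal(out.values, g.values)

    def test_impulse_matches_analytic_gaussian(self):
        # fwhm 10 mm -> sigma = 10 / (2 sqrt(2 ln 2)) = 4.2466 mm
        spacing = 2.0
        n = 61
        vals = np.zeros((n, n, n))
        vals[n // 2, n // 2, n // 2] = 1.0
        out = gaussian_smooth(VoxelGrid(vals, (spacing,) * 3), 10.0)
        sigma = 10.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        assert sigma == pytest.approx(4.2466, abs=1e-4)
        r = np.arange(n) * spacing - (n // 2) * spacing
        x, y, z = np.meshgrid(r, r, r, indexing="ij")
        # discrete impulse response ~ analytic kernel sampled at voxel centers
        analytic = np.exp(-(x**2 + y**2 + z**2) / (2 * sigma**2))
        analytic *= (spacing / (np.sqrt(2 * np.pi) * sigma)) ** 3
        center = out.values[n // 2, n // 2, n // 2]
        assert center == pytest.approx(
            analytic[n // 2, n // 2, n // 2], rel=1e-3
        )

    def test_interior_blob_integral_preserved(self, rng):
        vals = np.zeros((40, 40, 40))
        vals[15:25, 15:25, 15:25] = rng.random((10, 10, 10))
        g = VoxelGrid(vals, (4.0, 4.0, 4.0))
        out = gaussian_smooth(g, 12.0)
        assert out.values.sum() == pytest.approx(vals.sum(), rel=1e-6)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(VoxelGrid(np.zeros((4, 4, 4))), -1.0)


def two_spheres(peaks=(100.0, 30.0), spacing=4.0):
    """Two disjoint uniform spheres with the given plateau values."""
    from duodose.phantom import Ellipsoid, _voxel_centers

    shape = (48, 48, 24)
    pts = _voxel_centers(shape, (spacing,) * 3)
    a = Ellipsoid((60.0, 96.0, 48.0), (36.0, 36.0, 36.0)).contains(pts)
    b = Ellipsoid((150.0, 96.0, 48.0), (24.0, 24.0, 24.0)).contains(pts)
    vals = np.where(a, peaks[0], 0.0) + np.where(b, peaks[1], 0.0)
    return VoxelGrid(vals, (spacing,) * 3), a, b


class TestRemoveSpleen:
    def test_largest_component_zeroes_spleen_counts(self, default_spec):
        truth = make_phantom(default_spec)
        tc = simulate_spect(
            truth.tc_activity, default_spec.psf_fwhm_mm, 5_000_000, seed=5
        )
        cfg = SegmentationConfig()
        out = remove_spleen(tc, cfg)
        # the vast majority of spleen uptake is zeroed...
        assert (out.values[truth.spleen.as_bool()] == 0).mean() > 0.9
        # ...while liver counts are untouched
        liver = truth.liver.as_bool()
        np.testing.assert_array_equal(out.values[liver], tc.values[liver])

    def test_provided_empty_mask_is_identity(self, rng):
        tc = VoxelGrid(rng.random((8, 8, 8)), (4, 4, 4))
        cfg = SegmentationConfig(spleen_strategy="provided_mask")
        empty = BinaryMask(np.zeros((8, 8, 8), dtype=np.uint8), (4, 4, 4))
        out = remove_spleen(tc, cfg, empty)
        np.testing.assert_array_equal(out.values, tc.values)

    def test_single_region_unchanged_under_largest_component(self):
        img, a, _ = two_spheres(peaks=(100.0, 0.0))
        out = remove_spleen(img, SegmentationConfig())
        np.testing.assert_array_equal(out.values, img.values)

    def test_provided_mask_strategy_requires_mask(self, rng):
        tc = VoxelGrid(rng.random((8, 8, 8)))
        with pytest.raises(ValueError, match="spleen mask"):
            remove_spleen(tc, SegmentationConfig(spleen_strategy="provided_mask"))


class TestAutomaticHealthyMask:
    def test_uniform_sphere_recovered_exactly_without_smoothing(self):
        img, a, _ = two_spheres(peaks=(50.0, 0.0))
        cfg = SegmentationConfig(smoothing_fwhm_mm=0.0, min_component_ml=0.0)
        mask = automatic_healthy_mask(img, cfg)
        np.testing.assert_array_equal(mask.as_bool(), a)

    def test_cold_second_sphere_below_threshold_excluded(self):
        # peaks 100 and 30: threshold 0.4 * 100 = 40 > 30
        img, a, b = two_spheres(peaks=(100.0, 30.0))
        cfg = SegmentationConfig(
            smoothing_fwhm_mm=0.0, min_component_ml=0.0,
            spleen_strategy="provided_mask",
        )
        empty = BinaryMask(np.zeros(img.shape, dtype=np.uint8), img.spacing)
        mask = automatic_healthy_mask(img, cfg, spleen_mask=empty)
        np.testing.assert_array_equal(mask.as_bool(), a)
        assert not (mask.as_bool() & b).any()

    def test_threshold_uses_smoothed_max_on_original_image(self):
        # A hot single voxel raises the unsmoothed max far above the smoothed
        # max; thresholding the original at 40% of the *smoothed* max must
        # still keep the plateau.
        img, a, _ = two_spheres(peaks=(50.0, 0.0))
        vals = img.values.copy()
        vals[15, 24, 12] *= 4.0  # inside sphere a
        spiked = img.copy_with(vals)
        cfg = SegmentationConfig(smoothing_fwhm_mm=20.0, min_component_ml=0.0)
        mask = automatic_healthy_mask(spiked, cfg)
        assert (mask.as_bool() & a).sum() / a.sum() > 0.95

    def test_invariant_to_positive_rescaling(self, default_truth, default_spec):
        tc = simulate_spect(
            default_truth.tc_activity, default_spec.psf_fwhm_mm, 2_000_000, seed=9
        )
        m1 = automatic_healthy_mask(tc)
        m2 = automatic_healthy_mask(tc.copy_with(tc.values * 37.5))
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_lowering_threshold_never_shrinks_mask(self, default_truth, default_spec):
        tc = simulate_spect(
            default_truth.tc_activity, default_spec.psf_fwhm_mm, 2_000_000, seed=9
        )
        masks = [
            automatic_healthy_mask(
                tc, SegmentationConfig(threshold_fraction=f, min_component_ml=0.0)
            )
            for f in (0.6, 0.4, 0.2)
        ]
        for tighter, looser in zip(masks, masks[1:]):
            assert (tighter.as_bool() <= looser.as_bool()).all()

    def test_matches_naive_reimplementation_on_small_grids(self, rng):
        """Voxel-for-voxel equality with a triple-loop threshold + 26-connected
        component oracle (no smoothing, so the threshold rule is exact)."""
        cfg = SegmentationConfig(smoothing_fwhm_mm=0.0, min_component_ml=0.5,
                                 spleen_strategy="provided_mask")
        for _ in range(10):
            shape = tuple(rng.integers(6, 14, size=3))
            vals = rng.random(shape) * 100.0
            vals[vals < 30] = 0.0
            img = VoxelGrid(vals, (10.0, 10.0, 10.0))
            empty = BinaryMask(np.zeros(shape, dtype=np.uint8), img.spacing)
            got = automatic_healthy_mask(img, cfg, spleen_mask=empty)
            expected = naive_threshold_segmentation(
                vals, cfg.threshold_fraction, img.voxel_volume_ml, cfg.min_component_ml
            )
            np.testing.assert_array_equal(got.as_bool(), expected)

    def test_all_zero_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            automatic_healthy_mask(VoxelGrid(np.zeros((6, 6, 6))))

    def test_recovers_phantom_healthy_truth(self, default_spec):
        spec = dataclasses.replace(
            default_spec, psf_fwhm_mm=8.0, tc_total_counts=10_000_000
        )
        truth = make_phantom(spec)
        tc = simulate_spect(truth.tc_activity, 8.0, spec.tc_total_counts, seed=1)
        mask = automatic_healthy_mask(tc)
        assert dice(mask, truth.healthy_truth) >= 0.85


def naive_threshold_segmentation(vals, fraction, voxel_ml, min_ml):
    """Triple-loop oracle: absolute threshold, 26-connected flood fill, size filter."""
    nx, ny, nz = vals.shape
    thr = fraction * vals.max()
    above = [
        (i, j, k)
        for i in range(nx)
        for j in range(ny)
        for k in range(nz)
        if vals[i, j, k] >= thr
    ]
    above_set = set(above)
    seen, components = set(), []
    for start in above:
        if start in seen:
            continue
        comp, stack = [], [start]
        seen.add(start)
        while stack:
            i, j, k = stack.pop()
            comp.append((i, j, k))
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for dk in (-1, 0, 1):
                        nb = (i + di, j + dj, k + dk)
                        if nb in above_set and nb not in seen:
                            seen.add(nb)
                            stack.append(nb)
        components.append(comp)
    out = np.zeros(vals.shape, dtype=bool)
    for comp in components:
        if len(comp) * voxel_ml >= min_ml:
            for idx in comp:
                out[idx] = True
    return out


class TestReferenceHealthyMask:
    def test_liver_only_passthrough(self, default_truth):
        out = reference_healthy_mask(default_truth.liver)
        np.testing.assert_array_equal(out.values, default_truth.liver.values)

    def test_large_tumor_subtracted_by_volume(self):
        spacing = (10.0, 10.0, 10.0)  # 1 ml voxels
        liver = np.zeros((16, 16, 16), dtype=np.uint8)
        liver[1:13, 1:13, 1:13] = 1  # 1728 ml
        tumor = np.zeros_like(liver)
        tumor[4:8, 4:8, 4:8] = 1  # 64 ml, equiv. diameter ~ 49.6 mm
        out = reference_healthy_mask(
            BinaryMask(liver, spacing), [BinaryMask(tumor, spacing)]
        )
        assert out.volume_ml == pytest.approx(1728.0 - 64.0, abs=1.0)

    def test_subcentimeter_tumor_ignored(self):
        # 0.4 ml -> equivalent sphere diameter 2*(3*0.4/(4 pi))^(1/3) cm = 9.1 mm
        spacing = (2.0, 2.0, 2.0)  # 0.008 ml voxels
        liver = np.ones((20, 20, 20), dtype=np.uint8)
        tumor = np.zeros_like(liver)
        tumor.flat[:50] = 1  # 50 voxels = 0.4 ml
        tumor_mask = BinaryMask(tumor, spacing)
        assert equivalent_sphere_diameter_mm(tumor_mask) == pytest.approx(9.14, abs=0.05)
        out = reference_healthy_mask(BinaryMask(liver, spacing), [tumor_mask])
        np.testing.assert_array_equal(out.values, liver)

    def test_necrosis_excluded(self, default_truth):
        out = reference_healthy_mask(
            default_truth.liver, [default_truth.tumors], default_truth.necrosis
        )
        np.testing.assert_array_equal(out.values, default_truth.healthy_truth.values)

    def test_result_subset_of_liver_disjoint_from_retained_tumors(self, default_truth):
        out = reference_healthy_mask(default_truth.liver, [default_truth.tumors])
        assert (out.as_bool() <= default_truth.liver.as_bool()).all()
        assert not (out.as_bool() & default_truth.tumors.as_bool()).any()

    def test_grid_mismatch_rejected(self):
        from duodose import GridError

        a = BinaryMask(np.ones((4, 4, 4), dtype=np.uint8), (1, 1, 1))
        b = BinaryMask(np.ones((4, 4, 4), dtype=np.uint8), (2, 2, 2))
        with pytest.raises(GridError):
            reference_healthy_mask(a, [b])
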
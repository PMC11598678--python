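"""Hessian vesselness, skeleton extraction and refinement."""

import numpy as np
import pytest
from scipy.ndimage import binary_dilation, label

from nirvein import centerline as C
from nirvein import phantom as PH


def straight_tube_image(height=64, width=64, row=32, width_px=5,
                        contrast=0.5, background=0.8):
    pts = np.stack([np.full(width, row), np.arange(width)], axis=1)
    mask = PH.rasterize_vessel((height, width), pts, width_px)
    return background * (1.0 - contrast * mask), mask


class TestHessian:
    def test_constant_image_zero_eigenvalues(self):
        l1, l2 = C.hessian_eigenvalues(np.full((32, 32), 0.7), 2.0)
        assert np.allclose(l1, 0) and np.allclose(l2, 0)

    def test_quadratic_image_analytic_eigenvalues(self):
        r = np.arange(64, dtype=float)[:, None] * np.ones(64)
        l1, l2 = C.hessian_eigenvalues(r**2, 2.0)
        interior = (slice(16, 48), slice(16, 48))
        assert np.allclose(l2[interior], 2.0, atol=0.15)
        assert np.allclose(l1[interior], 0.0, atol=0.15)

    def test_eigenvalue_ordering(self, rng):
        img = rng.random((32, 32))
        l1, l2 = C.hessian_eigenvalues(img, 1.5)
        assert np.all(np.abs(l1) <= np.abs(l2) + 1e-12)

    def test_dark_tube_axis_signature(self):
        img, _ = straight_tube_image()
        l1, l2 = C.hessian_eigenvalues(img, 2.0)
        axis = l2[32, 10:54]
        assert np.all(axis > 0)
        assert np.all(np.abs(axis) > 5 * np.abs(l1[32, 10:54]))

    def test_sigma_validation(self):
        with pytest.raises(ValueError):
            C.hessian_eigenvalues(np.zeros((8, 8)), 0.0)


class TestResponse:
    def test_zero_eigenvalues_zero_response(self):
        z = np.zeros((16, 16))
        assert np.allclose(C.vein_response(z, z), 0)

    def test_bright_ridge_gated_out(self):
        # lambda2 < 0 everywhere contradicts a dark tube
        l2 = -np.ones((16, 16))
        l1 = 0.1 * np.ones((16, 16))
        assert np.allclose(C.vein_response(l1, l2), 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            C.vein_response(np.zeros((4, 4)), np.zeros((5, 4)))

    def test_response_peaks_on_true_centerline(self):
        img, _ = straight_tube_image()
        resp = C.multiscale_response(img, C.HessianConfig(sigmas=(2.0, 3.0)))
        for col in range(8, 56):
            assert abs(int(np.argmax(resp[:, col])) - 32) <= 1


class TestExtract:
    def test_empty_response_empty_skeleton(self):
        with pytest.warns(UserWarning, match="threshold"):
            out = C.extract_centerline(np.zeros((16, 16)))
        assert not out.any()

    def test_threshold_above_max_empty(self):
        resp = np.random.default_rng(0).random((16, 16)) * 0.1
        with pytest.warns(UserWarning):
            out = C.extract_centerline(resp, C.HessianConfig(response_threshold=0.5))
        assert not out.any()

    def test_solid_tube_thins_to_single_path(self):
        mask = np.zeros((32, 64))
        mask[14:19] = 1.0  # 5-px horizontal bar
        skel = C.extract_centerline(mask, C.HessianConfig(response_threshold=0.5))
        n_components = label(skel, structure=np.ones((3, 3)))[1]
        assert n_components == 1
        assert np.all(skel.sum(axis=0)[2:-2] == 1)  # 1 px wide along the run


class TestRefine:
    def test_small_island_removed(self):
        skel = np.zeros((32, 32), bool)
        skel[5, 5:8] = True  # 3-px island
        skel[20, 2:30] = True
        out = C.refine_centerline(skel, C.RefineConfig(min_region_area=10,
                                                       max_gap_distance=0, spur_length=0))
        assert not out[5].any() and out[20, 2:30].all()

    def test_collinear_gap_joined(self):
        skel = np.zeros((16, 40), bool)
        skel[8, 2:15] = True
        skel[8, 19:38] = True  # 4-px gap
        out = C.refine_centerline(skel, C.RefineConfig(min_region_area=0,
                                                       max_gap_distance=5, spur_length=0))
        assert label(out, structure=np.ones((3, 3)))[1] == 1
        assert out[8, 15:19].all()

    def test_distant_components_not_joined(self):
        skel = np.zeros((16, 40), bool)
        skel[8, 2:10] = True
        skel[8, 25:38] = True
        out = C.refine_centerline(skel, C.RefineConfig(min_region_area=0,
                                                       max_gap_distance=5, spur_length=0))
        assert label(out, structure=np.ones((3, 3)))[1] == 2

    def test_clean_skeleton_fixed_point(self):
        skel = np.zeros((20, 40), bool)
        skel[10, 2:38] = True
        out = C.refine_centerline(skel, C.RefineConfig(min_region_area=5,
                                                       max_gap_distance=10, spur_length=5))
        assert np.array_equal(out, skel)

    def test_short_spur_pruned_long_branch_kept(self):
        skel = np.zeros((24, 40), bool)
        skel[12, 2:38] = True
        skel[8:12, 20] = True  # 4-px spur off the main line
        out = C.refine_centerline(skel, C.RefineConfig(min_region_area=0,
                                                       max_gap_distance=0, spur_length=6))
        assert not out[8:12, 20].any()
        assert out[12, 2:38].all()

    def test_component_count_never_increases(self, rng):
        for _ in range(5):
            skel = rng.random((24, 24)) > 0.8
            before = label(skel, structure=np.ones((3, 3)))[1]
            out = C.refine_centerline(skel, C.RefineConfig(min_region_area=2,
                                                           max_gap_distance=4, spur_length=2))
            after = label(out, structure=np.ones((3, 3)))[1]
            assert after <= before


class TestLocalization:
    def test_centerline_within_dilated_mask_on_clean_phantom(self, clean_phantom):
        img, mask, _ = clean_phantom
        skel = C.centerline_pipeline(img, C.HessianConfig(response_threshold=0.15),
                                     C.RefineConfig(min_region_area=10, max_gap_distance=0))
        assert skel.any()
        outside = skel & ~binary_dilation(mask, iterations=2)
        assert outside.sum() == 0
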
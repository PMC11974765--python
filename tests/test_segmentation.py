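"""HU-window thresholding, seeded region growing, surface extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from avf_hemoflow.segmentation import (SegmentationConfig, SegmentationMask,
                                       cleanup_mask, extract_surface,
                                       inlet_extension, region_grow,
                                       threshold_volume)
from avf_hemoflow.synthgen import ImageVolume, make_straight_tube, rasterize_to_ct


def _volume(arr, spacing=0.05):
    return ImageVolume(intensities=np.asarray(arr, float),
                       spacing=(spacing,) * 3)


class TestThreshold:
    def test_all_background_gives_empty_mask_not_error(self):
        vol = _volume(np.zeros((8, 8, 8)))
        mask = threshold_volume(vol, SegmentationConfig())
        assert mask.empty and mask.voxel_count == 0

    def test_noiseless_cylinder_count_matches_rasterization(self):
        geom = make_straight_tube(0.5, 3.0)
        img = rasterize_to_ct(geom, noise_sd=0.0, seed=0, spacing=0.05)
        mask = threshold_volume(img, SegmentationConfig())
        assert mask.voxel_count == int((img.intensities == 600.0).sum())

    def test_degenerate_window_equals_wide_window_on_single_intensity(self):
        geom = make_straight_tube(0.5, 3.0)
        img = rasterize_to_ct(geom, noise_sd=0.0, seed=0, spacing=0.05)
        wide = threshold_volume(img, SegmentationConfig(300, 1000))
        tight = threshold_volume(img, SegmentationConfig(599.5, 600.5))
        assert np.array_equal(wide.mask, tight.mask)

    def test_bounds_are_inclusive(self):
        vol = _volume(np.array([[[299.9, 300.0, 1000.0, 1000.1]]]))
        mask = threshold_volume(vol, SegmentationConfig(300, 1000))
        assert mask.mask.ravel().tolist() == [False, True, True, False]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(lo=st.floats(100, 500), width=st.floats(1, 500),
           extra=st.floats(0, 400), seed=st.integers(0, 100))
    def test_widening_the_window_never_shrinks_the_mask(self, lo, width, extra, seed):
        rng = np.random.default_rng(seed)
        vol = _volume(rng.uniform(0, 1200, size=(6, 6, 6)))
        small = threshold_volume(vol, SegmentationConfig(lo, lo + width))
        big = threshold_volume(vol, SegmentationConfig(lo - extra,
                                                       lo + width + extra))
        assert np.all(big.mask >= small.mask)


def _cyl_mask(shape, center_yz, radius_vox, spacing=0.05):
    iy, iz = np.meshgrid(np.arange(shape[1]), np.arange(shape[2]), indexing="ij")
    disc = (iy - center_yz[0]) ** 2 + (iz - center_yz[1]) ** 2 <= radius_vox**2
    m = np.broadcast_to(disc, shape).copy()
    return SegmentationMask(mask=m, spacing=(spacing,) * 3)


class TestRegionGrow:
    def test_single_component_is_identity(self):
        mask = _cyl_mask((20, 16, 16), (8, 8), 4)
        cfg = SegmentationConfig(seeds=[(10, 8, 8)])
        out = region_grow(mask, cfg)
        assert np.array_equal(out.mask, mask.mask)

    def test_disjoint_noise_blob_is_removed(self):
        mask = _cyl_mask((20, 24, 24), (8, 8), 4)
        blob = np.zeros_like(mask.mask)
        blob[2:5, 18:21, 18:21] = True  # 27 disconnected voxels
        combined = SegmentationMask(mask=mask.mask | blob, spacing=mask.spacing)
        out = region_grow(combined, SegmentationConfig(seeds=[(10, 8, 8)]))
        assert out.voxel_count == mask.voxel_count

    def test_two_seeds_keep_two_tubes(self):
        a = _cyl_mask((20, 30, 16), (6, 8), 3)
        b = _cyl_mask((20, 30, 16), (22, 8), 3)
        both = SegmentationMask(mask=a.mask | b.mask, spacing=a.spacing)
        out = region_grow(both, SegmentationConfig(seeds=[(5, 6, 8), (5, 22, 8)]))
        # oracle: brute-force connected-component labeling
        labels, n = ndimage.label(both.mask)
        assert n == 2
        assert out.voxel_count == both.voxel_count

    def test_seed_outside_mask_raises_naming_the_seed(self):
        mask = _cyl_mask((10, 12, 12), (6, 6), 3)
        with pytest.raises(ValueError, match=r"\(0, 0, 0\)"):
            region_grow(mask, SegmentationConfig(seeds=[(0, 0, 0)]))

    def test_subset_and_idempotent(self):
        # region growing only removes voxels, and applying it twice is a no-op
        a = _cyl_mask((10, 20, 12), (5, 6), 3)
        blob = np.zeros_like(a.mask)
        blob[1:3, 15:18, 1:4] = True
        combined = SegmentationMask(mask=a.mask | blob, spacing=a.spacing)
        cfg = SegmentationConfig(seeds=[(5, 5, 6)])
        once = region_grow(combined, cfg)
        twice = region_grow(once, cfg)
        assert np.array_equal(once.mask, twice.mask)
        assert np.all(combined.mask >= once.mask)

    def test_grown_mask_is_subset_of_threshold_output(self, segmented_mask,
                                                      ct_volume):
        thr = threshold_volume(ct_volume, SegmentationConfig())
        # cleanup may add hole-filled voxels; the grown-only stage is a subset,
        # so every segmented voxel outside the threshold mask came from filling
        added = segmented_mask.mask & ~thr.mask
        assert added.sum() < 0.01 * segmented_mask.voxel_count


class TestSurface:
    def test_voxelized_sphere_area(self):
        n, r = 28, 10
        g = np.arange(n) - (n - 1) / 2
        X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
        m = X**2 + Y**2 + Z**2 <= r**2
        mask = SegmentationMask(mask=m, spacing=(1.0, 1.0, 1.0))
        mesh = extract_surface(mask)
        assert mesh.is_watertight
        assert abs(mesh.area - 4 * np.pi * r**2) / (4 * np.pi * r**2) < 0.15

    def test_single_voxel_mask_gives_closed_voxel_scale_surface(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        mesh = extract_surface(SegmentationMask(mask=m, spacing=(0.1,) * 3),
                               smoothing_iterations=0)
        assert mesh.is_watertight
        assert mesh.extents.max() < 0.25

    def test_avf_mask_surface_is_genus_zero(self, segmented_mask):
        mesh = extract_surface(segmented_mask)
        assert mesh.is_watertight
        assert mesh.euler_number == 2

    def test_border_touching_mask_is_capped_and_flagged(self):
        m = np.zeros((10, 8, 8), bool)
        m[:, 2:6, 2:6] = True   # tube through the whole volume
        mesh = extract_surface(SegmentationMask(mask=m, spacing=(0.1,) * 3),
                               smoothing_iterations=0)
        assert mesh.is_watertight
        assert mesh.metadata["border_capped"]

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            extract_surface(SegmentationMask(mask=np.zeros((4, 4, 4), bool),
                                             spacing=(0.1,) * 3))


class TestInletExtension:
    def test_geometry_extension_lengthens_artery_by_exact_amount(self):
        geom = make_straight_tube(0.5, 4.0)
        x = np.linspace(-3.9, 3.9, 7)
        inlet_extension(geom, 2.0)
        lo, hi = geom.branches["proximal_artery"].u_range
        assert lo == pytest.approx(-4.0)
        assert geom.contains(np.array([[3.9, 0, 0], [-3.9, 0, 0]])).all()
        assert not geom.contains(np.array([[4.1, 0, 0]])).any()

    def test_zero_extension_is_identity(self):
        geom = make_straight_tube(0.5, 4.0)
        assert inlet_extension(geom, 0.0) is geom
        assert geom.inlet_extension_length == 0.0

    def test_surface_extension_adds_cylindrical_wall_area(self):
        D, L, ext = 0.5, 3.0, 2.0
        geom = make_straight_tube(D, L, resolution=0.03)
        img = rasterize_to_ct(geom, noise_sd=0.0, seed=0, spacing=0.03)
        mask = threshold_volume(img, SegmentationConfig())
        mesh = extract_surface(mask, smoothing_iterations=0)
        # drop the end caps so the tube has open rims to extrude
        keep = np.abs(mesh.triangles_center[:, 0]) < L / 2 - 0.05
        import trimesh
        tube = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces[keep],
                               process=True)
        extended = inlet_extension(tube, ext)
        added = extended.area - tube.area
        expected = 2 * np.pi * (D / 2) * ext * 2  # two ends
        assert abs(added - expected) / expected < 0.05
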
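"""Centerline extraction, diameter profiles, remodeling statistics, resistance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avf_hemoflow.segmentation import SegmentationMask
from avf_hemoflow.vessel_geometry import (DiameterProfile, extract_centerline,
                                          diameter_profile, percent_change,
                                          poiseuille_resistance, segment_stats)

VOX = 0.05


def _mask_from_indicator(fn, lo, hi, spacing=VOX):
    # voxel centres on exact multiples of the spacing (0 is a centre), with
    # fixture radii chosen mid-cell so surfaces never graze a voxel centre:
    # this keeps symmetric shapes voxelizing symmetrically
    axes = [np.arange(round(lo[a] / spacing), round(hi[a] / spacing) + 1)
            * spacing for a in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    return SegmentationMask(mask=fn(X, Y, Z), spacing=(spacing,) * 3,
                            origin=(axes[0][0], axes[1][0], axes[2][0]))


@pytest.fixture(scope="module")
def cylinder_mask():
    R, L = 0.28, 4.0   # boundary falls mid-cell on the 0.05 mm grid
    return _mask_from_indicator(lambda x, y, z: (y**2 + z**2 < R**2)
                                & (np.abs(x) < L / 2),
                                (-2.2, -0.5, -0.5), (2.2, 0.5, 0.5)), R, L


class TestCenterline:
    def test_cylinder_axis_recovered_within_half_voxel(self, cylinder_mask):
        mask, R, L = cylinder_mask
        cl = extract_centerline(mask)
        (name, br), = cl.branches.items()
        off_axis = np.hypot(br.points[:, 1], br.points[:, 2])
        assert off_axis.max() < 0.5 * VOX + 1e-9
        interior = np.abs(br.points[:, 0]) < L / 2 - 2 * R
        assert np.abs(br.inscribed_radius[interior] - R).max() < 0.5 * VOX

    def test_quarter_torus_arclength_within_two_percent(self):
        Rmaj, r = 2.0, 0.28

        def torus(x, y, z):
            ang = np.arctan2(y, x)
            return ((np.hypot(x, y) - Rmaj) ** 2 + z**2 < r**2) \
                & (ang > 0) & (ang < np.pi / 2)

        mask = _mask_from_indicator(torus, (-0.5, -0.5, -0.4), (2.6, 2.6, 0.4))
        cl = extract_centerline(mask)
        (name, br), = cl.branches.items()
        length = np.abs(br.arclength).max()
        expected = Rmaj * np.pi / 2
        assert abs(length - expected) / expected < 0.02

    def test_avf_mask_decomposes_into_four_labeled_branches(self, mask_centerline):
        assert set(mask_centerline.branches) == {
            "proximal_artery", "distal_artery", "fistula", "vein"}
        assert mask_centerline.junction is not None
        # the medial-axis junction of a Y sits up to ~one parent radius into
        # the daughter branch; require it within that zone of the anastomosis
        assert np.linalg.norm(mask_centerline.junction) < 0.5
        # sign convention: arteries negative, fistula/vein positive
        assert mask_centerline.branches["proximal_artery"].arclength.min() < 0
        assert mask_centerline.branches["fistula"].arclength.max() > 0

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            extract_centerline(SegmentationMask(mask=np.zeros((4, 4, 4), bool),
                                                spacing=(0.1,) * 3))


class TestDiameterProfile:
    def test_cylinder_profile_constant_within_a_voxel(self, cylinder_mask):
        mask, R, L = cylinder_mask
        cl = extract_centerline(mask)
        prof = diameter_profile(cl, mask, step=0.2)
        # for an unbranched path arclength runs 0..L from one tube end; skip
        # the capped ends where the section plane leaves the lumen
        s = np.abs(prof.arclength)
        interior = (s > 3 * R) & (s < s.max() - 3 * R)
        assert np.abs(prof.diameter[interior] - 2 * R).max() < VOX

    def test_elliptical_section_gives_equivalent_circle_diameter(self):
        a, b = 0.315, 0.165   # semi-axis boundaries mid-cell on the 0.03 grid
        mask = _mask_from_indicator(
            lambda x, y, z: ((y / a) ** 2 + (z / b) ** 2 < 1) & (np.abs(x) < 1.5),
            (-1.6, -0.45, -0.3), (1.6, 0.45, 0.3), spacing=0.03)
        cl = extract_centerline(mask)
        prof = diameter_profile(cl, mask, step=0.2)
        s = np.abs(prof.arclength)
        interior = (s > 0.7) & (s < s.max() - 0.7)
        expected = 2 * np.sqrt(a * b)      # area pi a b -> D = 2 sqrt(ab)
        assert np.abs(prof.diameter[interior] - expected).max() < 0.03

    def test_analytic_geometry_route_returns_ground_truth(self, day7_geometry):
        cl = extract_centerline(day7_geometry)
        prof = diameter_profile(cl, day7_geometry, step=0.05)
        fist = prof.select("fistula")
        expected = day7_geometry.params.fistula_vein_diameter(fist.arclength)
        assert np.allclose(fist.diameter, expected)

    def test_area_diameter_consistency(self, day7_geometry):
        cl = extract_centerline(day7_geometry)
        prof = diameter_profile(cl, day7_geometry, step=0.1)
        assert np.allclose(prof.area, np.pi * prof.diameter**2 / 4)


class TestRoundTrip:
    def test_segmentation_recovers_ground_truth_within_one_voxel(
            self, mask_diameter_profile, day7_geometry, ct_volume,
            junction_exclusion):
        """Rasterize (noisy) -> segment -> centerline -> D(s) vs analytic truth.

        Checked at every fistula/vein station at least 3 voxels wide and clear
        of the branch confluence, where a perpendicular cross-section is
        geometrically well defined.
        """
        vox = ct_volume.spacing[0]
        s_excl = junction_exclusion
        from conftest import profile_band_error
        prof = mask_diameter_profile
        sel = np.isin(prof.branch, ["fistula", "vein"])
        s = prof.arclength[sel]
        d = prof.diameter[sel]
        truth = day7_geometry.params.fistula_vein_diameter(s)
        ok = (truth >= 3 * vox) & (s > s_excl) & (s < 6.5)
        err = profile_band_error(
            s[ok], d[ok], day7_geometry.params.fistula_vein_diameter, vox)
        assert err.max() < vox

    def test_artery_diameter_recovered(self, mask_diameter_profile, day7_geometry):
        prof = mask_diameter_profile.select("proximal_artery")
        sel = (prof.arclength < -0.8) & (prof.arclength > -2.5)
        truth = day7_geometry.params.artery_diameter(prof.arclength[sel])
        assert np.abs(prof.diameter[sel] - truth).max() < 0.072


class TestSegmentStats:
    def test_constant_profile(self):
        s = np.linspace(0, 2, 21)
        prof = DiameterProfile(s, np.pi * 0.25**2 / 4 * np.ones_like(s) * 4,
                               np.full_like(s, 0.5), np.full(21, "f", object))
        st_ = segment_stats(prof, (0.0, 2.0))
        assert (st_.mean_diameter, st_.min_diameter, st_.max_diameter) == \
            (0.5, 0.5, 0.5)

    def test_day7_window_statistics_match_targets(self, day7_geometry):
        cl = extract_centerline(day7_geometry)
        prof = diameter_profile(cl, day7_geometry, step=0.005)
        fist = prof.select("fistula")
        stats2 = segment_stats(fist, (0.0, 2.0))
        assert stats2.mean_diameter == pytest.approx(0.74, abs=0.005)
        assert stats2.min_diameter == pytest.approx(0.46, abs=0.005)
        assert stats2.max_diameter == pytest.approx(0.95, abs=0.005)

    def test_window_nesting_monotonicity(self, day7_geometry):
        cl = extract_centerline(day7_geometry)
        prof = diameter_profile(cl, day7_geometry, step=0.01,
                                branches=["fistula"])
        s2 = segment_stats(prof, (0.0, 2.0))
        s4 = segment_stats(prof, (0.0, 4.0))
        assert s4.min_diameter <= s2.min_diameter
        assert s4.max_diameter >= s2.max_diameter

    def test_empty_window_raises(self, day7_geometry):
        cl = extract_centerline(day7_geometry)
        prof = diameter_profile(cl, day7_geometry, step=0.1)
        with pytest.raises(ValueError):
            segment_stats(prof, (50.0, 60.0))


class TestPercentChange:
    @pytest.mark.parametrize("before,after,expected", [
        (0.74, 0.58, -21.6),   # 2 mm fistula segment, day 7 -> 21
        (0.46, 0.31, -32.6),   # minimum stenosis diameter
        (1.07, 1.71, 59.8),    # vein maximum
    ])
    def test_reported_remodeling_percentages(self, before, after, expected):
        assert percent_change(before, after) == pytest.approx(expected, abs=0.05)

    def test_identity_is_zero(self):
        assert percent_change(0.5, 0.5) == 0.0

    def test_nonpositive_baseline_raises(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=st.floats(0.05, 10.0), b=st.floats(0.05, 10.0))
    def test_forward_and_backward_changes_compose_to_identity(self, a, b):
        p1 = percent_change(a, b)
        p2 = percent_change(b, a)
        assert (1 + p1 / 100) * (1 + p2 / 100) == pytest.approx(1.0, rel=1e-9)


def _uniform_profile(d, length=4.0, n=201):
    s = np.linspace(0, length, n)
    dia = np.full_like(s, d)
    return DiameterProfile(s, np.pi * dia**2 / 4, dia, np.full(n, "f", object))


class TestPoiseuilleResistance:
    MU = 4e-3

    def test_uniform_tube_closed_form(self):
        D, L = 0.5, 4.0
        R = poiseuille_resistance(_uniform_profile(D, L), self.MU)
        expected = 128 * self.MU * (L * 1e-3) / (np.pi * (D * 1e-3) ** 4)
        assert R == pytest.approx(expected, rel=1e-9)

    def test_diameter_doubling_divides_by_sixteen(self):
        r1 = poiseuille_resistance(_uniform_profile(0.4), self.MU)
        r2 = poiseuille_resistance(_uniform_profile(0.8), self.MU)
        assert r1 / r2 == pytest.approx(16.0, rel=1e-9)

    def test_two_segment_tube_is_mean_of_closed_forms(self):
        D, L = 0.5, 4.0
        s = np.linspace(0, L, 4001)
        dia = np.where(s < L / 2, D, D / 2)
        prof = DiameterProfile(s, np.pi * dia**2 / 4, dia,
                               np.full_like(s, "f", dtype=object))
        R = poiseuille_resistance(prof, self.MU)
        runi = poiseuille_resistance(_uniform_profile(D, L), self.MU)
        # half the length at D, half at D/2 (16x): (1 + 16)/2 = 8.5x
        assert R / runi == pytest.approx(8.5, rel=0.01)

    def test_pointwise_widening_never_increases_resistance(self, day7_geometry):
        s = np.linspace(0, 4, 401)
        d = day7_geometry.params.fistula_vein_diameter(s)
        base = DiameterProfile(s, np.pi * d**2 / 4, d,
                               np.full_like(s, "f", dtype=object))
        wide_d = d * 1.1
        wide = DiameterProfile(s, np.pi * wide_d**2 / 4, wide_d,
                               np.full_like(s, "f", dtype=object))
        assert poiseuille_resistance(wide, self.MU) \
            <= poiseuille_resistance(base, self.MU)

    def test_day21_over_day7_ratio_is_large(self):
        """Late-stage stenosis multiplies the 4 mm segment resistance ~9-fold."""
        from avf_hemoflow.synthgen import AVFShapeParams
        s = np.linspace(0, 4, 2001)
        res = {}
        for name, p in [("d7", AVFShapeParams.day7()),
                        ("d21", AVFShapeParams.day21())]:
            d = p.fistula_vein_diameter(s)
            prof = DiameterProfile(s, np.pi * d**2 / 4, d,
                                   np.full_like(s, "f", dtype=object))
            res[name] = poiseuille_resistance(prof, self.MU)
        assert res["d21"] / res["d7"] > 4.0
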
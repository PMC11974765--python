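"""Shared fixtures: synthetic geometries, rasterized volumes, solver fields.

Heavy artifacts (CT rasterization + segmentation round-trip, the pulsatile
stenosed-fistula solve) are session-scoped so the morphometry, wall-metric and
acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from avf_hemoflow import segmentation as seg
from avf_hemoflow import synthgen, vessel_geometry
from avf_hemoflow.cfd.mesh import avf_path_mesh, tube_mesh
from avf_hemoflow.cfd.solver import BloodModel, SolverConfig, solve_pulsatile, solve_steady

VOXEL_MM = 0.072
CT_NOISE_SD = 30.0
CT_SEED = 20260107


def _junction_exclusion_mm(params, voxel: float = VOXEL_MM) -> float:
    """Arclength below which fistula cross-sections include the anastomosis.

    Near an end-to-side junction the two lumens are one connected cavity: a
    plane normal to the fistula axis also slices the arterial lumen until the
    tubes separate, roughly (R_artery + R_fistula)/sin(angle) from the origin.
    Measured diameters are only well defined beyond that zone.
    """
    import numpy as np
    r_art = 0.5 * params.artery_diameter_dist
    s2 = np.linspace(0.0, 2.0, 401)
    r_fist = 0.5 * float(params.fistula_vein_diameter(s2).max())
    return (r_art + r_fist) / np.sin(np.deg2rad(params.anastomosis_angle)) \
        + 5.0 * voxel


@pytest.fixture(scope="session")
def junction_exclusion(day7_params):
    return _junction_exclusion_mm(day7_params)


def profile_band_error(s, d, truth_fn, vox):
    """Max deviation of measured diameters from the one-voxel truth band.

    A measured profile carries ~one-voxel uncertainty both in diameter and in
    arclength registration (on steep stenosis flanks the two are
    indistinguishable), so each station is compared against the ground-truth
    envelope over s +- one voxel.
    """
    lo = np.array([truth_fn(np.linspace(si - vox, si + vox, 9)).min()
                   for si in s])
    hi = np.array([truth_fn(np.linspace(si - vox, si + vox, 9)).max()
                   for si in s])
    return np.maximum(np.maximum(lo - d, d - hi), 0.0)


@pytest.fixture(scope="session")
def day7_params():
    return synthgen.AVFShapeParams.day7()


@pytest.fixture(scope="session")
def day7_geometry(day7_params):
    return synthgen.make_avf_geometry(day7_params)


@pytest.fixture(scope="session")
def blood():
    return BloodModel()


@pytest.fixture(scope="session")
def ct_volume(day7_geometry):
    """Noisy contrast-CT-like rasterization of the day-7 AVF at 72 um voxels."""
    return synthgen.rasterize_to_ct(day7_geometry, noise_sd=CT_NOISE_SD,
                                    seed=CT_SEED, spacing=VOXEL_MM)


@pytest.fixture(scope="session")
def segmented_mask(ct_volume, day7_geometry):
    """Threshold + seeded region growing + cleanup of the noisy volume."""
    seed_pt = day7_geometry.branches["fistula"].points(np.array([2.8]))[0]
    ijk = tuple(np.round((seed_pt - np.asarray(ct_volume.origin))
                         / np.asarray(ct_volume.spacing)).astype(int))
    cfg = seg.SegmentationConfig(seeds=[ijk])
    mask = seg.threshold_volume(ct_volume, cfg)
    mask = seg.region_grow(mask, cfg)
    return seg.cleanup_mask(mask, cfg)


@pytest.fixture(scope="session")
def mask_centerline(segmented_mask, day7_geometry):
    hints = vessel_geometry.avf_endpoint_hints(day7_geometry)
    return vessel_geometry.extract_centerline(
        segmented_mask, endpoint_hints=hints,
        fistula_split=day7_geometry.params.fistula_length)


@pytest.fixture(scope="session")
def mask_diameter_profile(mask_centerline, segmented_mask):
    return vessel_geometry.diameter_profile(mask_centerline, segmented_mask,
                                            step=0.1)


# -- solver fixtures ---------------------------------------------------------

# Day-7 study conditions for the fistula-path simulations: the measured AVF
# flow (1.33 mL/min = 22.17 mm^3/s) at 450 beats/min with a pulsatile
# murine-arterial waveform (pulsatility index 1.5).
AVF_FLOW_MM3_S = 22.17
HEART_RATE = 450.0
PULSATILITY = 1.5


@pytest.fixture(scope="session")
def avf_mesh(day7_geometry):
    return avf_path_mesh(day7_geometry, ni=60, nj=16, s_range_mm=(0.0, 6.0))


@pytest.fixture(scope="session")
def steady_avf_field(avf_mesh, blood):
    return solve_steady(avf_mesh, blood, inlet_flow_mm3_s=AVF_FLOW_MM3_S)


@pytest.fixture(scope="session")
def pulsatile_avf_field(avf_mesh, blood, day7_geometry):
    area_in = np.pi * (0.5 * day7_geometry.flow_path_diameter(0.0)) ** 2
    vc_mean = 2.0 * AVF_FLOW_MM3_S / area_in
    wf = synthgen.make_waveform(vc_mean, PULSATILITY, heart_rate=HEART_RATE,
                                n_samples=128, shape="pulse")
    return solve_pulsatile(avf_mesh, blood, wf, SolverConfig(store_max=100))


@pytest.fixture(scope="session")
def poiseuille_field(blood):
    """Reference steady tube solve shared by validation and metric tests."""
    mesh = tube_mesh(0.25, length_mm=4.0, ni=40, nj=16)
    return solve_steady(mesh, blood, inlet_flow_mm3_s=10.0), 10.0, 0.25
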
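"""Synthetic inputs with known ground truth for the AVF hemodynamics pipeline.

Generates the three input classes the pipeline consumes, each with an exact
analytic ground truth attached:

* parametric end-to-side arteriovenous-fistula (AVF) lumen geometries —
  a carotid-like artery joined by a fistula/vein branch carrying a localized
  stenosis and downstream venous ballooning;
* contrast-CT-like image volumes rasterized from those geometries
  (lumen ~600 HU against a 0 HU background, optional Gaussian noise,
  72 um isotropic voxels by default);
* pulsatile centerline-velocity waveforms emulating PW-Doppler traces at a
  murine heart rate (~450 beats/min).

All interface lengths are millimetres and times seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import root

__all__ = [
    "InvalidGeometryError",
    "AVFShapeParams",
    "ImageVolume",
    "VelocityWaveform",
    "VesselGeometry",
    "make_avf_geometry",
    "rasterize_to_ct",
    "make_waveform",
    "calibrate_fistula_profile",
]


class InvalidGeometryError(ValueError):
    """Raised for degenerate shape parameters (overlapping branches, full occlusion...)."""


# ---------------------------------------------------------------------------
# Shape parameters
# ---------------------------------------------------------------------------

# Target segment statistics used to freeze the default profiles: equivalent
# lumen diameters (mm) of the murine AVF model at 7 and 21 days post-surgery,
# reported as mean (min - max) over the first 2 mm and 4 mm of fistula.
DAY7_TARGETS = {
    "artery_prox": (0.29, 0.23, 0.35),
    "artery_dist": (0.36, 0.27, 0.51),
    "avf_2mm": (0.74, 0.46, 0.95),
    "avf_4mm": (0.88, 0.46, 1.07),
}
DAY21_TARGETS = {
    "artery_prox": (0.39, 0.34, 0.54),
    "artery_dist": (0.46, 0.40, 0.52),
    "avf_2mm": (0.58, 0.31, 0.96),
    "avf_4mm": (0.86, 0.31, 1.71),
}


@dataclass(frozen=True)
class AVFShapeParams:
    """Parameters of the idealized end-to-side AVF lumen.

    The fistula/vein diameter profile D(s) (s = arclength from the anastomosis,
    mm) is a monotone-cubic baseline through a small set of knots, blended to
    ``fistula_diameter * (1 - stenosis_severity)`` inside a cosine-tapered
    stenosis window centred at ``stenosis_center_arclength``.  Defaults are
    calibrated so the day-7 segment statistics (mean/min/max diameter over the
    first 2 mm and 4 mm of fistula) match the study targets; see
    :func:`calibrate_fistula_profile`.
    """

    artery_diameter_prox: float = 0.29     # mm, proximal carotid
    artery_diameter_dist: float = 0.36     # mm, distal carotid
    fistula_diameter: float = 0.74         # mm, reference (2 mm segment mean)
    vein_diameter: float = 1.07            # mm, diameter at the fistula/vein transition
    stenosis_center_arclength: float = 1.4  # mm from anastomosis
    stenosis_severity: float = 1.0 - 0.46 / 0.74   # 1 - D_min/D_ref
    stenosis_length: float = 1.2           # mm, full width of the cosine taper
    anastomosis_angle: float = 60.0        # degrees between artery axis and fistula
    fistula_length: float = 4.0            # mm of fistula from the anastomosis
    vein_balloon_factor: float = 1.0       # outlet diameter / vein_diameter
    # baseline-profile knots (calibrated; see calibrate_fistula_profile)
    fistula_entry_diameter: float = 0.58076  # mm at s = 0 (calibrated)
    fistula_peak_diameter: float = 0.95    # mm local maximum before the stenosis
    fistula_peak_arclength: float = 0.9    # mm
    fistula_dip_diameter: float = 0.95     # mm knot between peak and recovery
    fistula_dip_arclength: float = 2.0     # mm
    fistula_recovery_diameter: float = 0.98066  # mm post-stenotic recovery (calibrated)
    fistula_recovery_arclength: float = 2.4  # mm
    artery_half_length: float = 3.0        # mm of artery on each side of the junction
    vein_length: float = 3.0               # mm of vein past the fistula segment

    def __post_init__(self) -> None:
        for name in ("artery_diameter_prox", "artery_diameter_dist",
                     "fistula_diameter", "vein_diameter"):
            if getattr(self, name) <= 0:
                raise InvalidGeometryError(f"{name} must be > 0")
        if not 0.0 <= self.stenosis_severity < 1.0:
            raise InvalidGeometryError("stenosis_severity must lie in [0, 1)")
        half = 0.5 * self.stenosis_length
        if not (self.stenosis_center_arclength - half >= 0.0
                and self.stenosis_center_arclength + half <= self.fistula_length):
            raise InvalidGeometryError("stenosis window must lie within the fistula segment")
        if self.vein_balloon_factor < 1.0:
            raise InvalidGeometryError("vein_balloon_factor must be >= 1")
        if not 15.0 <= self.anastomosis_angle <= 165.0:
            raise InvalidGeometryError(
                "anastomosis_angle too shallow: fistula would overlap the artery")

    # -- derived quantities -------------------------------------------------

    @property
    def min_stenosis_diameter(self) -> float:
        """Ground-truth minimum fistula diameter, mm."""
        return self.fistula_diameter * (1.0 - self.stenosis_severity)

    @property
    def min_diameter(self) -> float:
        s = np.linspace(0.0, self.fistula_length + self.vein_length, 2001)
        return float(min(self.fistula_vein_diameter(s).min(),
                         self.artery_diameter(np.linspace(-self.artery_half_length,
                                                          self.artery_half_length, 201)).min()))

    def _baseline(self) -> PchipInterpolator:
        lf, lv = self.fistula_length, self.vein_length
        knots_s = [0.0, self.fistula_peak_arclength, self.fistula_dip_arclength,
                   self.fistula_recovery_arclength, lf, lf + lv]
        knots_d = [self.fistula_entry_diameter, self.fistula_peak_diameter,
                   self.fistula_dip_diameter, self.fistula_recovery_diameter,
                   self.vein_diameter, self.vein_diameter * self.vein_balloon_factor]
        return PchipInterpolator(knots_s, knots_d)

    def fistula_vein_diameter(self, s):
        """Analytic diameter D(s), mm, along the fistula/vein branch (s >= 0, mm)."""
        s = np.asarray(s, dtype=float)
        base = self._baseline()(np.clip(s, 0.0, self.fistula_length + self.vein_length))
        x = (s - self.stenosis_center_arclength) / self.stenosis_length  # +-0.5 window
        m = np.where(np.abs(x) < 0.5, np.cos(np.pi * x) ** 2, 0.0)
        return (1.0 - m) * base + m * self.min_stenosis_diameter

    def artery_diameter(self, x):
        """Analytic artery diameter, mm, vs signed axial position x (mm, junction at 0)."""
        x = np.asarray(x, dtype=float)
        t = 0.5 * (1.0 + np.tanh(x / 0.8))
        return self.artery_diameter_prox + (self.artery_diameter_dist
                                            - self.artery_diameter_prox) * t

    # -- canonical parameter sets -------------------------------------------

    @classmethod
    def day7(cls) -> "AVFShapeParams":
        """Day-7-scale model (defaults): localized stenosis close to the anastomosis."""
        return cls()

    @classmethod
    def day21(cls) -> "AVFShapeParams":
        """Day-21-scale model: elongated stenosis shifted downstream, dilated vein."""
        return cls(
            artery_diameter_prox=0.39,
            artery_diameter_dist=0.46,
            fistula_diameter=0.58,
            vein_diameter=1.71,
            stenosis_center_arclength=1.8,
            stenosis_severity=1.0 - 0.31 / 0.58,
            stenosis_length=1.4,
            fistula_entry_diameter=0.63388,
            fistula_peak_diameter=0.96,
            fistula_peak_arclength=0.35,
            fistula_dip_diameter=0.50,
            fistula_dip_arclength=0.9,
            fistula_recovery_diameter=0.89052,
            fistula_recovery_arclength=2.6,
        )


def calibrate_fistula_profile(params: AVFShapeParams,
                              mean_2mm: float, mean_4mm: float) -> AVFShapeParams:
    """Adjust the entry/recovery knots so segment-mean diameters hit targets.

    Solves for ``fistula_entry_diameter`` and ``fistula_recovery_diameter`` such
    that the analytic D(s) averages to ``mean_2mm`` over (0, 2) mm and
    ``mean_4mm`` over (0, 4) mm.  Deterministic (no randomness); used once to
    freeze the default parameter sets.
    """
    s2 = np.linspace(0.0, 2.0, 2001)
    s4 = np.linspace(0.0, 4.0, 4001)

    def resid(v):
        p = replace(params, fistula_entry_diameter=float(v[0]),
                    fistula_recovery_diameter=float(v[1]))
        return [np.trapezoid(p.fistula_vein_diameter(s2), s2) / 2.0 - mean_2mm,
                np.trapezoid(p.fistula_vein_diameter(s4), s4) / 4.0 - mean_4mm]

    sol = root(resid, x0=[params.fistula_entry_diameter, params.fistula_recovery_diameter])
    if not sol.success or np.any(sol.x <= 0):
        raise InvalidGeometryError("fistula profile calibration failed: " + sol.message)
    return replace(params, fistula_entry_diameter=float(sol.x[0]),
                   fistula_recovery_diameter=float(sol.x[1]))


# ---------------------------------------------------------------------------
# Image volume
# ---------------------------------------------------------------------------

@dataclass
class ImageVolume:
    """3-D scalar intensity grid in HU-like units with voxel spacing metadata."""

    intensities: np.ndarray              # (nx, ny, nz), axis order = (x, y, z)
    spacing: tuple[float, float, float]  # mm per voxel, per axis
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm, centre of voxel [0,0,0]
    axis_order: str = "xyz"
    warnings_: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3-D array")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on all axes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def voxel_centers_1d(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
                     for a in range(3))


# ---------------------------------------------------------------------------
# Velocity waveform
# ---------------------------------------------------------------------------

@dataclass
class VelocityWaveform:
    """Periodic centerline (peak) velocity trace over one cardiac cycle.

    ``times`` spans exactly one period (endpoints included) and the waveform is
    treated as T-periodic; ``velocities`` are peak/centerline values in mm/s as
    read from a PW-Doppler trace.
    """

    times: np.ndarray       # s, strictly increasing, times[0]=0, times[-1]=period
    velocities: np.ndarray  # mm/s
    period: float           # s
    heart_rate: float       # min^-1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("need at least two time samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.isclose(self.period, 60.0 / self.heart_rate, rtol=1e-6):
            raise ValueError("period must equal 60/heart_rate")
        if not np.isclose(self.times[-1] - self.times[0], self.period, rtol=1e-9):
            raise ValueError("times must span exactly one period")
        if not np.isclose(self.velocities[0], self.velocities[-1],
                          rtol=1e-6, atol=1e-9 * max(1.0, np.abs(self.velocities).max())):
            raise ValueError("waveform must be periodic: v(0) != v(T)")

    def mean(self) -> float:
        """Time-mean velocity over one period (trapezoid on stored samples), mm/s."""
        return float(np.trapezoid(self.velocities, self.times) / self.period)

    def __call__(self, t):
        """Periodic linear interpolation, mm/s."""
        tt = np.mod(np.asarray(t, dtype=float) - self.times[0], self.period) + self.times[0]
        return np.interp(tt, self.times, self.velocities)


def make_waveform(mean_velocity: float, pulsatility_index: float,
                  heart_rate: float = 450.0, n_samples: int = 64,
                  shape: str = "sinusoid") -> VelocityWaveform:
    """Build a periodic velocity waveform with prescribed time-mean and pulsatility.

    Parameters
    ----------
    mean_velocity : mm/s, target time-mean (> 0).
    pulsatility_index : (max - min)/mean of the generated trace.
    heart_rate : beats/min; the period is 60/heart_rate seconds.
    n_samples : number of samples (>= 16); endpoints share the periodic value.
    shape : "sinusoid" for ``mean (1 + PI/2 sin)``, or "pulse" for a skewed
        systolic peak (von-Mises-like bump on a diastolic baseline), closer to
        an arterial Doppler trace.

    Both shapes are non-reversing families: parameters producing negative
    velocities raise ``ValueError``.
    """
    if mean_velocity <= 0:
        raise ValueError("mean_velocity must be > 0")
    if n_samples < 16:
        raise ValueError("n_samples must be >= 16")
    if pulsatility_index < 0:
        raise ValueError("pulsatility_index must be >= 0")
    period = 60.0 / heart_rate
    t = np.linspace(0.0, period, n_samples + 1)
    if shape == "sinusoid":
        raw = np.sin(2.0 * np.pi * t / period)
        span = raw.max() - raw.min()   # exactly 2 when n_samples % 4 == 0
        v = mean_velocity * (1.0 + pulsatility_index * raw / span)
    elif shape == "pulse":
        kappa = 8.0  # sharpness of the systolic peak
        w = np.exp(kappa * (np.cos(2.0 * np.pi * (t / period - 0.2)) - 1.0))
        wbar = np.trapezoid(w, t) / period
        span = w.max() - w.min()
        if pulsatility_index == 0:
            v = np.full_like(t, mean_velocity)
        else:
            c1 = pulsatility_index * mean_velocity / span
            c0 = mean_velocity - c1 * wbar
            v = c0 + c1 * w
    else:
        raise ValueError(f"unknown waveform shape {shape!r}")
    if v.min() < 0:
        raise ValueError("pulsatility_index produces negative velocities "
                         "for a non-reversing waveform shape")
    v[-1] = v[0]
    return VelocityWaveform(times=t, velocities=v, period=period, heart_rate=heart_rate)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@dataclass
class Branch:
    """A straight tube branch with analytic centerline and diameter function."""

    name: str
    start: np.ndarray       # mm, point at local parameter u = 0
    direction: np.ndarray   # unit vector
    u_range: tuple[float, float]   # local parameter range (mm along axis)
    diameter_of_u: Callable[[np.ndarray], np.ndarray]
    arclength_of_u: Callable[[np.ndarray], np.ndarray]  # signed s per plot convention

    def points(self, u):
        u = np.atleast_1d(np.asarray(u, dtype=float))
        return self.start[None, :] + u[:, None] * self.direction[None, :]


class VesselGeometry:
    """Discretized AVF lumen with exact analytic centerline ground truth.

    Holds the construction parameters, the analytic centerline/diameter
    functions for the four branches (proximal artery, distal artery, fistula,
    vein), an implicit inside test, and — lazily — a watertight triangulated
    surface with labeled inlet/outlet/wall patches.

    Arclength convention: the anastomosis is s = 0; arteries carry negative s
    (upstream), fistula and vein positive s.
    """

    BRANCH_NAMES = ("proximal_artery", "distal_artery", "fistula", "vein")

    def __init__(self, params: AVFShapeParams, resolution: float = 0.04):
        if resolution <= 0:
            raise InvalidGeometryError("resolution must be > 0")
        self.params = params
        self.resolution = float(resolution)
        if params.min_diameter / resolution < 6.0:
            raise InvalidGeometryError(
                f"resolution {resolution} mm too coarse: fewer than 6 elements "
                f"across the minimum diameter {params.min_diameter:.3f} mm")
        th = np.deg2rad(params.anastomosis_angle)
        self._fv_dir = np.array([np.cos(th), np.sin(th), 0.0])
        la = params.artery_half_length
        lf, lv = params.fistula_length, params.vein_length
        self.branches = {
            "proximal_artery": Branch(
                "proximal_artery", np.zeros(3), np.array([1.0, 0, 0]), (-la, 0.0),
                diameter_of_u=params.artery_diameter,
                arclength_of_u=lambda u: np.asarray(u, float)),       # negative upstream
            "distal_artery": Branch(
                "distal_artery", np.zeros(3), np.array([1.0, 0, 0]), (0.0, la),
                diameter_of_u=params.artery_diameter,
                arclength_of_u=lambda u: -np.asarray(u, float)),      # negative upstream
            "fistula": Branch(
                "fistula", np.zeros(3), self._fv_dir, (0.0, lf),
                diameter_of_u=params.fistula_vein_diameter,
                arclength_of_u=lambda u: np.asarray(u, float)),
            "vein": Branch(
                "vein", np.zeros(3), self._fv_dir, (lf, lf + lv),
                diameter_of_u=params.fistula_vein_diameter,
                arclength_of_u=lambda u: np.asarray(u, float)),
        }
        self._surface = None
        self._patches = None
        self.inlet_extension_length = 0.0

    # -- analytic ground truth ----------------------------------------------

    def diameter(self, branch: str, s):
        """Ground-truth diameter (mm) at signed arclength s on a branch."""
        b = self.branches[branch]
        s = np.asarray(s, dtype=float)
        if branch == "distal_artery":
            u = -s
        else:
            u = s
        return b.diameter_of_u(u)

    def centerline_points(self, branch: str, n: int = 200):
        """(points, signed arclength, diameter) samples of a branch centerline."""
        b = self.branches[branch]
        u = np.linspace(b.u_range[0], b.u_range[1], n)
        return b.points(u), b.arclength_of_u(u), b.diameter_of_u(u)

    def flow_path_diameter(self, s):
        """Diameter along the proximal-artery -> fistula -> vein flow path.

        s < 0 follows the artery, s >= 0 the fistula/vein branch; a cosine
        blend over |s| < 0.25 mm bridges the step at the anastomosis so the
        idealized axisymmetric solver geometry stays smooth.
        """
        s = np.asarray(s, dtype=float)
        da = self.params.artery_diameter(s)
        dfv = self.params.fistula_vein_diameter(np.clip(s, 0.0, None))
        half = 0.25
        w = np.clip((s + half) / (2 * half), 0.0, 1.0)
        w = 0.5 * (1.0 - np.cos(np.pi * w))
        return (1.0 - w) * da + w * dfv

    # -- implicit inside test -------------------------------------------------

    def _tube_sdf(self, pts, axis_dir, u_lo, u_hi, dia_of_u):
        u = pts @ axis_dir
        radial = np.linalg.norm(pts - np.outer(u, axis_dir), axis=-1)
        uc = np.clip(u, u_lo, u_hi)
        f_rad = radial - 0.5 * dia_of_u(uc)
        f_cap = np.maximum(u_lo - u, u - u_hi)
        return np.maximum(f_rad, f_cap)

    #: soft-union rounding scale (mm); exact min() away from the junction crease
    UNION_SMOOTH_MM = 0.03

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        """Approximate signed distance (mm, negative inside) to the lumen union.

        The two tube fields are combined with a smooth minimum: a sharp min()
        leaves a tangential crease at the anastomosis that can pinch the
        extracted iso-surface into a non-manifold edge.  The rounding only
        acts where the fields are within ~UNION_SMOOTH_MM of each other.
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        p = self.params
        ext = self.inlet_extension_length
        f_art = self._tube_sdf(pts, np.array([1.0, 0, 0]),
                               -p.artery_half_length - ext, p.artery_half_length + ext,
                               p.artery_diameter)
        f_fv = self._tube_sdf(pts, self._fv_dir, 0.0,
                              p.fistula_length + p.vein_length,
                              p.fistula_vein_diameter)
        k = self.UNION_SMOOTH_MM
        lo = np.minimum(f_art, f_fv)
        hi = np.maximum(f_art, f_fv)
        # log-sum-exp soft minimum, numerically exact once hi - lo >> k
        return lo - k * np.log1p(np.exp(-(hi - lo) / k))

    def contains(self, pts: np.ndarray) -> np.ndarray:
        return self.signed_distance(pts) < 0.0

    # -- surface -------------------------------------------------------------

    def surface(self):
        """Watertight triangulated lumen surface (trimesh.Trimesh, mm units)."""
        if self._surface is None:
            self._build_surface()
        return self._surface

    def patches(self) -> dict[str, np.ndarray]:
        """Face-index arrays for 'proximal_artery_inlet', 'distal_artery_inlet',
        'venous_outlet' and 'wall' patches of the surface."""
        if self._patches is None:
            self._build_surface()
        return self._patches

    def _build_surface(self):
        import trimesh
        from skimage.measure import marching_cubes

        p = self.params
        h = self.resolution
        ext = self.inlet_extension_length
        la = p.artery_half_length + ext
        end_fv = (p.fistula_length + p.vein_length)
        rmax = 0.5 * max(p.vein_diameter * p.vein_balloon_factor,
                         p.artery_diameter_dist, p.fistula_peak_diameter)
        lo = np.minimum(np.array([-la, 0.0, 0.0]), end_fv * self._fv_dir) - 2 * rmax
        hi = np.maximum(np.array([la, 0.0, 0.0]), end_fv * self._fv_dir) + 2 * rmax
        # sub-voxel offset so no grid plane coincides with the geometry's
        # mirror plane (z = 0), where marching-cubes saddles can pinch
        lo = lo + h * np.array([0.1291, 0.0713, 0.3173])
        ns = np.maximum(((hi - lo) / h).astype(int) + 3, 8)
        xs = [lo[a] + h * np.arange(ns[a]) for a in range(3)]
        grid = np.stack(np.meshgrid(*xs, indexing="ij"), axis=-1)
        f = self.signed_distance(grid.reshape(-1, 3)).reshape(grid.shape[:3])
        verts, faces, _, _ = marching_cubes(f, level=0.0, spacing=(h, h, h))
        verts += lo
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
        trimesh.repair.fix_normals(mesh)
        self._surface = mesh
        # label end-cap patches by proximity to the analytic end planes
        cent = mesh.triangles_center
        tol = 1.2 * h
        r_art = np.linalg.norm(cent[:, 1:], axis=1)
        u_fv = cent @ self._fv_dir
        r_fv = np.linalg.norm(cent - np.outer(u_fv, self._fv_dir), axis=1)
        prox = (np.abs(cent[:, 0] + la) < tol) \
            & (r_art < 0.5 * p.artery_diameter_prox + tol)
        dist = (np.abs(cent[:, 0] - la) < tol) \
            & (r_art < 0.5 * p.artery_diameter_dist + tol)
        vout = (np.abs(u_fv - end_fv) < tol) \
            & (r_fv < 0.5 * p.vein_diameter * p.vein_balloon_factor + tol)
        wall = ~(prox | dist | vout)
        self._patches = {
            "proximal_artery_inlet": np.flatnonzero(prox),
            "distal_artery_inlet": np.flatnonzero(dist),
            "venous_outlet": np.flatnonzero(vout),
            "wall": np.flatnonzero(wall),
        }


def make_avf_geometry(params: AVFShapeParams, resolution: float = 0.04) -> VesselGeometry:
    """Construct the parametric AVF lumen with exact analytic ground truth.

    ``resolution`` (mm) controls the triangulated-surface sampling; the
    analytic centerline and D(s) carried by the result are exact regardless.
    Raises :class:`InvalidGeometryError` for degenerate parameters.
    """
    return VesselGeometry(params, resolution=resolution)


def make_straight_tube(diameter: float, length: float,
                       resolution: float = 0.04) -> VesselGeometry:
    """Single straight tube (no fistula, no stenosis) for validation fixtures."""
    params = AVFShapeParams(
        artery_diameter_prox=diameter, artery_diameter_dist=diameter,
        fistula_diameter=diameter, vein_diameter=diameter,
        stenosis_severity=0.0, stenosis_center_arclength=1.0, stenosis_length=1.0,
        fistula_entry_diameter=diameter, fistula_peak_diameter=diameter,
        fistula_dip_diameter=diameter, fistula_recovery_diameter=diameter,
        artery_half_length=length / 2.0, anastomosis_angle=90.0,
    )
    geom = VesselGeometry(params, resolution=resolution)
    # suppress the fistula branch: keep only the artery tube
    geom.branches = {k: v for k, v in geom.branches.items()
                     if k in ("proximal_artery", "distal_artery")}

    def _sdf(pts):  # respects inlet extensions applied later
        ext = geom.inlet_extension_length
        return geom._tube_sdf(np.atleast_2d(np.asarray(pts, float)),
                              np.array([1.0, 0, 0]),
                              -length / 2.0 - ext, length / 2.0 + ext,
                              params.artery_diameter)

    geom.signed_distance = _sdf  # type: ignore[method-assign]
    return geom


# ---------------------------------------------------------------------------
# CT rasterization
# ---------------------------------------------------------------------------

def rasterize_to_ct(geometry: VesselGeometry, lumen_hu: float = 600.0,
                    background_hu: float = 0.0, noise_sd: float = 0.0,
                    seed: int = 0, spacing: float = 0.072,
                    margin: float = 0.3) -> ImageVolume:
    """Rasterize a lumen geometry into a contrast-CT-like image volume.

    Voxels whose centers lie inside the lumen take ``lumen_hu`` (default 600 HU,
    mid-window of a 300-1000 HU contrast segmentation window), all others
    ``background_hu``; i.i.d. Gaussian noise of ``noise_sd`` HU is added with
    the given seed.  A warning is attached (and emitted) when the minimum
    lumen diameter spans fewer than 3 voxels.
    """
    if lumen_hu <= background_hu:
        raise ValueError("lumen_hu must exceed background_hu")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    p = geometry.params
    ext = geometry.inlet_extension_length
    la = p.artery_half_length + ext
    end_fv = (p.fistula_length + p.vein_length)
    rmax = 0.5 * max(p.vein_diameter * p.vein_balloon_factor,
                     p.artery_diameter_dist, p.fistula_peak_diameter,
                     p.fistula_diameter)
    fv_end = end_fv * geometry._fv_dir if "fistula" in geometry.branches else np.zeros(3)
    lo = np.minimum(np.array([-la, 0.0, 0.0]), fv_end) - rmax - margin
    hi = np.maximum(np.array([la, 0.0, 0.0]), fv_end) + rmax + margin
    ns = np.ceil((hi - lo) / spacing).astype(int) + 1
    xs = [lo[a] + spacing * np.arange(ns[a]) for a in range(3)]
    grid = np.stack(np.meshgrid(*xs, indexing="ij"), axis=-1)
    inside = geometry.contains(grid.reshape(-1, 3)).reshape(grid.shape[:3])
    vol = np.where(inside, float(lumen_hu), float(background_hu))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vol = vol + rng.normal(0.0, noise_sd, size=vol.shape)
    img = ImageVolume(intensities=vol, spacing=(spacing,) * 3,
                      origin=tuple(lo))
    min_d = p.min_diameter
    if min_d < 3.0 * spacing:
        msg = (f"minimum lumen diameter {min_d:.3f} mm spans fewer than 3 voxels "
               f"at spacing {spacing} mm; segmentation will not resolve it")
        img.warnings_.append(msg)
        warnings.warn(msg)
    return img
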
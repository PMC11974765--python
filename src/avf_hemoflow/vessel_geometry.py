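"""Centerline extraction and vessel morphometry.

Produces diameter profiles along arclength, per-segment statistics (mean /
min / max over a window, the form used for temporal remodeling tables),
percent-change comparisons between timepoints, and the Poiseuille flow
resistance of a vessel segment.

Conventions
-----------
* "Diameter" is the equivalent-circle diameter of the lumen cross-section
  taken perpendicular to the local centerline tangent: D = 2 sqrt(A/pi).
* Arclength is measured from the anastomosis (branch junction): negative
  upstream into the arteries, positive into the fistula and vein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import SegmentationMask
from .synthgen import VesselGeometry

__all__ = [
    "CenterlineBranch",
    "Centerline",
    "DiameterProfile",
    "SegmentStats",
    "extract_centerline",
    "diameter_profile",
    "segment_stats",
    "percent_change",
    "poiseuille_resistance",
]


@dataclass
class CenterlineBranch:
    points: np.ndarray            # (n, 3) mm, ordered junction -> endpoint
    arclength: np.ndarray         # (n,) mm, signed (negative = upstream artery)
    inscribed_radius: np.ndarray  # (n,) mm, distance to wall

    def __post_init__(self) -> None:
        d = np.abs(np.diff(self.arclength))
        if np.any(d <= 0):
            raise ValueError("arclength must be strictly monotonic along a branch")

    def tangent(self) -> np.ndarray:
        t = np.gradient(self.points, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    def point_at(self, s: float) -> np.ndarray:
        order = np.argsort(self.arclength)
        return np.array([np.interp(s, self.arclength[order], self.points[order, a])
                         for a in range(3)])


@dataclass
class Centerline:
    branches: dict[str, CenterlineBranch]
    junction: np.ndarray | None = None   # mm; anastomosis position, arclength origin


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def extract_centerline(source, endpoint_hints: dict[str, np.ndarray] | None = None,
                       fistula_split: float | None = None,
                       min_branch_voxels: int = 3,
                       smooth_window: int = 5) -> Centerline:
    """Extract branch centerlines from a lumen mask or an analytic geometry.

    For a :class:`SegmentationMask`, the mask is skeletonized, the skeleton is
    decomposed into endpoint-to-junction paths, each path is smoothed, snapped
    to the ridge scale of the interior distance transform (the inscribed radius
    is the distance-to-wall along the path) and extended to the mask boundary.
    Loopy (non-tree) skeletons raise ``ValueError``; branches shorter than
    ``min_branch_voxels`` are dropped with a warning.

    ``endpoint_hints`` maps branch labels to approximate endpoint positions
    (mm); unlabeled branches get ``branch_<i>``.  If a branch labeled ``vein``
    exists and ``fistula_split`` (mm) is given, it is split into ``fistula``
    (arclength < split) and ``vein``.

    For a :class:`~avf_hemoflow.synthgen.VesselGeometry` the exact analytic
    centerline is returned (no discretization involved).
    """
    if isinstance(source, VesselGeometry):
        return _centerline_from_geometry(source)
    if isinstance(source, SegmentationMask):
        return _centerline_from_mask(source, endpoint_hints, fistula_split,
                                     min_branch_voxels, smooth_window)
    raise TypeError("source must be a SegmentationMask or VesselGeometry")


def _centerline_from_geometry(geom: VesselGeometry, n: int = 400) -> Centerline:
    branches = {}
    for name in geom.branches:
        pts, s, dia = geom.centerline_points(name, n=n)
        order = np.argsort(np.abs(s))  # junction first
        branches[name] = CenterlineBranch(points=pts[order], arclength=s[order],
                                          inscribed_radius=0.5 * dia[order])
    return Centerline(branches=branches, junction=np.zeros(3))


def _neighbors_offsets() -> np.ndarray:
    off = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                    for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)])
    return off


def _centerline_from_mask(mask: SegmentationMask, endpoint_hints, fistula_split,
                          min_branch_voxels, smooth_window) -> Centerline:
    import networkx as nx
    from skimage.morphology import skeletonize

    if mask.empty:
        raise ValueError("cannot extract a centerline from an empty mask")
    spacing = np.asarray(mask.spacing)
    origin = np.asarray(mask.origin)
    edt = ndimage.distance_transform_edt(mask.mask, sampling=spacing)
    sk = skeletonize(mask.mask)
    idx = np.argwhere(sk)
    if len(idx) == 0:
        raise ValueError("skeletonization produced no voxels")
    node_id = {tuple(v): i for i, v in enumerate(idx)}
    G = nx.Graph()
    G.add_nodes_from(range(len(idx)))
    off = _neighbors_offsets()
    for i, v in enumerate(idx):
        for o in off:
            nb = tuple(v + o)
            j = node_id.get(nb)
            if j is not None and j > i:
                G.add_edge(i, j, weight=float(np.linalg.norm(o * spacing)))
    cycles = nx.cycle_basis(G)
    if cycles:
        # parasitic voxel-scale loops are a known thinning artifact near
        # junctions; break them on their longest edge (minimum spanning
        # tree).  Anatomically real loops are large and rejected.
        max_len = max(sum(G.edges[c[i], c[(i + 1) % len(c)]]["weight"]
                          for i in range(len(c))) for c in cycles)
        if max_len > 25.0 * float(spacing.min()):
            raise ValueError("skeleton contains loops: non-tubular topology")
        G = nx.minimum_spanning_tree(G, weight="weight")

    deg = dict(G.degree())
    endpoints = [n for n, d in deg.items() if d == 1]
    junctions = [n for n, d in deg.items() if d >= 3]
    if junctions:
        # collapse adjacent junction voxels to one representative
        Gj = G.subgraph(junctions)
        comp = max(nx.connected_components(Gj), key=len)
        j_star = min(comp)
        junction_xyz = origin + idx[j_star] * spacing
    else:
        j_star = endpoints[0] if endpoints else 0
        junction_xyz = None

    paths = []
    for e in endpoints:
        if e == j_star:
            continue
        path = nx.shortest_path(G, j_star, e, weight="weight")
        if len(path) < min_branch_voxels:
            warnings.warn(f"dropping skeleton branch with {len(path)} voxels")
            continue
        paths.append(path)

    branches: dict[str, CenterlineBranch] = {}
    used_labels = set()
    for bi, path in enumerate(paths):
        pts = origin + idx[path] * spacing
        pts = _edt_refine(pts, edt, spacing, origin)
        pts = _smooth_polyline(pts, smooth_window)
        pts = _extend_to_boundary(pts, mask, spacing, origin, end="tail")
        if junction_xyz is None and bi == 0:
            pts = _extend_to_boundary(pts, mask, spacing, origin, end="head")
        label = _match_label(pts[-1], endpoint_hints, used_labels) or f"branch_{bi}"
        used_labels.add(label)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        sign = -1.0 if "artery" in label else 1.0
        radius = _sample_edt(edt, pts, spacing, origin)
        branches[label] = CenterlineBranch(points=pts, arclength=sign * s,
                                           inscribed_radius=radius)

    _relocate_arclength_origin(branches)

    if fistula_split is not None and "vein" in branches:
        b = branches.pop("vein")
        pre = np.abs(b.arclength) < fistula_split
        if pre.sum() >= 2 and (~pre).sum() >= 2:
            branches["fistula"] = CenterlineBranch(
                points=b.points[pre], arclength=b.arclength[pre],
                inscribed_radius=b.inscribed_radius[pre])
            branches["vein"] = CenterlineBranch(
                points=b.points[~pre], arclength=b.arclength[~pre],
                inscribed_radius=b.inscribed_radius[~pre])
        else:
            branches["vein"] = b
    return Centerline(branches=branches, junction=junction_xyz)


def _relocate_arclength_origin(branches: dict[str, CenterlineBranch]) -> None:
    """Shift fistula/vein arclengths so s = 0 sits at the anastomosis.

    The medial-axis junction of an end-to-side connection lies up to one
    parent radius *into* the daughter branch, not on the artery axis.  The
    anatomical anastomosis is recovered by back-projecting the junction onto
    the artery centerline along the fistula direction: with d the distance
    from the junction to the artery axis and theta the branch angle, the
    junction sits d/sin(theta) along the fistula from the anastomosis.
    """
    artery = [b for name, b in branches.items() if "artery" in name]
    daughters = [(n, b) for n, b in branches.items() if "artery" not in n]
    if not artery or not daughters:
        return
    art = max(artery, key=lambda b: len(b.points))
    if len(art.points) < 12:
        return
    # artery line fitted away from the junction zone
    seg = art.points[5:15]
    centre = seg.mean(axis=0)
    t_a = np.linalg.svd(seg - centre)[2][0]
    name0, d0 = min(daughters, key=lambda nb: np.abs(nb[1].arclength).min())
    junction = d0.points[0]
    k = min(6, len(d0.points) - 1)
    t_f = d0.points[k] - d0.points[0]
    nf = np.linalg.norm(t_f)
    if nf == 0:
        return
    t_f /= nf
    rel = junction - centre
    dist = np.linalg.norm(rel - (rel @ t_a) * t_a)
    sin_theta = np.linalg.norm(np.cross(t_f, t_a))
    if sin_theta < 0.3:
        return
    offset = dist / sin_theta
    for name, b in daughters:
        b.arclength = b.arclength + np.sign(b.arclength.sum()) * offset


def _edt_refine(pts: np.ndarray, edt: np.ndarray, spacing, origin,
                reach: int = 2) -> np.ndarray:
    """Sub-voxel snap of skeleton points onto the distance-transform ridge.

    Skeletonization is voxel-quantized and its thinning order can leave the
    path a voxel off the true medial axis; replacing each point by the
    EDT^2-weighted centroid of its local in-lumen neighborhood recovers the
    ridge to sub-voxel accuracy.
    """
    shape = np.array(edt.shape)
    offs = np.array([(i, j, k) for i in range(-reach, reach + 1)
                     for j in range(-reach, reach + 1)
                     for k in range(-reach, reach + 1)])
    out = pts.copy()
    # local tangent from the raw path: corrections act only transversely,
    # so the refinement cannot shorten the path longitudinally
    tang = np.gradient(pts, axis=0)
    norms = np.linalg.norm(tang, axis=1, keepdims=True)
    tang = np.divide(tang, norms, out=np.zeros_like(tang), where=norms > 0)
    for q, p in enumerate(pts):
        pos = p.copy()
        for _ in range(3):
            ijk = np.round((pos - origin) / spacing).astype(int)
            nb = ijk + offs
            ok = np.all((nb >= 0) & (nb < shape), axis=1)
            nb = nb[ok]
            w = edt[nb[:, 0], nb[:, 1], nb[:, 2]] ** 2
            if w.sum() <= 0:
                break
            centroid = (w[:, None] * (origin + nb * spacing)).sum(axis=0) / w.sum()
            delta = centroid - pos
            delta -= (delta @ tang[q]) * tang[q]
            pos = pos + delta
        out[q] = pos
    return out


def _smooth_polyline(pts: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(pts) < window:
        return pts
    kernel = np.ones(window) / window
    sm = pts.copy()
    for a in range(3):
        sm[:, a] = np.convolve(np.pad(pts[:, a], window // 2, mode="edge"),
                               kernel, mode="valid")[: len(pts)]
    sm[0], sm[-1] = pts[0], pts[-1]
    return sm


def _extend_to_boundary(pts, mask, spacing, origin, end: str) -> np.ndarray:
    """Extrapolate a path end along its tangent until it leaves the mask.

    Skeletonization retreats roughly one radius from open tube ends; this
    restores the missing length at voxel resolution.
    """
    step = float(spacing.min()) * 0.5
    if end == "tail":
        p, t = pts[-1], pts[-1] - pts[max(0, len(pts) - 6)]
    else:
        p, t = pts[0], pts[0] - pts[min(len(pts) - 1, 5)]
    norm = np.linalg.norm(t)
    if norm == 0:
        return pts
    t = t / norm
    extra = []
    q = p.copy()
    for _ in range(int(20.0 / step)):
        q = q + step * t
        ijk = np.round((q - origin) / spacing).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= mask.mask.shape) or not mask.mask[tuple(ijk)]:
            break
        extra.append(q.copy())
    if not extra:
        return pts
    ext = np.asarray(extra)
    return np.vstack([pts, ext]) if end == "tail" else np.vstack([ext[::-1], pts])


def _sample_edt(edt, pts, spacing, origin) -> np.ndarray:
    coords = ((pts - origin) / spacing).T
    return ndimage.map_coordinates(edt, coords, order=1, mode="nearest")


def _match_label(endpoint_xyz, hints, used) -> str | None:
    if not hints:
        return None
    best, best_d = None, np.inf
    for label, pos in hints.items():
        if label in used:
            continue
        d = np.linalg.norm(np.asarray(pos, float) - endpoint_xyz)
        if d < best_d:
            best, best_d = label, d
    return best


def avf_endpoint_hints(geom: VesselGeometry) -> dict[str, np.ndarray]:
    """Expected branch-endpoint positions of a synthetic AVF, for labeling."""
    hints = {}
    for name in ("proximal_artery", "distal_artery", "vein"):
        if name in geom.branches:
            b = geom.branches[name]
            u_end = b.u_range[0] if name == "proximal_artery" else b.u_range[1]
            hints[name] = b.points(np.array([u_end]))[0]
    return hints


# ---------------------------------------------------------------------------
# Diameter profiles
# ---------------------------------------------------------------------------

@dataclass
class DiameterProfile:
    """Equivalent-circle diameter vs signed arclength, per branch."""

    arclength: np.ndarray   # mm
    area: np.ndarray        # mm^2
    diameter: np.ndarray    # mm, 2 sqrt(A/pi)
    branch: np.ndarray      # str labels
    skipped: list[float] = field(default_factory=list)  # stations that could not be measured

    def __post_init__(self) -> None:
        if np.any(self.diameter <= 0):
            raise ValueError("diameters must be positive")
        assert np.allclose(self.area, np.pi * self.diameter**2 / 4.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"arclength_mm": self.arclength, "area_mm2": self.area,
                             "diameter_mm": self.diameter, "branch": self.branch})

    def select(self, branch: str) -> "DiameterProfile":
        m = self.branch == branch
        return DiameterProfile(self.arclength[m], self.area[m], self.diameter[m],
                               self.branch[m])


def diameter_profile(centerline: Centerline, source, step: float = 0.05,
                     branches: list[str] | None = None) -> DiameterProfile:
    """Cross-sectional lumen area/diameter along each centerline branch.

    At each arclength station the lumen is resampled on the plane normal to
    the local centerline tangent (half-voxel in-plane resolution, connected
    component containing the centerline point) and the equivalent-circle
    diameter 2 sqrt(A/pi) recorded.  With an analytic ``VesselGeometry`` source
    the exact ground-truth D(s) is returned instead.  Stations whose
    cross-section plane leaves the volume are skipped and recorded in
    ``skipped``.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    names = branches or list(centerline.branches)
    s_all, a_all, d_all, b_all, skipped = [], [], [], [], []
    for name in names:
        br = centerline.branches[name]
        lo, hi = br.arclength.min(), br.arclength.max()
        stations = np.arange(lo, hi + 0.5 * step, step)
        if isinstance(source, VesselGeometry):
            dia = source.diameter(_geom_branch_for(name), stations)
            area = np.pi * dia**2 / 4.0
            ok = np.ones(len(stations), bool)
        else:
            dia = np.empty(len(stations))
            ok = np.zeros(len(stations), bool)
            for k, s in enumerate(stations):
                a = _plane_area(br, s, source)
                if a is None:
                    skipped.append(float(s))
                    continue
                dia[k] = 2.0 * np.sqrt(a / np.pi)
                ok[k] = True
            area = np.pi * dia**2 / 4.0
        s_all.append(stations[ok])
        a_all.append(area[ok])
        d_all.append(dia[ok])
        b_all.append(np.full(int(ok.sum()), name, dtype=object))
    return DiameterProfile(np.concatenate(s_all), np.concatenate(a_all),
                           np.concatenate(d_all), np.concatenate(b_all),
                           skipped=skipped)


def _geom_branch_for(name: str) -> str:
    return name if name in VesselGeometry.BRANCH_NAMES else "fistula"


def _plane_area(branch: CenterlineBranch, s: float, mask: SegmentationMask):
    """Lumen area (mm^2) on the plane normal to the centerline at arclength s."""
    order = np.argsort(branch.arclength)
    sa, pa = branch.arclength[order], branch.points[order]
    centre = np.array([np.interp(s, sa, pa[:, a]) for a in range(3)])
    tangents = np.gradient(pa, axis=0)
    tang = np.array([np.interp(s, sa, tangents[:, a]) for a in range(3)])
    n = np.linalg.norm(tang)
    if n == 0:
        return None
    tang /= n
    ref = np.array([0.0, 0.0, 1.0]) if abs(tang[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(tang, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(tang, e1)
    r_loc = float(np.interp(s, sa, branch.inscribed_radius[order]))
    half = max(3.0 * r_loc, 6.0 * float(np.min(mask.spacing)))
    h = 0.5 * float(np.min(mask.spacing))
    m = int(np.ceil(half / h))
    u = np.arange(-m, m + 1) * h
    U, V = np.meshgrid(u, u, indexing="ij")
    pts = centre[None, :] + U.ravel()[:, None] * e1[None, :] + V.ravel()[:, None] * e2[None, :]
    coords = ((pts - np.asarray(mask.origin)) / np.asarray(mask.spacing)).T
    shape = np.asarray(mask.mask.shape)
    out_of_volume = np.any(coords < -0.5, axis=0) | np.any(
        coords > (shape[:, None] - 0.5), axis=0)
    vals = ndimage.map_coordinates(mask.mask.astype(float), coords, order=1, cval=0.0)
    inside = (vals >= 0.5).reshape(U.shape)
    if out_of_volume.reshape(U.shape)[inside].any():
        return None  # cross-section plane exits the volume
    lab, nlab = ndimage.label(inside)
    centre_lab = lab[m, m]
    if centre_lab == 0:
        # centre off by sub-voxel: take nearest labeled pixel within the inscribed radius
        if not inside.any():
            return None
        dist2 = (U - 0.0) ** 2 + (V - 0.0) ** 2
        dist2[~inside] = np.inf
        k = np.unravel_index(np.argmin(dist2), inside.shape)
        if dist2[k] > max(r_loc, 2 * h) ** 2:
            return None
        centre_lab = lab[k]
    return float((lab == centre_lab).sum()) * h * h


# ---------------------------------------------------------------------------
# Statistics and derived quantities
# ---------------------------------------------------------------------------

@dataclass
class SegmentStats:
    mean_diameter: float
    min_diameter: float
    max_diameter: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.min_diameter <= self.mean_diameter <= self.max_diameter:
            raise ValueError("segment stats must satisfy min <= mean <= max")

    def __str__(self) -> str:  # Table-1 style "mean (min - max)"
        return (f"{self.mean_diameter:.2f} ({self.min_diameter:.2f} - "
                f"{self.max_diameter:.2f})")


def segment_stats(profile: DiameterProfile, window: tuple[float, float]) -> SegmentStats:
    """Mean/min/max diameter over samples with arclength in [start, end)."""
    start, end = window
    m = (profile.arclength >= start) & (profile.arclength < end)
    if not m.any():
        raise ValueError(f"window {window} contains no profile samples")
    d = profile.diameter[m]
    return SegmentStats(float(d.mean()), float(d.min()), float(d.max()), window)


def percent_change(before: float, after: float) -> float:
    """Signed percent change 100 (after - before)/before."""
    if before <= 0:
        raise ValueError("baseline value must be > 0")
    return 100.0 * (after - before) / before


def poiseuille_resistance(profile: DiameterProfile, viscosity: float = 4e-3,
                          window: tuple[float, float] | None = None) -> float:
    """Poiseuille flow resistance of a vessel segment, Pa.s/m^3.

    R = integral of 128 mu / (pi D(s)^4) ds over the window (trapezoid on the
    profile samples); diameters and arclengths are converted from mm to m.
    """
    s, d = profile.arclength, profile.diameter
    if window is not None:
        m = (s >= window[0]) & (s < window[1])
        if not m.any():
            raise ValueError(f"window {window} contains no profile samples")
        s, d = s[m], d[m]
    if np.any(d <= 0):
        raise ValueError("diameters must be strictly positive")
    order = np.argsort(s)
    s_m = s[order] * 1e-3
    d_m = d[order] * 1e-3
    integrand = 128.0 * viscosity / (np.pi * d_m**4)
    return float(np.trapezoid(integrand, s_m))
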
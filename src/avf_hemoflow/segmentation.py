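"""Lumen segmentation of contrast-CT-like volumes.

The segmentation contract mirrors a contrast-CT vascular workflow: an
HU-window threshold (default 300-1000 HU) isolates contrast-enhanced voxels,
seed-based region growing keeps only the components connected to user seeds,
an optional morphological cleanup replaces manual editing, and a marching-cubes
iso-surface exports the lumen as a triangulated (STL-ready) surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .synthgen import ImageVolume, VesselGeometry

__all__ = [
    "SegmentationConfig",
    "SegmentationMask",
    "threshold_volume",
    "region_grow",
    "cleanup_mask",
    "extract_surface",
    "inlet_extension",
]


@dataclass
class SegmentationConfig:
    """HU window, seeds and connectivity for the threshold + region-grow stages.

    ``connectivity`` is 6 (face neighbors) or 26 (face+edge+corner); the
    6-connected default is the conservative reading that prevents diagonal
    leakage across thin walls.  Bounds are inclusive.
    """

    hu_lower: float = 300.0
    hu_upper: float = 1000.0
    seeds: list[tuple[int, int, int]] = field(default_factory=list)
    connectivity: int = 6
    min_island_voxels: int = 27   # cleanup: drop isolated true-components smaller than this
    fill_holes: bool = True
    smoothing_iterations: int = 10  # Taubin iterations for extract_surface

    def __post_init__(self) -> None:
        if not self.hu_lower < self.hu_upper:
            raise ValueError("hu_lower must be < hu_upper")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")

    @property
    def _structure(self) -> np.ndarray:
        return ndimage.generate_binary_structure(3, 1 if self.connectivity == 6 else 3)


@dataclass
class SegmentationMask:
    """Boolean lumen mask aligned to its source :class:`ImageVolume`."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: dict = field(default_factory=dict)
    empty: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        self.empty = not bool(self.mask.any())

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


def threshold_volume(volume: ImageVolume, config: SegmentationConfig) -> SegmentationMask:
    """Mask of voxels with hu_lower <= intensity <= hu_upper (inclusive bounds).

    An empty result is returned as an all-false mask with ``empty=True``
    rather than an exception.
    """
    m = (volume.intensities >= config.hu_lower) & (volume.intensities <= config.hu_upper)
    return SegmentationMask(
        mask=m, spacing=volume.spacing, origin=volume.origin,
        provenance={"stage": "threshold",
                    "hu_window": (config.hu_lower, config.hu_upper)})


def region_grow(mask: SegmentationMask, config: SegmentationConfig) -> SegmentationMask:
    """Keep only the connected components of ``mask`` that contain a seed.

    Seeds are voxel indices into the mask array.  A seed falling on a false
    voxel raises ``ValueError`` naming the offending seed.  Idempotent, and the
    output is always a subset of the input.
    """
    if not config.seeds:
        raise ValueError("region_grow requires at least one seed")
    labels, _ = ndimage.label(mask.mask, structure=config._structure)
    keep = set()
    for s in config.seeds:
        lab = int(labels[tuple(s)])
        if lab == 0:
            raise ValueError(f"seed {tuple(s)} lies outside the thresholded mask")
        keep.add(lab)
    out = np.isin(labels, sorted(keep))
    return SegmentationMask(
        mask=out, spacing=mask.spacing, origin=mask.origin,
        provenance={**mask.provenance, "stage": "region_grow",
                    "seeds": [tuple(s) for s in config.seeds],
                    "connectivity": config.connectivity})


def cleanup_mask(mask: SegmentationMask, config: SegmentationConfig) -> SegmentationMask:
    """Automated stand-in for manual mask editing: fill holes, drop small islands."""
    m = mask.mask
    if config.fill_holes:
        m = ndimage.binary_fill_holes(m, structure=config._structure)
    if config.min_island_voxels > 0:
        labels, n = ndimage.label(m, structure=config._structure)
        if n:
            counts = np.bincount(labels.ravel())
            small = np.flatnonzero(counts < config.min_island_voxels)
            m = m & ~np.isin(labels, small[small > 0])
    return SegmentationMask(mask=m, spacing=mask.spacing, origin=mask.origin,
                            provenance={**mask.provenance, "stage": "cleanup"})


def extract_surface(mask: SegmentationMask, smoothing_iterations: int = 10):
    """Closed triangulated iso-surface of the mask at the 0.5 level, mm units.

    The volume is zero-padded first, so a lumen touching the array border is
    capped with a flat face (recorded in ``mesh.metadata['border_capped']``).
    Optional volume-preserving Taubin smoothing (default 10 iterations) stands
    in for interactive surface cleanup.  Returns a ``trimesh.Trimesh``.
    """
    import trimesh
    from skimage.measure import marching_cubes

    if mask.empty:
        raise ValueError("cannot extract a surface from an empty mask")
    m = mask.mask
    border = bool(m[0].any() or m[-1].any() or m[:, 0].any() or m[:, -1].any()
                  or m[:, :, 0].any() or m[:, :, -1].any())
    padded = np.pad(m.astype(float), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=mask.spacing)
    verts += np.asarray(mask.origin) - np.asarray(mask.spacing)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    trimesh.repair.fix_normals(mesh)
    if smoothing_iterations > 0:
        trimesh.smoothing.filter_taubin(mesh, iterations=smoothing_iterations)
    mesh.metadata["border_capped"] = border
    return mesh


def inlet_extension(obj, length: float = 2.0):
    """Extend artery inlet/outlet openings by ``length`` mm of straight tube.

    Mirrors the reconstruction step in which artery inlet/outlet regions are
    extended (2 mm by default) so that prescribed inflow can develop before
    reaching the junction.

    Two input kinds are supported:

    * :class:`~avf_hemoflow.synthgen.VesselGeometry` — the artery branch ranges
      and the implicit lumen are lengthened analytically (exact), returning the
      same geometry object mutated with ``inlet_extension_length`` set;
    * ``trimesh.Trimesh`` with open boundary rims — every near-planar rim is
      extruded along its mean outward normal with constant cross-section.

    ``length = 0`` returns the input unchanged.
    """
    if length < 0:
        raise ValueError("extension length must be >= 0")
    if length == 0:
        return obj
    if isinstance(obj, VesselGeometry):
        obj.inlet_extension_length += float(length)
        for name in ("proximal_artery", "distal_artery"):
            if name not in obj.branches:
                continue
            b = obj.branches[name]
            lo, hi = b.u_range
            b.u_range = (lo - length, hi) if name == "proximal_artery" else (lo, hi + length)
        obj._surface = None
        obj._patches = None
        return obj
    return _extrude_open_rims(obj, length)


def _extrude_open_rims(mesh, length: float, planarity_tol: float = 0.15):
    """Extrude each open boundary loop of a surface along its mean normal."""
    import trimesh

    paths = mesh.outline()
    if paths is None or len(paths.entities) == 0:
        raise ValueError("surface has no open rims to extend")
    verts = mesh.vertices.copy()
    faces = [mesh.faces.copy()]
    for ent in paths.entities:
        loop = ent.points
        if loop[0] == loop[-1]:
            loop = loop[:-1]
        pts = mesh.vertices[loop]
        centre = pts.mean(axis=0)
        # rim plane via PCA; smallest principal direction = rim normal
        u, s, vt = np.linalg.svd(pts - centre)
        normal = vt[2]
        rms = np.sqrt(np.mean(((pts - centre) @ normal) ** 2))
        scale = np.sqrt(np.mean(np.sum((pts - centre) ** 2, axis=1)))
        if rms > planarity_tol * scale:
            raise ValueError("rim is not planar within tolerance; cannot extrude")
        # orient the normal away from the mesh body
        body_dir = mesh.vertices.mean(axis=0) - centre
        if normal @ body_dir > 0:
            normal = -normal
        n0 = len(verts)
        verts = np.vstack([verts, pts + length * normal])
        n = len(loop)
        quads = []
        for k in range(n):
            a, b = loop[k], loop[(k + 1) % n]
            a2, b2 = n0 + k, n0 + (k + 1) % n
            quads.append([a, b, b2])
            quads.append([a, b2, a2])
        faces.append(np.asarray(quads))
    out = trimesh.Trimesh(vertices=verts, faces=np.vstack(faces), process=True)
    trimesh.repair.fix_normals(out)
    return out
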
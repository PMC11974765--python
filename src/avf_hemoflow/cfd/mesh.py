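"""Body-fitted structured quadrilateral meshes for the flow solver.

Meshes live in a 2-D (x, y) half-plane in millimetres at the interface; the
solver-facing metric arrays (face area vectors, volumes, centroids) are
precomputed in SI metres.  In ``axisym`` mode y is the radial coordinate and
all fluxes/volumes carry the radius weight (the common 2*pi factor is dropped
consistently); in ``planar`` mode the domain is a unit-depth channel.

Index conventions: cells (i, j) with i the axial/streamwise index
(0..ni-1, west inlet -> east outlet) and j the cross-stream index
(0..nj-1, south = axis/symmetry/wall, north = wall).
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["StructuredMesh2D", "tube_mesh", "channel_mesh", "avf_path_mesh"]

MM = 1e-3  # metres per millimetre


class StructuredMesh2D:
    """Structured quad grid with precomputed finite-volume metrics (SI)."""

    def __init__(self, X_mm: np.ndarray, Y_mm: np.ndarray, mode: str = "axisym",
                 bc: dict[str, str] | None = None):
        if mode not in ("axisym", "planar"):
            raise ValueError("mode must be 'axisym' or 'planar'")
        self.X_mm = np.asarray(X_mm, float)
        self.Y_mm = np.asarray(Y_mm, float)
        if self.X_mm.shape != self.Y_mm.shape or self.X_mm.ndim != 2:
            raise ValueError("X_mm and Y_mm must be matching 2-D node arrays")
        self.mode = mode
        self.ni = self.X_mm.shape[0] - 1
        self.nj = self.X_mm.shape[1] - 1
        default_bc = {"west": "inlet", "east": "outlet",
                      "south": "axis" if mode == "axisym" else "wall",
                      "north": "wall"}
        self.bc = {**default_bc, **(bc or {})}
        self._compute_metrics()

    # -- metric computation ---------------------------------------------------

    def _compute_metrics(self) -> None:
        X = self.X_mm * MM
        Y = self.Y_mm * MM
        ni, nj = self.ni, self.nj
        # cell centroids (mean of 4 nodes) and planar areas (shoelace on quad)
        x00, x10 = X[:-1, :-1], X[1:, :-1]
        x01, x11 = X[:-1, 1:], X[1:, 1:]
        y00, y10 = Y[:-1, :-1], Y[1:, :-1]
        y01, y11 = Y[:-1, 1:], Y[1:, 1:]
        self.xc = 0.25 * (x00 + x10 + x01 + x11)
        self.yc = 0.25 * (y00 + y10 + y01 + y11)
        # quad area via the cross product of its diagonals
        self.area = 0.5 * np.abs((x11 - x00) * (y01 - y10)
                                 - (x01 - x10) * (y11 - y00))
        if np.any(self.area <= 0):
            raise ValueError("mesh contains degenerate cells")
        self.wc = self.yc if self.mode == "axisym" else np.ones_like(self.yc)
        self.vol = self.area * self.wc

        # i-faces (constant-i, between columns), shape (ni+1, nj):
        # nodes (i, j) -> (i, j+1); outward normal toward +i
        ex = X[:, 1:] - X[:, :-1]
        ey = Y[:, 1:] - Y[:, :-1]
        self.fi_cx = 0.5 * (X[:, 1:] + X[:, :-1])
        self.fi_cy = 0.5 * (Y[:, 1:] + Y[:, :-1])
        wi = self.fi_cy if self.mode == "axisym" else np.ones_like(self.fi_cy)
        self.fi_Sx_p, self.fi_Sy_p = ey, -ex          # planar area vector
        self.fi_Sx, self.fi_Sy = ey * wi, -ex * wi    # weighted area vector
        # j-faces (constant-j), shape (ni, nj+1): nodes (i, j) -> (i+1, j);
        # outward normal toward +j
        fx = X[1:, :] - X[:-1, :]
        fy = Y[1:, :] - Y[:-1, :]
        self.fj_cx = 0.5 * (X[1:, :] + X[:-1, :])
        self.fj_cy = 0.5 * (Y[1:, :] + Y[:-1, :])
        wj = self.fj_cy if self.mode == "axisym" else np.ones_like(self.fj_cy)
        self.fj_Sx_p, self.fj_Sy_p = -fy, fx
        self.fj_Sx, self.fj_Sy = -fy * wj, fx * wj

        self.min_cell_size = float(np.sqrt(self.area).min())

    # -- convenience ----------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.ni * self.nj

    @property
    def axial_s_mm(self) -> np.ndarray:
        """Arclength station (mm) of each cell column (axial position of centroids)."""
        return self.xc.mean(axis=1) / MM

    def inlet_radii_mm(self) -> np.ndarray:
        """Cross-stream coordinate (mm) of west-face centroids."""
        return self.fi_cy[0] / MM

    def inlet_radius_mm(self) -> float:
        return float(self.Y_mm[0].max())

    def wall_face_arclength_mm(self) -> np.ndarray:
        """Axial station (mm) of north-wall face centroids."""
        return self.fj_cx[:, -1] / MM

    def refine(self, factor: int = 2) -> "StructuredMesh2D":
        """Nested refinement by node interpolation (bilinear in index space)."""
        from scipy.interpolate import RegularGridInterpolator
        ii = np.arange(self.ni + 1)
        jj = np.arange(self.nj + 1)
        fi = np.linspace(0, self.ni, factor * self.ni + 1)
        fj = np.linspace(0, self.nj, factor * self.nj + 1)
        FI, FJ = np.meshgrid(fi, fj, indexing="ij")
        pts = np.stack([FI.ravel(), FJ.ravel()], axis=-1)
        Xr = RegularGridInterpolator((ii, jj), self.X_mm)(pts).reshape(FI.shape)
        Yr = RegularGridInterpolator((ii, jj), self.Y_mm)(pts).reshape(FI.shape)
        return StructuredMesh2D(Xr, Yr, mode=self.mode, bc=dict(self.bc))


def _wall_clustered(n: int) -> np.ndarray:
    """n+1 points on [0, 1] clustered toward 1 (the wall)."""
    return np.sin(0.5 * np.pi * np.linspace(0.0, 1.0, n + 1))


def tube_mesh(radius_mm: float | Callable, length_mm: float | None = None,
              s_range_mm: tuple[float, float] | None = None,
              ni: int = 60, nj: int = 16, mode: str = "axisym",
              cluster_wall: bool = True) -> StructuredMesh2D:
    """Variable-radius tube (axisymmetric) or half-channel (planar symmetry).

    ``radius_mm`` is a constant or a function R(s) of axial position (mm).
    The grid is uniform axially and wall-clustered radially.
    """
    if s_range_mm is None:
        if length_mm is None:
            raise ValueError("provide length_mm or s_range_mm")
        s_range_mm = (0.0, length_mm)
    s = np.linspace(s_range_mm[0], s_range_mm[1], ni + 1)
    R = radius_mm(s) if callable(radius_mm) else np.full(ni + 1, float(radius_mm))
    if np.any(np.asarray(R) <= 0):
        raise ValueError("tube radius must be positive everywhere")
    eta = _wall_clustered(nj) if cluster_wall else np.linspace(0, 1, nj + 1)
    X = np.repeat(s[:, None], nj + 1, axis=1)
    Y = np.outer(R, eta)
    bc = {"south": "axis" if mode == "axisym" else "symmetry"}
    return StructuredMesh2D(X, Y, mode=mode, bc=bc)


def channel_mesh(height_mm: float, length_mm: float, ni: int = 40, nj: int = 20,
                 south: str = "wall") -> StructuredMesh2D:
    """Planar channel of full height with walls on both sides (Couette/Poiseuille)."""
    X, Y = np.meshgrid(np.linspace(0, length_mm, ni + 1),
                       np.linspace(0, height_mm, nj + 1), indexing="ij")
    return StructuredMesh2D(X, Y, mode="planar", bc={"south": south})


def avf_path_mesh(geometry, ni: int = 96, nj: int = 20,
                  s_range_mm: tuple[float, float] = (-2.0, 6.0),
                  mode: str = "axisym") -> StructuredMesh2D:
    """Axisymmetric solver mesh of the proximal-artery -> fistula -> vein path.

    Uses the geometry's ground-truth flow-path diameter D(s); negative s is
    the artery upstream of the anastomosis.
    """
    return tube_mesh(lambda s: 0.5 * geometry.flow_path_diameter(s),
                     s_range_mm=s_range_mm, ni=ni, nj=nj, mode=mode)
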
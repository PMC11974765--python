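"""Grid-independence study and centerline flow profiles for solver fields."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import StructuredMesh2D
from .solver import BloodModel, FlowField, SolverConfig, solve_steady

__all__ = ["CenterlineSeries", "GridIndependenceReport",
           "centerline_series", "grid_independence"]


# canonical coarse/medium/fine nested resolutions (ni, nj) for the
# grid-independence study on the synthetic AVF flow path
AVF_GRID_FAMILY = ((48, 10), (96, 20), (192, 40))
AVF_GRID_STATIONS_MM = np.linspace(-1.5, 5.5, 11)


def default_avf_mesh_family(geometry, s_range_mm=(-2.0, 6.0)):
    """The three shipped nested solver meshes of the synthetic AVF path."""
    from .mesh import avf_path_mesh
    return [avf_path_mesh(geometry, ni=ni, nj=nj, s_range_mm=s_range_mm)
            for ni, nj in AVF_GRID_FAMILY]


@dataclass
class CenterlineSeries:
    """Cross-section-averaged velocity/pressure vs arclength for one sample."""

    arclength: np.ndarray      # mm
    area: np.ndarray           # mm^2 (physical cross-section)
    mean_velocity: np.ndarray  # mm/s, area-weighted mean |u|
    mean_pressure: np.ndarray  # Pa
    pressure_drop_fraction: np.ndarray  # cumulative fraction of total drop

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "arclength_mm": self.arclength, "area_mm2": self.area,
            "mean_velocity_mm_s": self.mean_velocity,
            "mean_pressure_pa": self.mean_pressure,
            "pressure_drop_fraction": self.pressure_drop_fraction})


def centerline_series(flow: FlowField, sample: int = 0) -> CenterlineSeries:
    """Area-weighted cross-sectional averages along the vessel axis.

    Each mesh column is one centerline station.  Also reports the cumulative
    fraction of the total inlet-to-outlet pressure drop, the quantity used to
    localize where the drop is spent along the fistula.
    """
    m = flow.mesh
    u = flow.u[sample]
    p = flow.p[sample]
    # cross-section (axial-projected, radius-weighted) area elements per cell
    aw = 0.5 * (m.fi_Sx[:-1, :] + m.fi_Sx[1:, :])
    w = m.vol.reshape(m.ni, m.nj)
    mean_u = (np.abs(u) * aw).sum(axis=1) / aw.sum(axis=1)
    mean_p = (p * w).sum(axis=1) / w.sum(axis=1)
    R = 0.5 * (m.Y_mm[:-1, -1] + m.Y_mm[1:, -1])
    area = np.pi * R**2 if m.mode == "axisym" else 2.0 * R
    total = mean_p[0] - mean_p[-1]
    frac = ((mean_p[0] - mean_p) / total) if abs(total) > 0 else np.zeros_like(mean_p)
    return CenterlineSeries(arclength=m.axial_s_mm, area=area,
                            mean_velocity=mean_u, mean_pressure=mean_p,
                            pressure_drop_fraction=frac)


@dataclass
class GridIndependenceReport:
    """Pairwise refinement differences of station-sampled flow quantities."""

    n_cells: list[int]
    stations_mm: np.ndarray
    velocity_diff_pct: list[float]   # max relative difference, consecutive pairs
    pressure_diff_pct: list[float]
    criterion_pct: float = 1.0
    fields: list[FlowField] = field(default_factory=list, repr=False)

    @property
    def max_diff_pct(self) -> list[float]:
        return [max(v, p) for v, p in zip(self.velocity_diff_pct,
                                          self.pressure_diff_pct)]

    @property
    def independent(self) -> bool:
        """True when the finest consecutive pair differs by less than the criterion."""
        return self.max_diff_pct[-1] < self.criterion_pct


def _station_values(series: CenterlineSeries, stations: np.ndarray):
    vu = np.interp(stations, series.arclength, series.mean_velocity)
    vp = np.interp(stations, series.arclength, series.mean_pressure)
    return vu, vp


def grid_independence(meshes: list[StructuredMesh2D], blood: BloodModel,
                      inlet_flow_mm3_s: float,
                      config: SolverConfig | None = None,
                      stations_mm: np.ndarray | None = None,
                      criterion_pct: float = 1.0,
                      keep_fields: bool = False) -> GridIndependenceReport:
    """Steady-solve a nested mesh family and compare station-sampled profiles.

    Meshes must be ordered coarse -> fine (cell counts strictly increasing).
    For each consecutive pair the report carries the maximum relative
    difference (percent, normalized by the finer mesh's profile range) of the
    cross-section-averaged velocity and pressure at the given stations;
    ``independent`` flags whether the finest pair meets the criterion
    (default 1%).
    """
    if len(meshes) < 2:
        raise ValueError("need at least two mesh resolutions")
    counts = [m.n_cells for m in meshes]
    if any(b <= a for a, b in zip(counts, counts[1:])):
        raise ValueError("meshes must be ordered from coarse to fine")
    cfg = config or SolverConfig()
    if stations_mm is None:
        s0 = meshes[0].axial_s_mm
        stations_mm = np.linspace(s0[1], s0[-2], 9)
    stations_mm = np.asarray(stations_mm, float)
    series = []
    fields = []
    for m in meshes:
        f = solve_steady(m, blood, inlet_flow_mm3_s=inlet_flow_mm3_s, config=cfg)
        series.append(centerline_series(f))
        if keep_fields:
            fields.append(f)
    vdiffs, pdiffs = [], []
    for a, b in zip(series, series[1:]):
        va, pa = _station_values(a, stations_mm)
        vb, pb = _station_values(b, stations_mm)
        vscale = np.abs(vb).max()
        pscale = np.ptp(pb) if np.ptp(pb) > 0 else max(np.abs(pb).max(), 1e-300)
        vdiffs.append(float(np.abs(va - vb).max() / vscale * 100.0))
        pdiffs.append(float(np.abs(pa - pb).max() / pscale * 100.0))
    return GridIndependenceReport(n_cells=counts, stations_mm=stations_mm,
                                  velocity_diff_pct=vdiffs,
                                  pressure_diff_pct=pdiffs,
                                  criterion_pct=criterion_pct, fields=fields)
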
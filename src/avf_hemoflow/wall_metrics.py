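"""Wall-derived hemodynamic metrics: WSS, TAWSS, OSI, Q-criterion.

Definitions
-----------
* WSS vector: tau = mu (d v_t / d n) at the wall, with v_t the wall-tangential
  velocity and n the distance into the fluid; evaluated with a one-sided
  quadratic stencil through the wall value and the two nearest cell centres.
* TAWSS = (1/T) integral over one cycle of |tau|.
* OSI = 1/2 (1 - |integral tau dt| / integral |tau| dt), the vector form: the
  magnitude of the time-averaged WSS vector over the time-average of its
  magnitude.  0 = unidirectional shear, 0.5 = complete reversal; elements with
  zero TAWSS are assigned OSI 0.
* Q-criterion = 1/2 (||Omega||^2 - ||S||^2) with Omega/S the antisymmetric and
  symmetric parts of the velocity-gradient tensor (Frobenius norms); positive
  where rotation dominates strain.

Units: with velocities in mm/s, lengths in mm and mu in Pa.s, shear stresses
come out in Pa and Q in 1/s^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cfd.solver import FlowField

__all__ = [
    "WallShearField",
    "WallMetricField",
    "QCriterionField",
    "ArclengthProfile",
    "CorrelationResult",
    "wall_shear",
    "tawss",
    "osi",
    "q_criterion",
    "profile_by_arclength",
    "window_average",
    "correlate",
]


@dataclass
class WallShearField:
    """Per-wall-element WSS vectors over the stored samples of one cycle."""

    times: np.ndarray        # (nt,) s
    tau: np.ndarray          # (nt, nf, 2) Pa, in-plane vector
    arclength: np.ndarray    # (nf,) mm, centerline station of each wall element
    face_area: np.ndarray    # (nf,) mm^2, physical wall-band area (weights)
    period: float | None = None

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.tau, axis=2)


@dataclass
class WallMetricField:
    tawss: np.ndarray        # (nf,) Pa
    osi: np.ndarray          # (nf,) in [0, 0.5]
    arclength: np.ndarray    # (nf,) mm
    face_area: np.ndarray    # (nf,) mm^2


@dataclass
class QCriterionField:
    q: np.ndarray            # (nt, ni, nj) s^-2
    boundary_cell: np.ndarray  # (ni, nj) bool; one-sided gradients used there


def wall_shear(flow: FlowField, viscosity: float | None = None,
               wall_speed_mm_s: dict[str, float] | None = None) -> WallShearField:
    """WSS vectors on the no-slip walls of a solver flow field.

    ``viscosity`` defaults to the blood-model value used throughout (4e-3
    Pa.s).  ``wall_speed_mm_s`` gives tangential wall speeds for moving-wall
    (Couette) cases, keyed 'north'/'south'.
    """
    mu = 4e-3 if viscosity is None else viscosity
    m = flow.mesh
    walls = ["north"] + (["south"] if m.bc.get("south") == "wall" else [])
    taus, arcs, areas = [], [], []
    for side in walls:
        t, a, w = _wall_shear_side(flow, m, mu, side,
                                   (wall_speed_mm_s or {}).get(side, 0.0))
        taus.append(t); arcs.append(a); areas.append(w)
    return WallShearField(times=flow.times, tau=np.concatenate(taus, axis=1),
                          arclength=np.concatenate(arcs),
                          face_area=np.concatenate(areas), period=flow.period)


def _wall_shear_side(flow, m, mu, side, wall_speed):
    ni, nj = m.ni, m.nj
    if side == "north":
        jw = nj
        j1, j2 = nj - 1, nj - 2
    else:
        jw = 0
        j1, j2 = 0, 1
    # wall face geometry (mm)
    fx = m.fj_cx[:, jw] / 1e-3
    fy = m.fj_cy[:, jw] / 1e-3
    ex = (m.X_mm[1:, jw] - m.X_mm[:-1, jw])
    ey = (m.Y_mm[1:, jw] - m.Y_mm[:-1, jw])
    el = np.hypot(ex, ey)
    tx, ty = ex / el, ey / el                      # tangent, +i sense
    nx, ny = -ty, tx                               # unit normal (sign irrelevant:
    # distances below are absolute, and the gradient is taken along distance
    # *into the fluid*, which fixes the WSS sign by construction)
    # distances of the two near-wall cell centres along the normal
    c1x, c1y = m.xc[:, j1] / 1e-3, m.yc[:, j1] / 1e-3
    c2x, c2y = m.xc[:, j2] / 1e-3, m.yc[:, j2] / 1e-3
    d1 = np.abs((c1x - fx) * nx + (c1y - fy) * ny)
    d2 = np.abs((c2x - fx) * nx + (c2y - fy) * ny)
    # tangential velocities (mm/s), relative gradient includes the wall value
    u1 = flow.u[:, :, j1] * tx + flow.v[:, :, j1] * ty
    u2 = flow.u[:, :, j2] * tx + flow.v[:, :, j2] * ty
    uw = wall_speed
    # quadratic one-sided wall gradient d(u_t)/dn at n = 0
    grad = ((u1 - uw) / d1 * (d2 / (d2 - d1))
            - (u2 - uw) / d2 * (d1 / (d2 - d1)))
    tau_t = mu * grad                               # Pa, (nt, ni)
    tau = np.stack([tau_t * tx, tau_t * ty], axis=2)
    if m.mode == "axisym":
        area = 2.0 * np.pi * (m.fj_cy[:, jw] / 1e-3) * el
    else:
        area = el * 1.0
    arc = m.fj_cx[:, jw] / 1e-3
    return tau, arc, area


def _periodic_integral(times: np.ndarray, values: np.ndarray, period: float):
    """Trapezoid over one period with a wrap-around closing segment."""
    span = times[-1] - times[0]
    if span > period * (1 + 1e-9):
        raise ValueError("samples span more than one period")
    integral = np.trapezoid(values, times, axis=0)
    gap = period - span
    if gap > 1e-9 * period:
        integral = integral + 0.5 * (values[0] + values[-1]) * gap
    return integral


def tawss(wss: WallShearField, period: float | None = None) -> np.ndarray:
    """Time-averaged WSS magnitude per wall element, Pa."""
    T = period or wss.period
    if T is None:
        raise ValueError("period required")
    if wss.times[-1] - wss.times[0] < 0.5 * T:
        raise ValueError("samples do not cover the cycle")
    return _periodic_integral(wss.times, wss.magnitude, T) / T


def osi(wss: WallShearField, period: float | None = None) -> np.ndarray:
    """Oscillatory shear index per wall element, in [0, 0.5]."""
    T = period or wss.period
    if T is None:
        raise ValueError("period required")
    if wss.times[-1] - wss.times[0] < 0.5 * T:
        raise ValueError("samples do not cover the cycle")
    mean_vec = _periodic_integral(wss.times, wss.tau, T)
    num = np.linalg.norm(mean_vec, axis=-1)
    den = _periodic_integral(wss.times, wss.magnitude, T)
    out = np.zeros_like(den)
    nz = den > 0
    out[nz] = 0.5 * (1.0 - num[nz] / den[nz])
    return np.clip(out, 0.0, 0.5)


def wall_metric_field(wss: WallShearField, period: float | None = None) -> WallMetricField:
    return WallMetricField(tawss=tawss(wss, period), osi=osi(wss, period),
                           arclength=wss.arclength, face_area=wss.face_area)


# ---------------------------------------------------------------------------
# Q-criterion
# ---------------------------------------------------------------------------

def velocity_gradient(flow: FlowField, k: int = 0) -> np.ndarray:
    """Cell-centred velocity-gradient tensor G[a,b] = d u_a / d x_b (1/s).

    Computed by index-space differencing with the metric Jacobian; second
    order in the interior, one-sided at boundary cells.
    """
    m = flow.mesh
    xc, yc = m.xc / 1e-3, m.yc / 1e-3     # mm
    u, v = flow.u[k], flow.v[k]           # mm/s
    dx_dxi, dx_deta = np.gradient(xc)
    dy_dxi, dy_deta = np.gradient(yc)
    det = dx_dxi * dy_deta - dx_deta * dy_dxi
    du_dxi, du_deta = np.gradient(u)
    dv_dxi, dv_deta = np.gradient(v)
    ux = (du_dxi * dy_deta - du_deta * dy_dxi) / det
    uy = (du_deta * dx_dxi - du_dxi * dx_deta) / det
    vx = (dv_dxi * dy_deta - dv_deta * dy_dxi) / det
    vy = (dv_deta * dx_dxi - dv_dxi * dx_deta) / det
    G = np.zeros(u.shape + (3, 3))
    G[..., 0, 0] = ux
    G[..., 0, 1] = uy
    G[..., 1, 0] = vx
    G[..., 1, 1] = vy
    if m.mode == "axisym":
        # no-swirl axisymmetric flow carries a hoop stretching term v/r
        G[..., 2, 2] = np.divide(v, yc, out=np.zeros_like(v), where=yc > 0)
    return G


def q_criterion(flow: FlowField) -> QCriterionField:
    """Q = 1/2 (||Omega||^2 - ||S||^2) per cell and stored sample, s^-2."""
    m = flow.mesh
    qs = []
    for k in range(flow.n_times):
        G = velocity_gradient(flow, k)
        S = 0.5 * (G + np.swapaxes(G, -1, -2))
        W = 0.5 * (G - np.swapaxes(G, -1, -2))
        qs.append(0.5 * ((W**2).sum(axis=(-2, -1)) - (S**2).sum(axis=(-2, -1))))
    boundary = np.zeros((m.ni, m.nj), bool)
    boundary[0, :] = boundary[-1, :] = True
    boundary[:, 0] = boundary[:, -1] = True
    return QCriterionField(q=np.asarray(qs), boundary_cell=boundary)


# ---------------------------------------------------------------------------
# Profiles and correlations
# ---------------------------------------------------------------------------

@dataclass
class ArclengthProfile:
    """Binned max / area-weighted-mean profile of a wall metric vs arclength."""

    bin_centers: np.ndarray
    max: np.ndarray          # NaN in empty bins (gaps, never interpolated)
    mean: np.ndarray
    count: np.ndarray

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"arclength_mm": self.bin_centers, "max": self.max,
                             "mean": self.mean, "n_elements": self.count})


def profile_by_arclength(values: np.ndarray, arclength: np.ndarray,
                         face_area: np.ndarray | None = None,
                         bin_width: float = 0.1,
                         s_range: tuple[float, float] | None = None) -> ArclengthProfile:
    """Bin a per-wall-element metric by centerline arclength (default 0.1 mm)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if s_range is None:
        s_range = (float(arclength.min()), float(arclength.max()))
    edges = np.arange(s_range[0], s_range[1] + bin_width, bin_width)
    nb = len(edges) - 1
    w = np.ones_like(values) if face_area is None else face_area
    idx = np.digitize(arclength, edges) - 1
    mx = np.full(nb, np.nan)
    mn = np.full(nb, np.nan)
    ct = np.zeros(nb, int)
    for b in range(nb):
        sel = idx == b
        ct[b] = sel.sum()
        if ct[b]:
            mx[b] = values[sel].max()
            mn[b] = np.average(values[sel], weights=w[sel])
    return ArclengthProfile(bin_centers=0.5 * (edges[:-1] + edges[1:]),
                            max=mx, mean=mn, count=ct)


def window_average(values: np.ndarray, arclength: np.ndarray,
                   window: tuple[float, float],
                   face_area: np.ndarray | None = None) -> float:
    """Area-weighted mean of a wall metric over an arclength window."""
    sel = (arclength >= window[0]) & (arclength < window[1])
    if not sel.any():
        raise ValueError(f"window {window} contains no wall elements")
    w = None if face_area is None else face_area[sel]
    return float(np.average(values[sel], weights=w))


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    degenerate: bool = False
    pairs: np.ndarray | None = None   # (n, 2) co-located values


def correlate(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Spearman rank correlation over co-located (finite) profile bins.

    Fewer than 5 paired bins raises; zero-variance inputs are flagged as
    degenerate (rho = NaN) rather than reported as 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 5:
        raise ValueError("need at least 5 paired bins for a rank correlation")
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return CorrelationResult(rho=float("nan"), p_value=float("nan"),
                                 n=int(ok.sum()), degenerate=True,
                                 pairs=np.column_stack([xs, ys]))
    rho, p = stats.spearmanr(xs, ys)
    return CorrelationResult(rho=float(rho), p_value=float(p), n=int(ok.sum()),
                             pairs=np.column_stack([xs, ys]))
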
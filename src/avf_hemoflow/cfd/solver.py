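"""Incompressible Navier-Stokes finite-volume solver (SIMPLE, collocated).

Solves the incompressible Navier-Stokes equations

    rho (du/dt + u . grad u) = -grad p + mu lap u,   div u = 0

for Newtonian blood in rigid-walled 2-D planar or axisymmetric body-fitted
domains, with the numerical policy of the study pipeline: backward-Euler time
discretization, second-order (linear) upwind convection with a first-order
fallback, SIMPLE pressure-velocity coupling with Rhie-Chow face interpolation,
residual convergence to 1e-6, time step bounded by a target CFL number of 0.1,
and three simulated cardiac cycles with only the final cycle retained for
analysis.  Velocity boundary conditions (parabolic profiles driven by Doppler
waveforms) are applied at the inlet; the outlet holds zero pressure (all
pressures are relative to the venous outlet); walls are no-slip.

Interfaces use mm and mm/s; the solver works in SI internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ..synthgen import VelocityWaveform
from .mesh import StructuredMesh2D

__all__ = [
    "BloodModel",
    "SolverConfig",
    "FlowField",
    "SolverDivergedError",
    "solve_steady",
    "solve_pulsatile",
]


@dataclass(frozen=True)
class BloodModel:
    """Newtonian blood: density (kg/m^3) and dynamic viscosity (Pa.s)."""

    density: float = 1040.0
    dynamic_viscosity: float = 4.0e-3

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("density and viscosity must be positive")


@dataclass
class SolverConfig:
    cfl_target: float = 0.1          # max cell CFL for the fixed time step
    n_cycles: int = 3                # cardiac cycles; final cycle stored
    convergence_tol: float = 1e-6    # normalized residual target
    scheme: str = "upwind2"          # 'upwind1' or 'upwind2' (linear upwind)
    max_inner: int = 40              # SIMPLE iterations per time step
    max_outer: int = 3000            # SIMPLE iterations for a steady solve
    alpha_u: float = 0.7             # momentum under-relaxation (steady)
    alpha_p: float = 0.7             # pressure under-relaxation (steady, SIMPLEC)
    alpha_u_transient: float = 0.95  # relaxation within a time step (diagonal is
    alpha_p_transient: float = 1.0   # dominated by rho V/dt, so little is needed)
    min_steps_per_cycle: int = 400   # temporal-accuracy floor (dt never exceeds T/this)
    store_max: int = 80              # stored samples of the final cycle
    continue_on_inner_nonconvergence: bool = True

    def __post_init__(self) -> None:
        if self.cfl_target <= 0 or self.n_cycles < 1 or self.convergence_tol <= 0:
            raise ValueError("invalid solver configuration")
        if self.scheme not in ("upwind1", "upwind2"):
            raise ValueError("scheme must be 'upwind1' or 'upwind2'")


class SolverDivergedError(RuntimeError):
    def __init__(self, msg, residual_history=None, step=None):
        super().__init__(msg)
        self.residual_history = residual_history or []
        self.step = step


@dataclass
class FlowField:
    """Velocity/pressure samples on a mesh (final cycle for pulsatile runs).

    ``u``/``v`` are axial/cross-stream velocity components in mm/s with shape
    (n_times, ni, nj); ``p`` is pressure in Pa relative to the outlet.
    """

    mesh: StructuredMesh2D
    times: np.ndarray
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    period: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_times(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# Core SIMPLE machinery
# ---------------------------------------------------------------------------

class _Simple:
    """Assembled-once geometry + SIMPLE iteration machinery for one mesh."""

    def __init__(self, mesh: StructuredMesh2D, blood: BloodModel, cfg: SolverConfig,
                 wall_velocity: dict[str, tuple[float, float]] | None = None):
        self.m = mesh
        self.blood = blood
        self.cfg = cfg
        self.rho = blood.density
        self.mu = blood.dynamic_viscosity
        ni, nj = mesh.ni, mesh.nj
        self.n = ni * nj
        self.K = np.arange(self.n).reshape(ni, nj)
        # moving-wall tangential velocities (m/s), e.g. Couette's driven lid
        self.wall_u = {k: (np.asarray(vv, float) * 1e-3)
                       for k, vv in (wall_velocity or {}).items()}
        self.alpha_u = cfg.alpha_u
        self.alpha_p = cfg.alpha_p
        self._precompute()
        self.u = np.zeros((ni, nj))
        self.v = np.zeros((ni, nj))
        self.p = np.zeros((ni, nj))
        self.Fi = np.zeros((ni + 1, nj))   # mass flux (kg/s) through i-faces, +i sense
        self.Fj = np.zeros((ni, nj + 1))
        self.inlet_u = np.zeros(nj)        # inlet axial velocity per west face (m/s)
        self._pc_cache = None              # cached pressure-correction LU + coeffs
        self._pc_age = 0

    # -- geometry -------------------------------------------------------------

    def _precompute(self) -> None:
        m = self.m
        ni, nj = m.ni, m.nj
        K = self.K
        # interior i-faces (face index 1..ni-1)
        self.iP = K[:-1, :].ravel()
        self.iN = K[1:, :].ravel()
        Sx = m.fi_Sx[1:ni].ravel()
        Sy = m.fi_Sy[1:ni].ravel()
        dx = (m.xc[1:, :] - m.xc[:-1, :]).ravel()
        dy = (m.yc[1:, :] - m.yc[:-1, :]).ravel()
        Sd = Sx * dx + Sy * dy
        self.i_gD = (Sx**2 + Sy**2) / Sd
        self.i_Sx, self.i_Sy = Sx, Sy
        self.i_dx, self.i_dy = dx, dy
        # non-orthogonal part T = S - d |S|^2/(S.d)
        self.i_Tx = Sx - dx * self.i_gD
        self.i_Ty = Sy - dy * self.i_gD
        fx = m.fi_cx[1:ni].ravel()
        fy = m.fi_cy[1:ni].ravel()
        dP = np.hypot(fx - m.xc[:-1, :].ravel(), fy - m.yc[:-1, :].ravel())
        dN = np.hypot(fx - m.xc[1:, :].ravel(), fy - m.yc[1:, :].ravel())
        self.i_wN = dP / (dP + dN)
        self.i_fx, self.i_fy = fx, fy

        # interior j-faces (face index 1..nj-1)
        self.jP = K[:, :-1].ravel()
        self.jN = K[:, 1:].ravel()
        Sx = m.fj_Sx[:, 1:nj].ravel()
        Sy = m.fj_Sy[:, 1:nj].ravel()
        dx = (m.xc[:, 1:] - m.xc[:, :-1]).ravel()
        dy = (m.yc[:, 1:] - m.yc[:, :-1]).ravel()
        Sd = Sx * dx + Sy * dy
        self.j_gD = (Sx**2 + Sy**2) / Sd
        self.j_Sx, self.j_Sy = Sx, Sy
        self.j_dx, self.j_dy = dx, dy
        self.j_Tx = Sx - dx * self.j_gD
        self.j_Ty = Sy - dy * self.j_gD
        fx = m.fj_cx[:, 1:nj].ravel()
        fy = m.fj_cy[:, 1:nj].ravel()
        dP = np.hypot(fx - m.xc[:, :-1].ravel(), fy - m.yc[:, :-1].ravel())
        dN = np.hypot(fx - m.xc[:, 1:].ravel(), fy - m.yc[:, 1:].ravel())
        self.j_wN = dP / (dP + dN)
        self.j_fx, self.j_fy = fx, fy

        # boundary faces: owner cells, outward weighted S, gD
        def _bgeom(Sx, Sy, fcx, fcy, cx, cy, sign):
            # zero-area faces (on the axis of symmetry, r = 0) carry no flux
            Sox, Soy = sign * Sx, sign * Sy
            dxb, dyb = fcx - cx, fcy - cy
            S2 = Sox**2 + Soy**2
            Sd = Sox * dxb + Soy * dyb
            gD = np.divide(S2, Sd, out=np.zeros_like(S2), where=S2 > 0)
            return Sox, Soy, gD

        self.w_cells = K[0, :]
        self.w_Sox, self.w_Soy, self.w_gD = _bgeom(
            m.fi_Sx[0], m.fi_Sy[0], m.fi_cx[0], m.fi_cy[0],
            m.xc[0, :], m.yc[0, :], -1.0)
        self.e_cells = K[-1, :]
        self.e_Sox, self.e_Soy, self.e_gD = _bgeom(
            m.fi_Sx[ni], m.fi_Sy[ni], m.fi_cx[ni], m.fi_cy[ni],
            m.xc[-1, :], m.yc[-1, :], 1.0)
        self.s_cells = K[:, 0]
        self.s_Sox, self.s_Soy, self.s_gD = _bgeom(
            m.fj_Sx[:, 0], m.fj_Sy[:, 0], m.fj_cx[:, 0], m.fj_cy[:, 0],
            m.xc[:, 0], m.yc[:, 0], -1.0)
        self.n_cells_b = K[:, -1]
        self.n_Sox, self.n_Soy, self.n_gD = _bgeom(
            m.fj_Sx[:, nj], m.fj_Sy[:, nj], m.fj_cx[:, nj], m.fj_cy[:, nj],
            m.xc[:, -1], m.yc[:, -1], 1.0)

        self.vol = m.vol.ravel()
        self.area_p = m.area.ravel()
        self.yc_flat = m.yc.ravel()
        self.axisym = m.mode == "axisym"

    # -- inlet ----------------------------------------------------------------

    def set_inlet_centerline_velocity(self, vc_mm_s: float) -> None:
        """Parabolic inlet profile with the given centerline velocity (mm/s)."""
        m = self.m
        r = m.fi_cy[0] / (m.Y_mm[0].max() * 1e-3)  # normalized cross-stream coord
        if m.bc["south"] in ("axis", "symmetry"):
            shape = 1.0 - r**2
        else:  # wall-to-wall channel, r in [0, 1]
            shape = 4.0 * r * (1.0 - r)
        self.set_inlet_profile_mm_s(vc_mm_s * shape)

    def set_inlet_profile_mm_s(self, u_mm_s: np.ndarray) -> None:
        """Arbitrary axial inlet velocity profile, one value per west face (mm/s)."""
        self.inlet_u = np.asarray(u_mm_s, float) * 1e-3
        # inlet mass fluxes are imposed exactly
        self.Fi[0] = self.rho * self.inlet_u * self.m.fi_Sx[0]

    def inlet_mass_flux(self) -> float:
        return float(self.Fi[0].sum())

    # -- gradients ------------------------------------------------------------

    def _green_gauss(self, phi_flat: np.ndarray, bvals: dict | None = None) -> tuple:
        """Planar Green-Gauss cell gradient; bvals overrides boundary face values."""
        m = self.m
        ni, nj = m.ni, m.nj
        phi = phi_flat.reshape(ni, nj)
        gx = np.zeros(self.n)
        gy = np.zeros(self.n)
        # interior i-faces
        pf = (1 - self.i_wN) * phi_flat[self.iP] + self.i_wN * phi_flat[self.iN]
        Sxp = m.fi_Sx_p[1:ni].ravel()
        Syp = m.fi_Sy_p[1:ni].ravel()
        np.add.at(gx, self.iP, pf * Sxp)
        np.add.at(gy, self.iP, pf * Syp)
        np.add.at(gx, self.iN, -pf * Sxp)
        np.add.at(gy, self.iN, -pf * Syp)
        # interior j-faces
        pf = (1 - self.j_wN) * phi_flat[self.jP] + self.j_wN * phi_flat[self.jN]
        Sxp = m.fj_Sx_p[:, 1:nj].ravel()
        Syp = m.fj_Sy_p[:, 1:nj].ravel()
        np.add.at(gx, self.jP, pf * Sxp)
        np.add.at(gy, self.jP, pf * Syp)
        np.add.at(gx, self.jN, -pf * Sxp)
        np.add.at(gy, self.jN, -pf * Syp)
        # boundaries (outward planar S)
        bvals = bvals or {}
        for side, cells, Sxb, Syb, sign, _unused in (
            ("west", self.w_cells, m.fi_Sx_p[0], m.fi_Sy_p[0], -1.0, None),
            ("east", self.e_cells, m.fi_Sx_p[ni], m.fi_Sy_p[ni], 1.0, None),
            ("south", self.s_cells, m.fj_Sx_p[:, 0], m.fj_Sy_p[:, 0], -1.0, None),
            ("north", self.n_cells_b, m.fj_Sx_p[:, nj], m.fj_Sy_p[:, nj], 1.0, None),
        ):
            pb = bvals.get(side)
            if pb is None:
                pb = phi_flat[cells]
            gx[cells] += pb * sign * Sxb
            gy[cells] += pb * sign * Syb
        return gx / self.area_p, gy / self.area_p

    # -- momentum assembly ----------------------------------------------------

    def _face_phi_corr(self, F, phi, gx, gy, P, N, fx, fy):
        """Deferred second-order-upwind correction F*(phi_HO - phi_UP) per face."""
        up = np.where(F >= 0, P, N)
        xc, yc = self.m.xc.ravel(), self.m.yc.ravel()
        dxi = fx - xc[up]
        dyi = fy - yc[up]
        return F * (gx[up] * dxi + gy[up] * dyi)

    def _assemble_momentum(self, dt: float | None, u_old, v_old):
        """Build the u and v momentum systems; returns (Au, bu, Av, bv, diag)."""
        mu, rho = self.mu, self.rho
        n = self.n
        uf, vf = self.u.ravel(), self.v.ravel()
        pf = self.p.ravel()
        gu_x, gu_y = self._green_gauss(uf, self._vel_bvals("u"))
        gv_x, gv_y = self._green_gauss(vf, self._vel_bvals("v"))
        gp_x, gp_y = self._green_gauss(pf, {"east": np.zeros(self.m.nj)})
        self._gp = (gp_x, gp_y)

        diag = np.zeros(n)
        sumoff = np.zeros(n)   # row sums of (negative) off-diagonal coefficients
        rows, cols, vals = [], [], []
        bu = np.zeros(n)
        bv = np.zeros(n)

        for (P, N, gD, F, Tx, Ty, ffx, ffy) in (
            (self.iP, self.iN, self.i_gD, self.Fi[1:self.m.ni].ravel(),
             self.i_Tx, self.i_Ty, self.i_fx, self.i_fy),
            (self.jP, self.jN, self.j_gD, self.Fj[:, 1:self.m.nj].ravel(),
             self.j_Tx, self.j_Ty, self.j_fx, self.j_fy),
        ):
            Fp = np.maximum(F, 0.0)
            Fm = np.minimum(F, 0.0)
            aPN = Fm - mu * gD          # coeff of phi_N in row P
            aNP = -Fp - mu * gD         # coeff of phi_P in row N
            np.add.at(diag, P, Fp + mu * gD)
            np.add.at(diag, N, -Fm + mu * gD)
            rows.append(P); cols.append(N); vals.append(aPN)
            rows.append(N); cols.append(P); vals.append(aNP)
            np.add.at(sumoff, P, aPN)
            np.add.at(sumoff, N, aNP)
            # explicit non-orthogonal diffusion correction
            guf_x = 0.5 * (gu_x[P] + gu_x[N])
            guf_y = 0.5 * (gu_y[P] + gu_y[N])
            gvf_x = 0.5 * (gv_x[P] + gv_x[N])
            gvf_y = 0.5 * (gv_y[P] + gv_y[N])
            cu = mu * (guf_x * Tx + guf_y * Ty)
            cv = mu * (gvf_x * Tx + gvf_y * Ty)
            np.add.at(bu, P, cu)
            np.add.at(bu, N, -cu)
            np.add.at(bv, P, cv)
            np.add.at(bv, N, -cv)
            if self.cfg.scheme == "upwind2":
                su = self._face_phi_corr(F, uf, gu_x, gu_y, P, N, ffx, ffy)
                sv = self._face_phi_corr(F, vf, gv_x, gv_y, P, N, ffx, ffy)
                np.add.at(bu, P, -su)
                np.add.at(bu, N, su)
                np.add.at(bv, P, -sv)
                np.add.at(bv, N, sv)

        # boundaries
        diag_v_extra = np.zeros(n)
        self._bc_momentum(diag, bu, bv, diag_v_extra)

        # pressure force (weighted areas) with boundary face pressures
        px_sum, py_sum = self._pressure_face_sum(pf)
        bu -= px_sum
        bv -= py_sum
        if self.axisym:
            bv += pf * self.vol / self.yc_flat              # -dp/dr metric source
            diag_v_extra += mu * self.vol / self.yc_flat**2  # -mu v / r^2 sink

        if dt is not None:
            tcoef = rho * self.vol / dt
            diag += tcoef
            bu += tcoef * u_old.ravel()
            bv += tcoef * v_old.ravel()

        # under-relaxation
        alpha = self.alpha_u
        diag_u = diag / alpha
        diag_v = (diag + diag_v_extra) / alpha
        bu += (1 - alpha) / alpha * diag * uf
        bv += (1 - alpha) / alpha * (diag + diag_v_extra) * vf

        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        Au = sp.csr_matrix((np.concatenate([vals, diag_u]),
                            (np.concatenate([rows, np.arange(n)]),
                             np.concatenate([cols, np.arange(n)]))), shape=(n, n))
        Av = sp.csr_matrix((np.concatenate([vals, diag_v]),
                            (np.concatenate([rows, np.arange(n)]),
                             np.concatenate([cols, np.arange(n)]))), shape=(n, n))
        self._aP = diag_u  # relaxed diagonal
        # SIMPLEC: correction coefficient uses a_P - sum|a_nb| (consistent
        # neighbour approximation), which tolerates alpha_p near 1
        self._dP = np.maximum(diag_u + sumoff, 1e-30)
        return Au, bu, Av, bv

    def _vel_bvals(self, comp: str) -> dict:
        """Boundary face values of a velocity component for gradient reconstruction."""
        nj, ni = self.m.nj, self.m.ni
        out = {}
        out["west"] = self.inlet_u.copy() if comp == "u" else np.zeros(nj)
        wall_n = self.wall_u.get("north", (0.0, 0.0))
        out["north"] = np.full(ni, wall_n[0] if comp == "u" else wall_n[1])
        south = self.m.bc["south"]
        if south == "wall":
            wall_s = self.wall_u.get("south", (0.0, 0.0))
            out["south"] = np.full(ni, wall_s[0] if comp == "u" else wall_s[1])
        elif comp == "v":
            out["south"] = np.zeros(ni)   # axis/symmetry: v = 0
        return out

    def _pressure_face_sum(self, pf) -> tuple[np.ndarray, np.ndarray]:
        """Sum of p_f * S_outward (weighted) over each cell's faces."""
        m = self.m
        ni, nj = m.ni, m.nj
        px = np.zeros(self.n)
        py = np.zeros(self.n)
        pint = (1 - self.i_wN) * pf[self.iP] + self.i_wN * pf[self.iN]
        np.add.at(px, self.iP, pint * self.i_Sx)
        np.add.at(py, self.iP, pint * self.i_Sy)
        np.add.at(px, self.iN, -pint * self.i_Sx)
        np.add.at(py, self.iN, -pint * self.i_Sy)
        pint = (1 - self.j_wN) * pf[self.jP] + self.j_wN * pf[self.jN]
        np.add.at(px, self.jP, pint * self.j_Sx)
        np.add.at(py, self.jP, pint * self.j_Sy)
        np.add.at(px, self.jN, -pint * self.j_Sx)
        np.add.at(py, self.jN, -pint * self.j_Sy)
        # boundaries: zero-gradient everywhere except the zero-pressure outlet
        px[self.w_cells] += pf[self.w_cells] * self.w_Sox
        py[self.w_cells] += pf[self.w_cells] * self.w_Soy
        px[self.s_cells] += pf[self.s_cells] * self.s_Sox
        py[self.s_cells] += pf[self.s_cells] * self.s_Soy
        px[self.n_cells_b] += pf[self.n_cells_b] * self.n_Sox
        py[self.n_cells_b] += pf[self.n_cells_b] * self.n_Soy
        # east outlet: p_b = 0 -> contributes nothing
        return px, py

    def _bc_momentum(self, diag, bu, bv, diag_v_extra) -> None:
        mu = self.mu
        # west inlet: Dirichlet (inlet_u, 0); inflow convection + diffusion
        cells = self.w_cells
        Fb_in = self.Fi[0]                      # positive into the domain
        np.add.at(diag, cells, mu * self.w_gD)
        bu[cells] += mu * self.w_gD * self.inlet_u + np.maximum(Fb_in, 0) * self.inlet_u
        # (v_b = 0 contributes nothing to bv; outflow at an inlet not supported)
        # east outlet: zero-gradient, outflow convection only
        cells = self.e_cells
        Fb_out = self.Fi[self.m.ni]
        np.add.at(diag, cells, np.maximum(Fb_out, 0.0))
        # north wall: Dirichlet
        cells = self.n_cells_b
        wall_n = self.wall_u.get("north", (0.0, 0.0))
        np.add.at(diag, cells, mu * self.n_gD)
        bu[cells] += mu * self.n_gD * wall_n[0]
        bv[cells] += mu * self.n_gD * wall_n[1]
        # south: wall (Dirichlet) or axis/symmetry (v = 0 only, u zero-gradient)
        cells = self.s_cells
        south = self.m.bc["south"]
        if south == "wall":
            wall_s = self.wall_u.get("south", (0.0, 0.0))
            np.add.at(diag, cells, mu * self.s_gD)
            bu[cells] += mu * self.s_gD * wall_s[0]
            bv[cells] += mu * self.s_gD * wall_s[1]
        else:
            # axis/symmetry: u zero-gradient (no flux); v antisymmetric -> v_b = 0,
            # a Dirichlet condition in the v-equation only
            np.add.at(diag_v_extra, cells, mu * self.s_gD)

    # -- Rhie-Chow fluxes and pressure correction -----------------------------

    def _update_face_fluxes(self) -> None:
        rho = self.rho
        uf, vf = self.u.ravel(), self.v.ravel()
        gp_x, gp_y = self._gp
        VoA = self.vol / self._dP
        m = self.m
        ni, nj = m.ni, m.nj
        pf = self.p.ravel()
        for (P, N, wN, gD, Sx, Sy, dxv, dyv, store, sl) in (
            (self.iP, self.iN, self.i_wN, self.i_gD, self.i_Sx, self.i_Sy,
             self.i_dx, self.i_dy, self.Fi, (slice(1, ni), slice(None))),
            (self.jP, self.jN, self.j_wN, self.j_gD, self.j_Sx, self.j_Sy,
             self.j_dx, self.j_dy, self.Fj, (slice(None), slice(1, nj))),
        ):
            ufc = (1 - wN) * uf[P] + wN * uf[N]
            vfc = (1 - wN) * vf[P] + wN * vf[N]
            gpd = 0.5 * ((gp_x[P] + gp_x[N]) * dxv + (gp_y[P] + gp_y[N]) * dyv)
            Dhat = 0.5 * (VoA[P] + VoA[N]) * gD
            F = rho * (ufc * Sx + vfc * Sy) + rho * Dhat * (gpd - (pf[N] - pf[P]))
            store[sl] = F.reshape(store[sl].shape)
            if store is self.Fi:
                self._i_Dhat = Dhat
            else:
                self._j_Dhat = Dhat
        # outlet: zero-gradient velocity flux (corrected by p')
        self.Fi[ni] = rho * (uf[self.e_cells] * self.e_Sox
                             + vf[self.e_cells] * self.e_Soy)
        self._e_Dhat = VoA[self.e_cells] * self.e_gD
        # walls / axis: no flux
        self.Fj[:, 0] = 0.0
        self.Fj[:, nj] = 0.0

    def _pressure_correction(self):
        rho = self.rho
        n = self.n
        ni, nj = self.m.ni, self.m.nj
        imb = (self.Fi[1:] - self.Fi[:-1] + self.Fj[:, 1:] - self.Fj[:, :-1]).ravel()
        # The p' matrix varies slowly (through a_P only), and using slightly
        # stale coefficients changes the iteration path, not the fixed point:
        # fluxes are corrected with the same cached coefficients, so discrete
        # continuity is enforced exactly at every iteration.  Refresh the LU
        # every few iterations.
        if self._pc_cache is None or self._pc_age >= 10:
            ai = rho * self._i_Dhat
            aj = rho * self._j_Dhat
            a_e = rho * self._e_Dhat
            diag = np.zeros(n)
            np.add.at(diag, self.iP, ai)
            np.add.at(diag, self.iN, ai)
            np.add.at(diag, self.jP, aj)
            np.add.at(diag, self.jN, aj)
            np.add.at(diag, self.e_cells, a_e)
            A = sp.csc_matrix(
                (np.concatenate([-ai, -ai, -aj, -aj, diag]),
                 (np.concatenate([self.iP, self.iN, self.jP, self.jN,
                                  np.arange(n)]),
                  np.concatenate([self.iN, self.iP, self.jN, self.jP,
                                  np.arange(n)]))), shape=(n, n))
            self._pc_cache = (spla.splu(A), ai, aj, a_e)
            self._pc_age = 0
        self._pc_age += 1
        lu, ai, aj, a_e = self._pc_cache
        pc = lu.solve(-imb)
        # corrections
        self.p += self.alpha_p * pc.reshape(ni, nj)
        gpc_x, gpc_y = self._green_gauss(pc, {"east": np.zeros(nj)})
        VoA = self.vol / self._dP
        self.u -= (VoA * gpc_x).reshape(ni, nj)
        self.v -= (VoA * gpc_y).reshape(ni, nj)
        self.Fi[1:ni] += (ai * (pc[self.iP] - pc[self.iN])).reshape(ni - 1, nj)
        self.Fj[:, 1:nj] += (aj * (pc[self.jP] - pc[self.jN])).reshape(ni, nj - 1)
        self.Fi[ni] += a_e * pc[self.e_cells]
        return float(np.abs(imb).sum())

    # -- iteration ------------------------------------------------------------

    def iterate(self, dt=None, u_old=None, v_old=None):
        """One SIMPLE iteration; returns (momentum_residual, mass_residual)."""
        Au, bu, Av, bv = self._assemble_momentum(dt, u_old, v_old)
        uf = self.u.ravel()
        vf = self.v.ravel()
        res_u = np.abs(bu - Au @ uf).sum()
        res_v = np.abs(bv - Av @ vf).sum()
        norm = self._res_norm()
        transient = dt is not None
        self.u = self._solve_momentum(Au, bu, uf, transient).reshape(self.u.shape)
        self.v = self._solve_momentum(Av, bv, vf, transient).reshape(self.v.shape)
        self._update_face_fluxes()
        mass_imb = self._pressure_correction()
        mom_res = (res_u + res_v) / norm if norm > 0 else 0.0
        mass_res = mass_imb / max(abs(self.inlet_mass_flux()), 1e-300) \
            if abs(self.inlet_mass_flux()) > 0 else mass_imb
        return mom_res, mass_res

    def _solve_momentum(self, A, b, x0, transient):
        # transient systems are dominated by rho V/dt on the diagonal: a
        # Jacobi-preconditioned BiCGStab warm-started from the previous
        # iterate beats a fresh LU factorization
        if transient:
            M = sp.diags(1.0 / A.diagonal())
            # the RHS is dominated by the rho V/dt term, so the tolerance must
            # sit far below it for the outer 1e-6 residual target to be reachable
            atol = max(1e-16, 1e-12 * np.abs(b).sum())
            x, info = spla.bicgstab(A, b, x0=x0, M=M, atol=atol, rtol=1e-14,
                                    maxiter=300)
            if info == 0:
                return x
        return spla.spsolve(A, b)

    def _res_norm(self) -> float:
        u_scale = max(np.abs(self.inlet_u).max(), np.abs(self.u).max(),
                      np.abs(self.v).max())
        return self.rho * u_scale**2 * abs(self.m.fi_Sx[0]).sum() + 1e-300

    def net_boundary_flux_error(self) -> float:
        """|net boundary mass flux| / inflow (discrete global conservation)."""
        net = (self.Fi[-1].sum() - self.Fi[0].sum()
               + self.Fj[:, -1].sum() - self.Fj[:, 0].sum())
        inflow = abs(self.inlet_mass_flux())
        return abs(net) / inflow if inflow > 0 else abs(net)

    def snapshot(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.u * 1e3, self.v * 1e3, self.p.copy()  # mm/s, mm/s, Pa


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------

def _centerline_velocity_from_flow(mesh: StructuredMesh2D, q_mm3_s: float) -> float:
    """Centerline velocity (mm/s) of the parabolic inlet carrying q (mm^3/s)."""
    R = mesh.inlet_radius_mm()
    if mesh.bc["south"] in ("axis",):
        return 2.0 * q_mm3_s / (np.pi * R**2)
    if mesh.bc["south"] == "symmetry":   # half-channel, unit depth (mm)
        return 1.5 * q_mm3_s / R
    return 1.5 * q_mm3_s / R             # full channel, unit depth


def solve_steady(mesh: StructuredMesh2D, blood: BloodModel,
                 inlet_flow_mm3_s: float | None = None,
                 inlet_centerline_mm_s: float | None = None,
                 inlet_profile_mm_s: np.ndarray | None = None,
                 config: SolverConfig | None = None,
                 wall_velocity: dict | None = None) -> FlowField:
    """Steady SIMPLE solve; returns a single-sample :class:`FlowField`.

    The inlet carries a parabolic profile specified either by volumetric flow
    (mm^3/s) or centerline velocity (mm/s).  Raises
    :class:`SolverDivergedError` (with the residual history attached) if the
    residuals do not reach ``config.convergence_tol`` within
    ``config.max_outer`` iterations.
    """
    cfg = config or SolverConfig()
    s = _Simple(mesh, blood, cfg, wall_velocity)
    if inlet_profile_mm_s is not None:
        s.set_inlet_profile_mm_s(inlet_profile_mm_s)
    else:
        if inlet_centerline_mm_s is None:
            inlet_centerline_mm_s = (
                _centerline_velocity_from_flow(mesh, inlet_flow_mm3_s)
                if inlet_flow_mm3_s else 0.0)
        s.set_inlet_centerline_velocity(inlet_centerline_mm_s)
    history = []
    for it in range(cfg.max_outer):
        mom, mass = s.iterate()
        history.append((mom, mass))
        if not np.isfinite(mom):
            raise SolverDivergedError("steady solve diverged", history, it)
        if mom < cfg.convergence_tol and mass < cfg.convergence_tol and it > 2:
            break
    else:
        raise SolverDivergedError(
            f"steady solve did not converge in {cfg.max_outer} iterations "
            f"(last residuals {history[-1]})", history)
    u, v, p = s.snapshot()
    return FlowField(mesh=mesh, times=np.array([0.0]), u=u[None], v=v[None],
                     p=p[None],
                     metadata={"iterations": len(history),
                               "residuals": history[-1],
                               "mass_error": [s.net_boundary_flux_error()]})


def choose_dt(mesh: StructuredMesh2D, waveform: VelocityWaveform,
              config: SolverConfig) -> float:
    """Fixed time step: max cell CFL <= cfl_target at the peak velocity estimate.

    The velocity scale is the peak inlet centerline velocity amplified by the
    worst inlet-to-throat area ratio (mass conservation); dt is additionally
    capped at period/min_steps_per_cycle for temporal accuracy, then rounded
    down to an integer divisor of the period.
    """
    vc_peak = float(np.abs(waveform.velocities).max()) * 1e-3
    R = mesh.Y_mm[:, -1] * 1e-3
    if mesh.mode == "axisym":
        area = R**2
    else:
        area = R
    amp = float(area[0] / area.min())
    u_max = max(vc_peak * amp, 1e-12)
    # streamwise CFL: axial spacing over the local peak axial velocity (the
    # near-wall radial clustering does not constrain dt because both velocity
    # components vanish at the wall)
    dx_axial = float(np.abs(np.diff(mesh.X_mm, axis=0)).min()) * 1e-3
    dt_cfl = config.cfl_target * dx_axial / u_max
    dt = min(dt_cfl, waveform.period / config.min_steps_per_cycle)
    n_steps = int(np.ceil(waveform.period / dt))
    return waveform.period / n_steps


def solve_pulsatile(mesh: StructuredMesh2D, blood: BloodModel,
                    waveform: VelocityWaveform,
                    config: SolverConfig | None = None) -> FlowField:
    """Pulsatile solve over ``config.n_cycles`` cycles; final cycle stored.

    The inlet carries a parabolic profile whose centerline velocity follows
    ``waveform``; backward-Euler stepping with per-step SIMPLE inner
    iterations to ``convergence_tol`` (capped at ``max_inner``, warning or
    error per ``continue_on_inner_nonconvergence``).
    """
    import warnings as _w

    cfg = config or SolverConfig()
    s = _Simple(mesh, blood, cfg)
    s.alpha_u = cfg.alpha_u_transient
    s.alpha_p = cfg.alpha_p_transient
    dt = choose_dt(mesh, waveform, cfg)
    n_per_cycle = int(round(waveform.period / dt))
    n_total = n_per_cycle * cfg.n_cycles
    store_every = max(1, n_per_cycle // cfg.store_max)
    times, us, vs, ps, mass_err = [], [], [], [], []
    inner_hist = []
    n_unconverged = 0
    for step in range(1, n_total + 1):
        t = step * dt
        s.set_inlet_centerline_velocity(float(waveform(t)))
        u_old, v_old = s.u.copy(), s.v.copy()
        inner = 0
        for inner in range(1, cfg.max_inner + 1):
            mom, mass = s.iterate(dt=dt, u_old=u_old, v_old=v_old)
            if not np.isfinite(mom) or np.abs(s.u).max() * 1e3 > 1e7:
                raise SolverDivergedError(
                    f"pulsatile solve diverged at step {step}", inner_hist, step)
            if mom < cfg.convergence_tol and mass < cfg.convergence_tol:
                break
        else:
            if not cfg.continue_on_inner_nonconvergence:
                raise SolverDivergedError(
                    f"inner iterations did not converge at step {step}",
                    inner_hist, step)
            n_unconverged += 1
        inner_hist.append(inner)
        in_final = step > n_total - n_per_cycle
        if in_final and ((step - (n_total - n_per_cycle)) % store_every == 0):
            u, v, p = s.snapshot()
            times.append(t - (cfg.n_cycles - 1) * waveform.period)
            us.append(u); vs.append(v); ps.append(p)
            mass_err.append(s.net_boundary_flux_error())
    if n_unconverged:
        _w.warn(f"inner iterations hit max_inner on {n_unconverged} of "
                f"{n_total} steps (continuing per config)")
    return FlowField(mesh=mesh, times=np.asarray(times), u=np.asarray(us),
                     v=np.asarray(vs), p=np.asarray(ps), period=waveform.period,
                     metadata={"dt": dt, "steps_per_cycle": n_per_cycle,
                               "inner_iterations": inner_hist,
                               "n_unconverged_steps": n_unconverged,
                               "mass_error": mass_err})
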
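#!/usr/bin/env python
"""Validate the flow solver against closed-form laminar solutions.

Three checks: steady Poiseuille tube flow (centerline velocity, pressure
gradient, wall shear), oscillatory Womersley flow at Womersley number 3
(centerline amplitude and phase of the fundamental harmonic), and the
three-resolution grid-independence study on the synthetic AVF flow path.
"""

import json
from pathlib import Path

import numpy as np

from avf_hemoflow.cfd import analytic
from avf_hemoflow.cfd.harness import (AVF_GRID_STATIONS_MM,
                                      default_avf_mesh_family, grid_independence)
from avf_hemoflow.cfd.mesh import tube_mesh
from avf_hemoflow.cfd.solver import (BloodModel, SolverConfig, solve_pulsatile,
                                     solve_steady)
from avf_hemoflow.synthgen import AVFShapeParams, VelocityWaveform, make_avf_geometry
from avf_hemoflow.wall_metrics import wall_shear

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
OUT.mkdir(exist_ok=True)
blood = BloodModel()
report = {}

# --- Poiseuille ------------------------------------------------------------
Q, R = 10.0, 0.25  # mm^3/s, mm
mesh = tube_mesh(R, length_mm=4.0, ni=40, nj=16)
flow = solve_steady(mesh, blood, inlet_flow_mm3_s=Q)
r0 = mesh.yc[mesh.ni // 2, 0] / 1e-3
uc_num = float(flow.u[0][mesh.ni // 2, 0])
uc_ref = analytic.poiseuille_centerline_velocity(Q, R) * (1 - (r0 / R) ** 2)
s = mesh.axial_s_mm
mid = slice(10, 30)
grad_num = float(-np.polyfit(s[mid], flow.p[0].mean(axis=1)[mid], 1)[0])
grad_ref = analytic.poiseuille_pressure_gradient(Q, R)
ws = wall_shear(flow)
tau_num = float(np.linalg.norm(ws.tau[0], axis=1)[mesh.ni // 2])
tau_ref = analytic.poiseuille_wall_shear(Q, R)
report["poiseuille"] = {
    "centerline_mm_s": {"numeric": uc_num, "analytic": uc_ref,
                        "rel_err": abs(uc_num - uc_ref) / uc_ref},
    "pressure_gradient_pa_mm": {"numeric": grad_num, "analytic": grad_ref,
                                "rel_err": abs(grad_num - grad_ref) / grad_ref},
    "wall_shear_pa": {"numeric": tau_num, "analytic": tau_ref,
                      "rel_err": abs(tau_num - tau_ref) / tau_ref},
}
print(f"Poiseuille: centerline err {report['poiseuille']['centerline_mm_s']['rel_err']:.2%}, "
      f"dp/ds err {report['poiseuille']['pressure_gradient_pa_mm']['rel_err']:.2%}, "
      f"WSS err {report['poiseuille']['wall_shear_pa']['rel_err']:.2%}")

# --- Womersley alpha = 3 ---------------------------------------------------
alpha, Rw = 3.0, 0.5
omega = blood.dynamic_viscosity * alpha**2 / (blood.density * (Rw * 1e-3) ** 2)
T = 2 * np.pi / omega
t = np.linspace(0, T, 129)
V0, eps = 20.0, 0.8
wf = VelocityWaveform(times=t, velocities=V0 * (1 + eps * np.sin(2 * np.pi * t / T)),
                      period=T, heart_rate=60 / T)
wmesh = tube_mesh(Rw, length_mm=3.0, ni=16, nj=24)
wflow = solve_pulsatile(wmesh, blood, wf,
                        SolverConfig(min_steps_per_cycle=400, store_max=100))
uc = wflow.u[:, wmesh.ni // 2, 0]
amp, phase = analytic.fit_harmonic(wflow.times, uc, T)
uhat = analytic.womersley_centerline_per_flux(alpha, Rw) \
    * (-1j * eps * V0 * np.pi * Rw**2 / 2)
dphi = float((phase - np.angle(uhat) + np.pi) % (2 * np.pi) - np.pi)
report["womersley"] = {
    "alpha": alpha, "period_s": T,
    "amplitude_mm_s": {"numeric": float(amp), "analytic": float(abs(uhat)),
                       "rel_err": float(abs(amp - abs(uhat)) / abs(uhat))},
    "phase_error_rad": dphi,
}
print(f"Womersley (alpha=3): amplitude err "
      f"{report['womersley']['amplitude_mm_s']['rel_err']:.2%}, "
      f"phase err {dphi:.4f} rad")

# --- Grid independence on the synthetic AVF --------------------------------
geom = make_avf_geometry(AVFShapeParams.day7())
rep = grid_independence(default_avf_mesh_family(geom), blood, 22.17,
                        stations_mm=AVF_GRID_STATIONS_MM)
report["grid_independence"] = {
    "n_cells": rep.n_cells,
    "velocity_diff_pct": rep.velocity_diff_pct,
    "pressure_diff_pct": rep.pressure_diff_pct,
    "medium_vs_fine_max_pct": rep.max_diff_pct[-1],
    "independent_at_1pct": rep.independent,
}
print(f"Grid independence {rep.n_cells}: coarse-medium {rep.max_diff_pct[0]:.2f}%, "
      f"medium-fine {rep.max_diff_pct[-1]:.2f}% -> "
      f"{'independent' if rep.independent else 'NOT independent'} at 1%")

(OUT / "solver_validation.json").write_text(json.dumps(report, indent=1))
print(f"wrote {OUT / 'solver_validation.json'}")
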
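"""Closed-form laminar pipe/channel flows used as solver validation oracles.

These are textbook solutions (Poiseuille steady flow; Womersley oscillatory
flow driven by a harmonic pressure gradient) evaluated independently of the
finite-volume discretization.
"""

from __future__ import annotations

import numpy as np
from scipy.special import jv

__all__ = [
    "poiseuille_centerline_velocity",
    "poiseuille_pressure_gradient",
    "poiseuille_wall_shear",
    "womersley_number",
    "womersley_profile",
    "womersley_centerline_series",
]


def poiseuille_centerline_velocity(q_mm3_s: float, radius_mm: float) -> float:
    """Centerline velocity 2Q/(pi R^2) of steady tube flow, mm/s."""
    return 2.0 * q_mm3_s / (np.pi * radius_mm**2)


def poiseuille_pressure_gradient(q_mm3_s: float, radius_mm: float,
                                 viscosity: float = 4e-3) -> float:
    """Axial pressure gradient magnitude 8 mu Q/(pi R^4), Pa/mm."""
    q = q_mm3_s * 1e-9
    r = radius_mm * 1e-3
    return 8.0 * viscosity * q / (np.pi * r**4) * 1e-3


def poiseuille_wall_shear(q_mm3_s: float, radius_mm: float,
                          viscosity: float = 4e-3) -> float:
    """Wall shear stress magnitude 4 mu Q/(pi R^3), Pa."""
    q = q_mm3_s * 1e-9
    r = radius_mm * 1e-3
    return 4.0 * viscosity * q / (np.pi * r**3)


def womersley_number(radius_mm: float, period_s: float, density: float = 1040.0,
                     viscosity: float = 4e-3) -> float:
    """alpha = R sqrt(omega rho / mu) with omega = 2 pi / T."""
    omega = 2.0 * np.pi / period_s
    return radius_mm * 1e-3 * np.sqrt(omega * density / viscosity)


def _womersley_shape(r_over_R: np.ndarray, alpha: float) -> np.ndarray:
    """Complex profile (1 - J0(i^1.5 a r/R)/J0(i^1.5 a)) of the harmonic mode."""
    i32 = 1j ** 1.5
    return 1.0 - jv(0, i32 * alpha * np.asarray(r_over_R)) / jv(0, i32 * alpha)


def womersley_profile(r_over_R, alpha: float, t_over_T, k_amplitude: float = 1.0):
    """Oscillatory tube-flow axial velocity, arbitrary units.

    Driven by the pressure gradient -dp/dz = K cos(omega t); the velocity is
    Re{ (i K / (rho omega)) [1 - J0(i^1.5 a r/R)/J0(i^1.5 a)] e^{i omega t} }
    with the prefactor absorbed into ``k_amplitude`` = K/(rho omega).
    """
    shape = _womersley_shape(r_over_R, alpha)
    phase = np.exp(1j * 2.0 * np.pi * np.atleast_1d(t_over_T))
    return np.real(1j * k_amplitude * np.outer(phase, shape)).squeeze()


def womersley_centerline_series(alpha: float, t_over_T,
                                k_amplitude: float = 1.0) -> np.ndarray:
    """Centerline (r = 0) velocity over time for the harmonic mode."""
    return womersley_profile(np.array([0.0]), alpha, t_over_T, k_amplitude)


def womersley_centerline_per_flux(alpha: float, radius_mm: float) -> complex:
    """Complex ratio of centerline velocity to volumetric flux, harmonic mode.

    For the fully developed oscillatory mode at Womersley number ``alpha``,
    returns C such that the complex centerline-velocity amplitude (mm/s) is
    C times the complex flux amplitude (mm^3/s).  Encodes both the amplitude
    attenuation and the phase lead of the centerline velocity relative to the
    flux as alpha grows.
    """
    lam = 1j ** 1.5 * alpha
    center = 1.0 - 1.0 / jv(0, lam)
    flux_shape = 1.0 - 2.0 * jv(1, lam) / (lam * jv(0, lam))
    return center / (np.pi * radius_mm**2 * flux_shape)


def fit_harmonic(times: np.ndarray, values: np.ndarray, period: float):
    """Least-squares amplitude and phase of the fundamental harmonic.

    Returns (amplitude, phase_rad) of A cos(omega t + phi) fitted to the
    samples; used to compare solver output with the analytic oscillation.
    """
    w = 2.0 * np.pi / period
    M = np.column_stack([np.cos(w * times), np.sin(w * times),
                         np.ones_like(times)])
    coef, *_ = np.linalg.lstsq(M, values, rcond=None)
    a, b = coef[0], coef[1]
    return float(np.hypot(a, b)), float(np.arctan2(-b, a))
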
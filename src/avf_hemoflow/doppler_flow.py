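"""Doppler-derived volumetric flow estimation and inlet boundary profiles.

Flow rates follow the clinical convention Q = A * Vbar with the mean velocity
taken as half the centerline (peak) Doppler velocity — the parabolic-profile
assumption.  An optional 1/cos(beam angle) correction can be applied to the
measured velocities; it is off by default since insonation angles are only
bounded, not recorded, in typical protocols.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthgen import VelocityWaveform

__all__ = [
    "DopplerMeasurement",
    "FlowSummary",
    "flow_rate",
    "flow_split",
    "inlet_profile",
]

MM3_PER_S_TO_ML_PER_MIN = 60.0 / 1000.0


@dataclass
class DopplerMeasurement:
    """A PW-Doppler acquisition site: peak-velocity waveform plus lumen area."""

    site: str                    # 'proximal_artery', 'distal_artery' or 'avf'
    waveform: VelocityWaveform   # centerline/peak velocities, mm/s
    area: float                  # mm^2, lumen cross-section at the site (from CT)
    beam_angle: float | None = None  # degrees; None = no angle correction

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("area must be > 0")
        if self.beam_angle is not None and not 0 <= self.beam_angle < 90:
            raise ValueError("beam_angle must lie in [0, 90) degrees")


@dataclass
class FlowSummary:
    """Branch flow distribution around the AVF junction."""

    q_proximal: float            # mL/min
    q_avf: float                 # mL/min
    q_distal: float              # mL/min (flow away from the junction)
    avf_fraction: float          # q_avf / q_proximal
    conservation_residual: float  # |q_prox - q_avf - q_dist| / q_prox


def flow_rate(measurement: DopplerMeasurement) -> float:
    """Mean volumetric flow, mL/min: Q = A x (time-mean peak velocity)/2.

    If a beam angle is supplied the measured velocities are first corrected by
    1/cos(angle).  Conversion: mm^3/s x 60/1000 = mL/min.
    """
    v_mean_peak = measurement.waveform.mean()  # mm/s
    if measurement.beam_angle is not None:
        v_mean_peak /= np.cos(np.deg2rad(measurement.beam_angle))
    q_mm3_s = measurement.area * v_mean_peak / 2.0
    return q_mm3_s * MM3_PER_S_TO_ML_PER_MIN


def flow_split(q_prox: float, q_avf: float, q_dist: float) -> FlowSummary:
    """Flow fractions at the junction; the distal artery carries flow away.

    The conservation residual |q_prox - q_avf - q_dist| / q_prox is reported
    as-is, never clipped.
    """
    if q_prox <= 0:
        raise ValueError("proximal flow must be > 0")
    return FlowSummary(
        q_proximal=q_prox, q_avf=q_avf, q_distal=q_dist,
        avf_fraction=q_avf / q_prox,
        conservation_residual=abs(q_prox - q_avf - q_dist) / q_prox)


def inlet_profile(waveform: VelocityWaveform, patch_radius: float,
                  radii: np.ndarray, times: np.ndarray | None = None) -> np.ndarray:
    """Time-dependent parabolic (Poiseuille) inlet velocity field.

    The waveform value is the centerline (peak) velocity; the spatial profile
    is ``v(r, t) = V(t) (1 - (r/R)^2)`` on a circular patch of radius ``R``, so
    the patch-mean velocity is V(t)/2 and the instantaneous flux A V(t)/2.

    Parameters
    ----------
    patch_radius : mm; must exceed every entry of ``radii``.
    radii : radial positions (mm) of the points to evaluate.
    times : evaluation times (s); defaults to the waveform's own samples.

    Returns an array of shape (n_times, n_points), mm/s, directed along the
    inward patch normal.
    """
    if patch_radius <= 0:
        raise ValueError("patch_radius must be > 0")
    radii = np.asarray(radii, dtype=float)
    if np.any(radii < 0) or np.any(radii > patch_radius * (1 + 1e-9)):
        raise ValueError("radii must lie within the patch")
    if times is None:
        times = waveform.times
    v_c = np.atleast_1d(waveform(times))
    shape = 1.0 - (radii / patch_radius) ** 2
    return v_c[:, None] * shape[None, :]
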
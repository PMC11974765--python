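"""TAWSS, OSI, Q-criterion and profile/correlation analyses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avf_hemoflow.cfd.mesh import channel_mesh
from avf_hemoflow.cfd.solver import FlowField
from avf_hemoflow.wall_metrics import (WallShearField, correlate, osi,
                                       profile_by_arclength, q_criterion,
                                       tawss, wall_shear, window_average)


def _wss_from_scalar(times, tau_t, period):
    """WallShearField with a single element and x-directed shear."""
    tau = np.zeros((len(times), 1, 2))
    tau[:, 0, 0] = tau_t
    return WallShearField(times=np.asarray(times), tau=tau,
                          arclength=np.array([0.0]), face_area=np.array([1.0]),
                          period=period)


class TestTawss:
    def test_constant_shear(self):
        t = np.linspace(0, 1, 65)
        w = _wss_from_scalar(t, np.full_like(t, -2.5), 1.0)
        assert tawss(w)[0] == pytest.approx(2.5, rel=1e-12)

    def test_rectified_sinusoid_closed_form(self):
        """TAWSS of tau0 sin(2 pi t/T) is (2/pi) tau0."""
        t = np.linspace(0, 1, 2049)
        w = _wss_from_scalar(t, 3.0 * np.sin(2 * np.pi * t), 1.0)
        assert tawss(w)[0] == pytest.approx(3.0 * 2 / np.pi, rel=1e-4)

    def test_zero_waveform(self):
        t = np.linspace(0, 1, 33)
        assert tawss(_wss_from_scalar(t, np.zeros_like(t), 1.0))[0] == 0.0

    def test_insufficient_coverage_raises(self):
        t = np.linspace(0, 0.2, 16)
        with pytest.raises(ValueError):
            tawss(_wss_from_scalar(t, np.ones_like(t), 1.0))


class TestOsi:
    def test_unidirectional_shear_gives_zero(self):
        t = np.linspace(0, 1, 65)
        w = _wss_from_scalar(t, 1.0 + 0.5 * np.sin(2 * np.pi * t), 1.0)
        assert osi(w)[0] == pytest.approx(0.0, abs=1e-12)

    def test_complete_reversal_gives_half(self):
        t = np.linspace(0, 1, 65)
        w = _wss_from_scalar(t, np.sin(2 * np.pi * t), 1.0)
        assert osi(w)[0] == pytest.approx(0.5, abs=1e-12)

    def test_three_quarter_forward_square_wave(self):
        """tau = +1 for 0.75T, -1 for 0.25T: OSI = (1 - 0.5/1)/2 = 0.25."""
        t = np.linspace(0, 1, 8193)
        tau_t = np.where((t % 1.0) < 0.75, 1.0, -1.0)
        w = _wss_from_scalar(t, tau_t, 1.0)
        assert osi(w)[0] == pytest.approx(0.25, abs=2e-3)

    def test_zero_shear_element_assigned_zero(self):
        t = np.linspace(0, 1, 33)
        w = _wss_from_scalar(t, np.zeros_like(t), 1.0)
        assert osi(w)[0] == 0.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(8, 64))
    def test_bounds_hold_for_arbitrary_vector_histories(self, seed, n):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 1, n + 1)
        tau = rng.normal(size=(n + 1, 5, 2)) * rng.lognormal(size=(1, 5, 1))
        w = WallShearField(times=t, tau=tau, arclength=np.arange(5.0),
                           face_area=np.ones(5), period=1.0)
        vals = osi(w)
        assert np.all(vals >= 0.0) and np.all(vals <= 0.5)

    def test_steady_field_has_zero_osi_and_tawss_equals_magnitude(
            self, poiseuille_field):
        flow, _, _ = poiseuille_field
        ws = wall_shear(flow)
        # replicate the single sample across a fictitious cycle
        w2 = WallShearField(times=np.array([0.0, 0.5, 1.0]),
                            tau=np.repeat(ws.tau, 3, axis=0),
                            arclength=ws.arclength, face_area=ws.face_area,
                            period=1.0)
        assert np.allclose(osi(w2), 0.0)
        assert np.allclose(tawss(w2), np.linalg.norm(ws.tau[0], axis=1))


class TestQCriterion:
    def _field_from(self, fn):
        mesh = channel_mesh(1.0, 1.0, ni=16, nj=16, south="wall")
        x = mesh.xc / 1e-3
        y = mesh.yc / 1e-3
        u, v = fn(x, y)
        return FlowField(mesh=mesh, times=np.array([0.0]), u=u[None],
                         v=v[None], p=np.zeros_like(u)[None])

    def test_simple_shear_is_zero(self):
        g = 7.0
        f = self._field_from(lambda x, y: (g * y, np.zeros_like(y)))
        q = q_criterion(f)
        inner = q.q[0][~q.boundary_cell]
        assert np.allclose(inner, 0.0, atol=1e-9 * g**2)

    def test_rigid_rotation_gives_omega_squared(self):
        w = 4.0
        f = self._field_from(lambda x, y: (-w * y, w * x))
        q = q_criterion(f)
        inner = q.q[0][~q.boundary_cell]
        assert np.allclose(inner, w**2, rtol=1e-9)

    def test_pure_strain_gives_minus_epsilon_squared(self):
        e = 3.0
        f = self._field_from(lambda x, y: (e * x, -e * y))
        q = q_criterion(f)
        inner = q.q[0][~q.boundary_cell]
        assert np.allclose(inner, -e**2, rtol=1e-9)


class TestProfiles:
    def test_uniform_metric_max_equals_mean(self):
        s = np.linspace(0, 4, 100)
        vals = np.full_like(s, 2.0)
        prof = profile_by_arclength(vals, s, bin_width=0.5)
        assert np.allclose(prof.max[prof.count > 0], 2.0)
        assert np.allclose(prof.mean[prof.count > 0], 2.0)

    def test_poiseuille_tawss_profile_is_flat(self, poiseuille_field):
        flow, Q, R = poiseuille_field
        ws = wall_shear(flow)
        sel = (ws.arclength > 0.8) & (ws.arclength < 3.2)
        prof = profile_by_arclength(np.linalg.norm(ws.tau[0], axis=1)[sel],
                                    ws.arclength[sel], ws.face_area[sel], 0.4)
        ok = prof.count > 0
        assert np.ptp(prof.mean[ok]) / prof.mean[ok].mean() < 0.03

    def test_empty_bins_reported_as_gaps(self):
        s = np.array([0.1, 0.2, 3.8, 3.9])
        prof = profile_by_arclength(np.ones_like(s), s, bin_width=0.5,
                                    s_range=(0.0, 4.0))
        assert np.isnan(prof.mean[3])
        assert prof.count[3] == 0

    def test_window_average(self):
        s = np.linspace(0, 4, 81)
        vals = s.copy()
        assert window_average(vals, s, (0.0, 4.0)) == pytest.approx(
            np.mean(s[s < 4.0]), rel=1e-12)


class TestCorrelate:
    def test_metric_against_itself_is_one(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        assert correlate(x, x).rho == pytest.approx(1.0)

    def test_constant_metric_is_flagged_degenerate_not_zero(self):
        x = np.ones(6)
        y = np.arange(6.0)
        res = correlate(x, y)
        assert res.degenerate
        assert np.isnan(res.rho)

    def test_too_few_bins_raise(self):
        with pytest.raises(ValueError):
            correlate(np.arange(4.0), np.arange(4.0))

    def test_nan_bins_are_dropped_as_gaps(self):
        x = np.array([1, 2, np.nan, 4, 5, 6, 7.0])
        y = -x
        res = correlate(x, y)
        assert res.n == 6
        assert res.rho == pytest.approx(-1.0)


class TestStokesScaling:
    def test_tawss_scales_linearly_with_flow(self, blood):
        """Creeping-regime linearity: k x flow -> k x wall shear, OSI unchanged."""
        from avf_hemoflow.cfd.mesh import tube_mesh
        from avf_hemoflow.cfd.solver import solve_steady
        mesh = tube_mesh(0.3, length_mm=3.0, ni=24, nj=10)
        taus = []
        for q in (0.4, 0.8):
            f = solve_steady(mesh, blood, inlet_flow_mm3_s=q)
            ws = wall_shear(f)
            taus.append(np.linalg.norm(ws.tau[0], axis=1))
        ratio = taus[1] / taus[0]
        assert np.allclose(ratio, 2.0, rtol=0.01)
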
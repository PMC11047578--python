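"""1D pulse-wave solver: tube law, wave speeds, 0D elements, coupling."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import vasculate as v
from vasculate.fixtures import make_tube_network, _straight_segment
from vasculate.centerline import assemble_network
from vasculate.units import MMHG


WALL = v.WallModel(E=400e3, h0=0.3, r0=3.0, sigma=0.5)
FLUID = v.FluidProps()


class TestTubeLaw:
    def test_reference_identity(self):
        assert v.tube_law(WALL.A0, WALL) == WALL.P0

    def test_quadrupled_area_adds_beta(self):
        assert v.tube_law(4 * WALL.A0, WALL) == pytest.approx(
            WALL.P0 + WALL.beta, rel=1e-14)

    @given(st.floats(min_value=0.05, max_value=20.0))
    def test_roundtrip_inverse(self, ratio):
        A = ratio * WALL.A0
        assert v.tube_law_inv(v.tube_law(A, WALL), WALL) == pytest.approx(
            A, rel=1e-12)

    def test_nonpositive_area_raises(self):
        with pytest.raises(ValueError):
            v.tube_law(-1.0, WALL)


class TestWaveSpeed:
    def test_moens_korteweg_at_reference(self):
        c0 = v.wave_speed(WALL.A0, WALL, FLUID)
        expected = math.sqrt(400e3 * 0.3e-3 / (2 * 1060 * 3e-3 * 0.75))
        assert c0 == pytest.approx(expected, rel=1e-12)
        assert c0 == pytest.approx(5.02, rel=2e-3)

    def test_area_scaling_quarter_power(self):
        assert (v.wave_speed(4 * WALL.A0, WALL, FLUID)
                / v.wave_speed(WALL.A0, WALL, FLUID)) == pytest.approx(
            math.sqrt(2), rel=1e-12)

    def test_density_scaling(self):
        heavy = v.FluidProps(rho=4 * 1060.0)
        assert v.wave_speed(WALL.A0, WALL, heavy) == pytest.approx(
            0.5 * v.wave_speed(WALL.A0, WALL, FLUID), rel=1e-12)


class TestAdvanceStep:
    def _rest_state(self, n=50, ds=1e-3):
        s = np.arange(n) * ds
        A = np.full(n, WALL.A0 * 1e-6)
        return v.VesselState(s_grid=s, A=A, Q=np.zeros(n), P=np.zeros(n))

    def test_rest_state_is_steady(self):
        state = self._rest_state()
        A0 = state.A.copy()
        for _ in range(50):
            v.advance_step(state, WALL, FLUID, 5e-5)
        assert np.abs(state.A / A0 - 1).max() < 1e-14
        assert np.abs(state.Q).max() < 1e-20

    def test_cfl_violation_raises_with_suggestion(self):
        state = self._rest_state()
        with pytest.raises(ValueError, match="suggest dt"):
            v.advance_step(state, WALL, FLUID, 1.0)

    def test_pulse_travels_at_wave_speed(self):
        fluid = v.FluidProps(K_R=0.0)
        c0 = v.wave_speed(WALL.A0, WALL, fluid)
        ds, n = 0.5e-3, 401
        s = np.arange(n) * ds
        A0 = WALL.A0 * 1e-6
        A = A0 * (1 + 0.01 * np.exp(-((s - 0.03) / 0.005) ** 2))
        c_loc = np.sqrt(WALL.beta / (2 * fluid.rho)) * (A / A0) ** 0.25
        u = 4 * (c_loc - np.sqrt(WALL.beta / (2 * fluid.rho)))
        state = v.VesselState(s_grid=s, A=A.copy(), Q=u * A, P=np.zeros(n))
        dt = 0.5 * ds / (1.05 * c0)

        def peak():
            i = int(np.argmax(state.A[5:-5])) + 5
            y0, y1, y2 = state.A[i - 1:i + 2]
            return s[i] + 0.5 * ds * (y0 - y2) / (y0 - 2 * y1 + y2)

        x0, t0 = peak(), state.t
        for _ in range(int(0.055 / (c0 * dt))):
            v.advance_step(state, WALL, fluid, dt)
        speed = (peak() - x0) / (state.t - t0)
        assert speed == pytest.approx(c0, rel=0.02)

    def test_steady_friction_pressure_drop(self):
        # near-rigid tube (A stays ~A0): steady momentum balance gives
        # dP/dz = -rho K_R Q / A0^2
        net, cfg = make_tube_network(length_mm=80.0, radius_mm=3.0, E=4e6)
        t = np.linspace(0, 0.5, 21)
        cfg.inflow_t, cfg.inflow_q = t, np.full(21, 3.0)
        cfg.period = 0.5
        cfg.conv_tol = 1e-6
        cfg.max_cycles = 40
        sol = v.simulate(net, cfg)
        P = sol.segments[0]["P"][-1]
        s = sol.segments[0]["s"]
        A0 = np.pi * 9e-6
        expected = cfg.fluid.rho * cfg.fluid.K_R * 3e-6 * (s[-1] - s[0]) / A0 ** 2
        assert P[0] - P[-1] == pytest.approx(expected, rel=0.01)


class TestWindkessel:
    def test_steady_state_pressure(self):
        wk = v.WindkesselState(R1=4e8, R2=3e9, C=3e-10, P_out=600.0)
        Q0 = 3e-6
        dt = 1e-4
        for _ in range(int(20 * wk.R2 * wk.C / dt)):
            P = v.windkessel_step(Q0, wk, dt)
        assert P == pytest.approx(wk.P_out + Q0 * (wk.R1 + wk.R2), rel=0.01)

    def test_zero_flow_stays_at_outflow_pressure(self):
        wk = v.WindkesselState(R1=4e8, R2=3e9, C=3e-10, P_out=600.0)
        for _ in range(100):
            P = v.windkessel_step(0.0, wk, 1e-3)
        assert P == pytest.approx(600.0, abs=1e-9)

    def test_relaxation_follows_exponential(self):
        wk = v.WindkesselState(R1=4e8, R2=3e9, C=3e-10, P_out=0.0)
        tau = wk.R2 * wk.C
        wk.P_c = 1000.0
        dt = tau / 2000
        t = 0.0
        for _ in range(2000):                    # one time constant
            v.windkessel_step(0.0, wk, dt)
            t += dt
        assert wk.P_c == pytest.approx(1000.0 * math.exp(-t / tau), rel=0.01)


class TestStenosis:
    ELEM = v.StenosisElement(segment=0, position=10.0, r0=3.0,
                             As_over_A0=0.1, Ls=10.0)

    def test_zero_severity_has_no_turbulent_term(self):
        elem = v.StenosisElement(segment=0, position=10.0, r0=3.0,
                                 As_over_A0=1.0, Ls=10.0)
        # with As = A0 the drop is purely viscous: linear in Q
        d1 = v.stenosis_pressure_drop(1e-6, 0.0, elem, FLUID)
        d2 = v.stenosis_pressure_drop(2e-6, 0.0, elem, FLUID)
        assert d2 == pytest.approx(2 * d1, rel=1e-12)

    def test_turbulent_coefficient_scaling(self):
        # severity 0.9: (A0/As - 1)^2 = 81; isolate the quadratic term
        def turb(elem, q):
            total = v.stenosis_pressure_drop(q, 0.0, elem, FLUID)
            lin = v.stenosis_pressure_drop(q, 0.0, v.StenosisElement(
                segment=0, position=10.0, r0=3.0, As_over_A0=1.0, Ls=10.0,
                Kv=elem.Kv), FLUID)
            return total - lin
        q = 5e-6
        ratio = turb(self.ELEM, q) / (1.52 * FLUID.rho / (
            2 * (self.ELEM.A0_sten * 1e-6) ** 2) * q * q)
        assert ratio == pytest.approx(81.0, rel=1e-9)

    def test_odd_symmetry_in_flow(self):
        d_fwd = v.stenosis_pressure_drop(4e-6, 0.0, self.ELEM, FLUID)
        d_bwd = v.stenosis_pressure_drop(-4e-6, 0.0, self.ELEM, FLUID)
        assert d_bwd == pytest.approx(-d_fwd, rel=1e-12)

    def test_severity_property(self):
        assert self.ELEM.severity == pytest.approx(0.9)


def _steady_cfg(cfg, q_mlps=3.0, period=0.5):
    t = np.linspace(0, period, 21)
    cfg.inflow_t, cfg.inflow_q = t, np.full(21, q_mlps)
    cfg.period = period
    return cfg


class TestSimulate:
    def test_single_tube_steady_flow_uniform(self):
        net, cfg = make_tube_network(length_mm=60.0)
        _steady_cfg(cfg)
        cfg.conv_tol = 1e-5
        cfg.max_cycles = 40
        sol = v.simulate(net, cfg)
        assert sol.converged
        Q = sol.segments[0]["Q"][-1]
        assert np.ptp(Q) / Q.mean() < 1e-3
        assert Q.mean() == pytest.approx(3e-6, rel=1e-3)

    def test_degree2_junction_matches_contiguous_tube(self):
        """Splice oracle: a tube split by a degree-2 junction converges
        to the same frictionless steady state as the whole tube."""
        fluid = v.FluidProps(K_R=1e-12)
        whole, cfg1 = make_tube_network(length_mm=80.0)
        split, cfg2 = make_tube_network(length_mm=80.0, split_at=30.0)
        for cfg in (cfg1, cfg2):
            _steady_cfg(cfg)
            cfg.fluid = fluid
            cfg.conv_tol = 1e-9
            cfg.max_cycles = 40
        s1 = v.simulate(whole, cfg1)
        s2 = v.simulate(split, cfg2)
        q1 = s1.segments[0]["Q"][-1]
        q2 = np.concatenate([s2.segments[0]["Q"][-1], s2.segments[1]["Q"][-1]])
        p1 = s1.segments[0]["P"][-1]
        p2 = np.concatenate([s2.segments[0]["P"][-1], s2.segments[1]["P"][-1]])
        assert np.abs(q2 / q1.mean() - 1).max() < 1e-8
        assert np.abs((p2.mean() - p1.mean()) / p1.mean()) < 1e-8

    def test_symmetric_bifurcation_splits_flow_evenly(self):
        segs = {
            0: _straight_segment((0, 0, -40), (0, 0, 0), 3.0, arterial_index=0),
            1: _straight_segment((0, 0, 0), (-30, 0, 30), 2.0, arterial_index=1),
            2: _straight_segment((0, 0, 0), (30, 0, 30), 2.0, arterial_index=2),
        }
        model = {"kind": "rcr", "R1": 4e8, "R2": 3e9, "C": 3e-10,
                 "P_out": 5 * MMHG}
        net = assemble_network(
            segs, {0: [(0, "end"), (1, "start"), (2, "start")]}, (0, "start"),
            {1: {"segment": 1, "end": "end", "model": dict(model)},
             2: {"segment": 2, "end": "end", "model": dict(model)}})
        t = np.linspace(0, 1, 51)
        cfg = v.SimConfig(inflow_t=t, inflow_q=np.full(51, 6.0), period=1.0,
                          conv_tol=1e-5, max_cycles=40)
        sol = v.simulate(net, cfg)
        q1 = sol.mean_flow(1).mean()
        q2 = sol.mean_flow(2).mean()
        assert q1 == pytest.approx(q2, rel=1e-9)
        # segment-mean flow carries ~0.1% steady-state ripple
        assert q1 + q2 == pytest.approx(6e-6, rel=2e-3)
        assert sol.conservation["max_junction_defect_m3s"] < 1e-16

    def test_grid_convergence_on_pulse(self):
        """Halving ds changes the peak midpoint pressure by < 1%."""
        peaks = []
        for ds in (1.0, 0.5):
            net, cfg = make_tube_network(length_mm=100.0)
            cfg.ds = ds
            cfg.max_cycles = 3          # transient cycles suffice for peaks
            with pytest.warns(UserWarning, match="convergence"):
                sol = v.simulate(net, cfg)
            P = sol.segments[0]["P"]
            peaks.append(P[:, P.shape[1] // 2].max())
        assert abs(peaks[1] / peaks[0] - 1) < 0.01

    def test_nonreflecting_outlet_reflection_below_2pct(self):
        net, cfg = make_tube_network(length_mm=150.0,
                                     terminal={"kind": "nonreflecting"})
        T = 0.4
        t = np.linspace(0, T, 401)
        cfg.inflow_t = t
        cfg.inflow_q = np.exp(-((t - 0.05) / 0.01) ** 2)
        cfg.period = T
        cfg.fluid = v.FluidProps(K_R=1e-12)
        cfg.max_cycles = 1
        cfg.n_output = 400
        with pytest.warns(UserWarning):
            sol = v.simulate(net, cfg)
        q_mid = sol.segments[0]["Q"][:, sol.segments[0]["Q"].shape[1] // 2]
        incident = q_mid.max()
        late = np.abs(q_mid[sol.times > 0.13]).max()
        assert late < 0.02 * incident

    def test_global_volume_balance(self):
        net, cfg = make_tube_network(length_mm=80.0)
        sol = v.simulate(net, cfg)
        assert sol.conservation["balance_rel"] < 5e-3
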
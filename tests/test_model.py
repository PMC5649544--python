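import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from hvcphys import (NeuronParams, preset, leak_only, ModelState,
                     StimulusProtocol, simulate, steady_state, rhs,
                     membrane_currents, ih_current, im_current, relax)
from hvcphys import gates
from hvcphys.model import _rhs


class TestIhCurrent:
    def test_zero_driving_force(self):
        p = preset("hvc_x@adult")          # V_h = -43 for every cell
        assert ih_current(-43.0, 0.7, 0.2, p) == 0.0

    def test_forced_arithmetic(self):
        p = NeuronParams(g_h=2.0, w_h=1.0, V_h=-43.0)
        assert ih_current(-93.0, 1.0, 0.0, p) == pytest.approx(-100.0)

    def test_adult_x_steady_gate_oracle(self):
        p = preset("hvc_x@adult")          # g_h = 2.25, w_h = 0.17
        v = -90.0
        g = float(gates.h_inf(v))
        expected = 2.25 * (0.17 * g + 0.83 * g) * (v + 43.0)
        assert ih_current(v, g, g, p) == pytest.approx(expected, rel=1e-12)
        assert expected < 0                # inward below V_h


class TestImCurrent:
    def test_zero_gate(self):
        assert im_current(-20.0, 0.0, preset("hvc_ra@adult")) == 0.0

    def test_zero_at_reversal(self):
        p = preset("hvc_ra@adult")
        assert im_current(p.V_K, 0.5, p) == 0.0

    def test_adult_ra_scalar_oracle(self):
        p = preset("hvc_ra@adult")         # g_M = 32, theta_z = -45
        z = float(gates.boltzmann(-20.0, p.theta_z, p.sigma_z))
        expected = 32.0 * z * (-20.0 + 90.0)
        assert im_current(-20.0, z, p) == pytest.approx(expected, rel=1e-12)
        assert expected > 0                # outward above V_K


class TestMembraneCurrents:
    def test_conductance_gating_nullity(self):
        p = leak_only(C=100.0, g_L=5.0, V_L=-65.0)
        st = ModelState.at_voltage(p, -50.0, ca=0.3)
        cur = membrane_currents(st, p)
        d = cur.as_dict()
        assert d["I_L"] != 0.0
        assert all(v == 0.0 for k, v in d.items() if k != "I_L")

    def test_leak_zero_at_reversal(self):
        p = leak_only(V_L=-70.0)
        st = ModelState.at_voltage(p, -70.0, ca=p.b_Ca)
        assert membrane_currents(st, p).I_L == 0.0

    def test_each_zeroed_conductance_silences_its_current(self):
        base = preset("hvc_x@adult")
        st = ModelState.at_voltage(base, -55.0)
        for g_name, i_name in [("g_Na", "I_Na"), ("g_K", "I_K"),
                               ("g_Nap", "I_Nap"), ("g_CaL", "I_CaL"),
                               ("g_CaT", "I_CaT"), ("g_A", "I_A"),
                               ("g_SK", "I_SK"), ("g_M", "I_M"),
                               ("g_h", "I_h")]:
            p = base.with_(**{g_name: 0.0})
            assert getattr(membrane_currents(st, p), i_name) == 0.0

    def test_sum_matches_rhs(self):
        # consistency oracle: sum of currents = -C dV/dt at I_app = 0
        p = preset("hvc_x@adult")
        st = ModelState.at_voltage(p, -67.0)
        total = membrane_currents(st, p).total()
        dv = rhs(st, p, i_app=0.0).v
        assert dv == pytest.approx(-total / p.C, rel=1e-12)


class TestRhs:
    def test_leak_equilibrium(self):
        p = leak_only(V_L=-70.0)
        st = ModelState.at_voltage(p, -70.0, ca=p.b_Ca)
        assert rhs(st, p, 0.0).v == pytest.approx(0.0, abs=1e-12)

    def test_leak_closed_form(self):
        p = leak_only(C=120.0, g_L=4.0, V_L=-70.0)
        st = ModelState.at_voltage(p, -60.0, ca=p.b_Ca)
        assert rhs(st, p, 0.0).v == pytest.approx(-4.0 * 10.0 / 120.0)

    def test_derivative_matches_finite_difference_of_current_sum(self):
        p = preset("hvc_x@adult")
        st = ModelState.at_voltage(p, -60.0)
        for i_app in (0.0, -200.0, 200.0):
            dv = rhs(st, p, i_app).v
            total = membrane_currents(st, p).total()
            assert dv == pytest.approx(-(total - i_app) / p.C, rel=1e-12)


class TestSimulate:
    def test_leak_only_matches_rc_closed_form(self):
        p = leak_only(C=120.0, g_L=4.0, V_L=-70.0)
        proto = StimulusProtocol(pre_ms=50.0, pulse_pA=(-10.0,),
                                 pulse_ms=300.0, post_ms=100.0, dt_out=0.1)
        tr, = simulate(p, proto)
        tau = p.C / p.g_L
        dv = -10.0 / p.g_L                  # pA/nS = mV
        expected = np.full_like(tr.t, -70.0)
        during = (tr.t >= 50.0) & (tr.t < 350.0)
        expected[during] = -70.0 + dv * (1 - np.exp(-(tr.t[during] - 50.0) / tau))
        v350 = -70.0 + dv * (1 - math.exp(-300.0 / tau))
        post = tr.t >= 350.0
        expected[post] = -70.0 + (v350 + 70.0) * np.exp(-(tr.t[post] - 350.0) / tau)
        assert np.max(np.abs(tr.v - expected)) < 0.1

    def test_trace_invariants(self, adult_x_sweeps):
        for tr in adult_x_sweeps:
            assert len(tr.t) == len(tr.v) == len(tr.i_app)
            assert np.all(np.diff(tr.t) > 0)
            assert np.allclose(np.diff(tr.t), tr.dt)

    def test_gating_bounds_along_trajectory(self):
        # gates stay in [0,1] (within solver tolerance) and Ca >= 0
        p = preset("hvc_x@adult")
        y0 = relax(p, 500.0).as_array()
        for i_app in (-200.0, 200.0):
            sol = solve_ivp(_rhs, (0.0, 300.0), y0, method="RK23",
                            rtol=1e-6, atol=1e-8, args=(p, i_app))
            assert sol.success
            g = sol.y[1:7]
            assert g.min() > -1e-6 and g.max() < 1.0 + 1e-6
            assert sol.y[7].min() >= 0.0

    def test_nonspiking_sweep_stable_under_tolerance_halving(self):
        # pointwise V convergence on a subthreshold response
        p = preset("hvc_x@subsong")
        proto = StimulusProtocol(pre_ms=50.0, pulse_pA=(-200.0,),
                                 pulse_ms=300.0, post_ms=200.0, dt_out=0.1)
        a, = simulate(p, proto, rtol=1e-6, atol=1e-8)
        b, = simulate(p, proto, rtol=5e-7, atol=5e-9)
        assert np.max(np.abs(a.v - b.v)) < 0.1


class TestSteadyState:
    def test_leak_only_rests_at_reversal(self):
        res = steady_state(leak_only(V_L=-70.0))
        assert not res.limit_cycle
        assert res.state.v == pytest.approx(-70.0, abs=1e-9)

    def test_residual_below_tolerance(self):
        res = steady_state(preset("hvc_ra@adult"))
        assert not res.limit_cycle
        assert res.residual < 1e-6

    def test_adult_resting_potentials(self):
        # the two calibration anchors of the adult models
        ra = steady_state(preset("hvc_ra@adult")).state.v
        x = steady_state(preset("hvc_x@adult")).state.v
        assert ra == pytest.approx(-77.0, abs=3.0)
        assert x == pytest.approx(-67.0, abs=3.0)


class TestParams:
    def test_preset_names_cover_both_cells_and_three_stages(self):
        from hvcphys import PRESET_NAMES
        assert len(PRESET_NAMES) == 6
        for cell in ("hvc_x", "hvc_ra"):
            for stage in ("subsong", "plastic", "adult"):
                p = preset(f"{cell}@{stage}")
                assert p.stage == stage

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            NeuronParams(g_Na=-1.0)
        with pytest.raises(ValueError):
            NeuronParams(C=0.0)
        with pytest.raises(ValueError):
            NeuronParams(w_h=1.5)
        with pytest.raises(KeyError):
            preset("hvc_av@adult")

    def test_roundtrip_dict(self):
        p = preset("hvc_x@plastic")
        assert NeuronParams.from_dict(p.to_dict()) == p
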
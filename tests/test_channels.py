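"""Gating kinetics, calcium dynamics, and the parvalbumin buffer."""

import math

import numpy as np
import pytest

import vpglu as vg
from vpglu import REFERENCE_THETA_NDB
from vpglu.channels import (
    CalciumState,
    ConductanceVector,
    GATE_CALCIUM,
    PVBufferState,
    equilibrium_bound_fraction,
    gate_dynamics,
    load_default_channels,
    total_ionic_current,
    update_calcium,
    update_pv_buffer,
)


@pytest.fixture(scope="module")
def channels():
    return load_default_channels()


class TestGateDynamics:
    def test_boltzmann_half_activation_is_half_open(self, channels):
        for ch in channels:
            for g in ch.gates:
                if g.kind == GATE_CALCIUM:
                    continue
                ss = g.steady_state(g.vhalf, ch_ca := 1e-4)
                if g.kind == 0:  # plain voltage gate
                    assert ss == pytest.approx(0.5, abs=1e-12)

    def test_deep_hyperpolarization_closes_activation_gates(self, channels):
        ss_nav, _ = gate_dynamics(channels["nav16"], -120.0)
        assert ss_nav["m"] < 0.05
        ss_kdr, _ = gate_dynamics(channels["kdr"], -120.0)
        assert ss_kdr["n"] < 0.05
        for name, gate in (("cal", "c"), ("km", "m"), ("ka", "a")):
            ss, _ = gate_dynamics(channels[name], -120.0)
            assert ss[gate] < 0.05

    @pytest.mark.parametrize("v", [-80.0, -50.0, 0.0])
    def test_sk_half_saturation_is_voltage_independent(self, channels, v):
        sk = channels["sk"]
        kd = sk.gates[0].kd
        ss, _ = gate_dynamics(sk, v, ca=kd)
        assert ss["z"] == pytest.approx(0.5, rel=1e-12)

    def test_steady_states_bounded_and_taus_positive(self, channels):
        for ch in channels:
            ch.validate()  # raises on violation

    def test_nonfinite_voltage_rejected(self, channels):
        with pytest.raises(ValueError):
            gate_dynamics(channels["nav16"], math.nan)


class TestTotalCurrent:
    def test_passive_limit(self, channels):
        theta = ConductanceVector(0, 0, 0, 0, 0, 0, 0, 0, 1e-4)
        gates = {ch.name: {g.name: 0.5 for g in ch.gates} for ch in channels}
        out = total_ionic_current(theta, gates, v=-50.0, ca=1e-4,
                                  channels=channels, e_leak=-60.0)
        assert out["total"] == pytest.approx(1e-4 * 10.0)

    def test_potassium_currents_vanish_at_reversal(self, channels):
        theta = ConductanceVector(0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 1e-4)
        gates = {ch.name: {g.name: 0.5 for g in ch.gates} for ch in channels}
        out = total_ionic_current(theta, gates, v=-90.0, ca=1e-4, channels=channels)
        for k_channel in ("kdr", "ka", "sk", "bk", "km"):
            assert out[k_channel] == pytest.approx(0.0, abs=1e-15)

    def test_sk_current_monotone_in_calcium(self, channels):
        theta = ConductanceVector(0, 0, 0, 0.1, 0, 0, 0, 0, 0)
        sk = channels["sk"].gates[0]
        v = -50.0
        mags = []
        for ca in (1e-5, 1e-4, 1e-3, 1e-2):
            gates = {ch.name: {g.name: (sk.steady_state(v, ca) if ch.name == "sk"
                                        else 0.5)
                               for g in ch.gates} for ch in channels}
            out = total_ionic_current(theta, gates, v=v, ca=ca, channels=channels)
            mags.append(abs(out["sk"]))
        assert all(b > a for a, b in zip(mags, mags[1:]))

    def test_out_of_range_gate_rejected(self, channels):
        theta = ConductanceVector(0.1, 0, 0, 0, 0, 0, 0, 0, 0)
        gates = {ch.name: {g.name: 0.5 for g in ch.gates} for ch in channels}
        gates["nav16"]["m"] = 1.5
        with pytest.raises(ValueError):
            total_ionic_current(theta, gates, v=0.0, ca=1e-4, channels=channels)


class TestCalciumShell:
    def test_baseline_is_fixed_point(self):
        st = CalciumState()
        out = update_calcium(st, i_ca=0.0, dt=0.025)
        assert out.free == pytest.approx(st.baseline, rel=1e-12)

    def test_constant_influx_reaches_linear_steady_state(self):
        # closed form: free -> baseline + J*tau; within 1% after 7 tau
        st = CalciumState()
        i_ca = -1e-4  # mA/cm2 inward
        j = -1e4 * i_ca / (2.0 * 96485.332 * st.depth_um)
        expected = st.baseline + j * st.tau_ms
        dt = 0.025
        n = int(round(7 * st.tau_ms / dt))
        for _ in range(n):
            st = update_calcium(st, i_ca, dt)
        assert st.free == pytest.approx(expected, rel=0.01)

    def test_steady_elevation_scales_linearly_with_influx(self):
        def steady(i_ca):
            st = CalciumState()
            for _ in range(int(10 * st.tau_ms / 0.05)):
                st = update_calcium(st, i_ca, 0.05)
            return st.free - st.baseline

        assert steady(-2e-4) == pytest.approx(2 * steady(-1e-4), rel=1e-6)

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            update_calcium(CalciumState(), 0.0, dt=0.0)


class TestPVBuffer:
    def test_zero_buffer_is_identity(self):
        ca = CalciumState(free=1e-3)
        pv = PVBufferState(total=0.0)
        ca2, pv2 = update_pv_buffer(ca, pv, dt=0.025)
        assert ca2.free == ca.free
        assert pv2.bound == 0.0

    def test_binding_isotherm_at_clamped_calcium(self):
        # clamp free Ca, iterate exchange: bound/total -> Ca/(Ca + Kd)
        clamp = 2e-4
        pv = PVBufferState(total=1.0, bound=0.0)
        for _ in range(400000):
            ca = CalciumState(free=clamp)
            _, pv = update_pv_buffer(ca, pv, dt=0.5)
        expected = equilibrium_bound_fraction(clamp, pv.k_on, pv.k_off)
        assert pv.bound / pv.total == pytest.approx(expected, rel=1e-3)

    @pytest.mark.parametrize("free,bound", [(1e-3, 0.2), (5e-5, 0.9), (1e-2, 0.01)])
    def test_exchange_conserves_total_calcium(self, free, bound):
        ca = CalciumState(free=free)
        pv = PVBufferState(total=1.0, bound=bound)
        ca2, pv2 = update_pv_buffer(ca, pv, dt=0.025)
        assert (ca2.free + pv2.bound) == pytest.approx(free + bound, abs=1e-12)

    def test_invalid_bound_rejected(self):
        with pytest.raises(ValueError):
            PVBufferState(total=1.0, bound=1.5)


class TestBufferingInSimulation:
    def test_gates_stay_in_unit_interval(self, desk_cfg):
        cell = desk_cfg.build(REFERENCE_THETA_NDB)
        settings = desk_cfg.settings
        state = cell.equilibrate(settings)
        for _ in range(10):  # 100 pA in 10 ms chunks
            _, state, _ = cell.run(np.full(400, 100.0), settings, state=state)
            assert np.all(state.gates_h >= 0.0) and np.all(state.gates_h <= 1.0)
            assert np.all(state.gates_n >= 0.0) and np.all(state.gates_n <= 1.0)
            assert np.all(state.ca >= 0.0)

    def test_pv_attenuates_spike_calcium_transient(self, desk_cfg):
        peaks = {}
        for pv in (0.0, 1.0):
            cell = desk_cfg.build(REFERENCE_THETA_NDB, pv_total_mM=pv)
            settings = desk_cfg.settings
            state = cell.equilibrate(settings)
            peak = 0.0
            for _ in range(100):  # 100 ms at 100 pA, sampled every ms
                _, state, _ = cell.run(np.full(40, 100.0), settings, state=state)
                peak = max(peak, state.ca.max())
            peaks[pv] = peak
        assert peaks[1.0] < peaks[0.0]

    def test_fi_curve_pv_insensitive_without_calcium_gated_channels(self, desk_cfg):
        # with SK (and BK, the other calcium-sensing channel) removed,
        # calcium no longer feeds back on voltage, so PV cannot move the
        # F-I curve at all
        theta = REFERENCE_THETA_NDB.replace(g_sk=0.0, g_bk=0.0)
        rates = {}
        for pv in (0.0, 5.0):
            cell = desk_cfg.build(theta, pv_total_mM=pv)
            rates[pv] = vg.fi_curve(cell, desk_cfg.settings)
        assert np.allclose(rates[0.0], rates[5.0], rtol=0.05, atol=0.0)

    def test_fi_curve_pv_sensitive_with_sk_present(self, desk_cfg,
                                                   reference_metrics_ndb):
        cell = desk_cfg.build(REFERENCE_THETA_NDB, pv_total_mM=5.0)
        rates_pv = vg.fi_curve(cell, desk_cfg.settings)
        assert not np.allclose(rates_pv, reference_metrics_ndb.fi_hz, rtol=0.05)
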
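import numpy as np
import pytest

from cbgt.network import build_populations, connection_table, WeightConfig, build_connectivity
from cbgt.protocol import region_rates
from cbgt.simulator import (
    DT_MS, ExternalDriveParams, IFBParams, NeuronState, ReceptorParams,
    SpikeRecord, advance_membrane, estimate_population_rate, init_state,
    nmda_voltage_factor, pack_network, run_segment, update_external_drive,
    update_synaptic_gates,
)
from cbgt import DecisionCircuit


RECEPTORS = ReceptorParams()


class TestMembrane:
    def test_leak_fixed_point(self):
        p = IFBParams(g_T=0.0)
        st = NeuronState(V=p.V_L)
        for _ in range(1000):
            st, spiked = advance_membrane(st, p, RECEPTORS)
            assert not spiked
        assert st.V == pytest.approx(p.V_L)

    def test_interspike_interval_matches_leaky_integrator(self):
        """Constant suprathreshold current: ISI equals the closed-form
        charging time from reset to threshold plus the refractory period."""
        p = IFBParams(g_T=0.0)
        I = 600.0  # pA
        v_inf = p.V_L + I / p.g_L
        tau = p.C / p.g_L
        t_cross = tau * np.log((v_inf - p.V_reset) / (v_inf - p.V_spike))
        dt = 0.01
        st = NeuronState(V=p.V_reset)
        spikes = []
        t = 0.0
        while len(spikes) < 4 and t < 200.0:
            st, spiked = advance_membrane(st, p, RECEPTORS, I_ext=I, dt=dt)
            t += dt
            if spiked:
                spikes.append(t)
        isi = np.diff(spikes)
        assert np.allclose(isi, t_cross + p.t_ref, rtol=0.01)

    def test_nmda_voltage_factor_value(self):
        assert nmda_voltage_factor(-65.0) == pytest.approx(
            1.0 / (1.0 + np.exp(0.062 * 65.0) / 3.57), rel=1e-12)
        assert nmda_voltage_factor(-65.0) == pytest.approx(0.0597, abs=2e-4)

    def test_burst_gate_relaxation_closed_form(self):
        p = IFBParams(g_T=0.0, V_L=-75.0, V_h=-60.0)  # rest below V_h
        st = NeuronState(V=p.V_L, h=0.0)
        dt = 0.1
        for _ in range(500):
            st, _ = advance_membrane(st, p, RECEPTORS, dt=dt)
        t = 500 * dt
        assert st.h == pytest.approx(1.0 - np.exp(-t / p.tau_h_plus), rel=1e-9)

    def test_nonfinite_state_raises(self):
        from cbgt.simulator import NumericalDivergenceError
        with pytest.raises(NumericalDivergenceError):
            advance_membrane(NeuronState(V=np.nan), IFBParams(), RECEPTORS)


class TestGates:
    def test_pure_decay(self):
        st = NeuronState(V=-70, s_AMPA=2.0, s_GABA=1.0, s_NMDA=0.5)
        out = update_synaptic_gates(st, RECEPTORS, dt=4.0)
        assert out.s_AMPA == pytest.approx(2.0 * np.exp(-4.0 / RECEPTORS.tau_AMPA))
        assert out.s_GABA == pytest.approx(1.0 * np.exp(-4.0 / RECEPTORS.tau_GABA))
        assert out.s_NMDA == pytest.approx(0.5 * np.exp(-4.0 / RECEPTORS.tau_NMDA))

    def test_unit_jump_per_spike(self):
        st = NeuronState(V=-70)
        out = update_synaptic_gates(st, RECEPTORS, n_spikes_AMPA=1, dt=1e-9)
        assert out.s_AMPA == pytest.approx(1.0)

    def test_nmda_saturates_below_one(self):
        st = NeuronState(V=-70)
        for _ in range(200):  # spike bombardment
            st = update_synaptic_gates(st, RECEPTORS, n_spikes_NMDA=3, dt=0.1)
            assert st.s_NMDA <= 1.0
        assert st.s_NMDA > 0.9


class TestExternalDrive:
    def test_deterministic_relaxation_to_mean(self):
        d = ExternalDriveParams(rate=10.0, efficacy=1.0, n_connections=100)
        mu = d.stationary_mean(RECEPTORS.tau_AMPA)
        S, prev_gap = 0.0, mu
        for _ in range(2000):
            S = update_external_drive(S, d, RECEPTORS, dt=0.1, rng=None)
            gap = abs(mu - S)
            assert gap <= prev_gap + 1e-12
            prev_gap = gap
        assert S == pytest.approx(mu, rel=1e-4)

    def test_long_run_mean_matches_rate_efficacy_count_tau(self, rng):
        d = ExternalDriveParams(rate=40.0, efficacy=2.0, n_connections=200)
        mu = d.stationary_mean(RECEPTORS.tau_AMPA)
        S, acc, n = mu, 0.0, 0
        for _ in range(400_000):  # 200 s at dt = 0.5 ms
            S = update_external_drive(S, d, RECEPTORS, dt=0.5, rng=rng)
            acc += S
            n += 1
        assert acc / n == pytest.approx(mu, rel=0.02)

    def test_zero_rate_decays_to_zero(self, rng):
        d = ExternalDriveParams(rate=0.0, efficacy=2.0, n_connections=200)
        S = 5.0
        for _ in range(1000):
            S = update_external_drive(S, d, RECEPTORS, dt=0.1, rng=rng)
        assert S == pytest.approx(0.0, abs=1e-6)


class TestRateEstimator:
    def test_no_spikes_zero_rate(self):
        tr = estimate_population_rate([], "Th_A", 75, 20.0, np.arange(0, 100, 1.0))
        assert np.all(tr.rates == 0.0)

    def test_single_spike_pulse(self):
        spikes = [SpikeRecord(0, np.array([10.0]))]
        grid = np.arange(0.0, 50.0, 0.5)
        tr = estimate_population_rate(spikes, "x", 1, 20.0, grid)
        expected = ((grid >= 10.0) & (grid < 30.0)) / 0.020
        assert np.allclose(tr.rates, expected)

    def test_poisson_population_recovers_rate(self, rng):
        rate, n, dur = 30.0, 50, 10_000.0
        spikes = [SpikeRecord(i, np.sort(rng.uniform(0, dur, rng.poisson(rate * dur / 1000))))
                  for i in range(n)]
        grid = np.arange(100.0, dur, 5.0)
        tr = estimate_population_rate(spikes, "x", n, 20.0, grid)
        assert tr.rates.mean() == pytest.approx(rate, rel=0.05)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            estimate_population_rate([], "x", 0, 20.0, np.arange(10.0))


class TestNetworkKernel:
    def test_state_invariants_during_run(self, small_circuit):
        net = small_circuit.packed
        drive = net.drive_arrays(small_circuit.drives, cx_rate=2.2)
        state = init_state(net, drive[0], drive[2], np.random.default_rng(0))
        run_segment(net, state, 3000, drive, seed=5)
        assert np.all(np.isfinite(state.V))
        assert np.all((state.h >= 0) & (state.h <= 1))
        nmda_rows = net.proj_rec == 1
        assert state.s[nmda_rows].max() <= 1.0 + 1e-12
        assert state.s.min() >= 0.0

    def test_energy_free_network_relaxes_to_leak(self, small_circuit):
        """No synaptic input, no drive, de-inactivated gate cleared: every
        neuron decays to its leak reversal and never spikes."""
        net = small_circuit.packed
        zero = tuple(np.zeros(net.n_neurons) for _ in range(4))
        state = init_state(net, zero[0], zero[2], np.random.default_rng(0))
        state.s[:] = 0.0
        state.h[:] = 0.0
        res = run_segment(net, state, 5000, zero, seed=5)
        assert res["pop_counts"].sum() == 0
        assert np.allclose(state.V, net.VL, atol=0.05)

    def test_timestep_halving_changes_rates_under_5pct(self):
        rates = {}
        for dt in (0.1, 0.05):
            c = DecisionCircuit(connectivity_seed=3, dt=dt)
            rates[dt] = region_rates(c.baseline_rates(duration=1000.0, seed=8))
        for pop, r in rates[0.1].items():
            if r >= 5.0:  # sparse populations are sampling-noise dominated
                assert rates[0.05][pop] == pytest.approx(r, rel=0.05), pop

    def test_run_segment_determinism(self, small_circuit):
        net = small_circuit.packed
        drive = net.drive_arrays(small_circuit.drives, cx_rate=2.2)

        def run():
            state = init_state(net, drive[0], drive[2], np.random.default_rng(3))
            res = run_segment(net, state, 2000, drive, seed=17)
            return res["pop_counts"].copy(), state.V.copy()

        c1, v1 = run()
        c2, v2 = run()
        assert np.array_equal(c1, c2)
        assert np.array_equal(v1, v2)
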
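"""Membrane update, PSP current contracts, and network stepping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import l5sim
from l5sim.dynamics import NetworkSimulator, membrane_step, psp_current, synaptic_current

PARAMS = l5sim.NeuronParams()


def _quiet_simulator(n=8, **cfg_overrides):
    """Small network with no synapses or inhibition: isolated driven LIFs."""
    cfg = l5sim.small_config(n, **{"connectivity.lbc_peak_prob": 0.0, **cfg_overrides})
    sim = NetworkSimulator(cfg, seed=1, ablation="no_mc")
    sim.weights[:] = 0.0
    sim._refresh_synaptic_matrix()
    return sim


class TestMembrane:
    def test_rest_is_fixed_point(self):
        assert membrane_step(-65.0, 0.0, PARAMS) == pytest.approx(-65.0)

    def test_single_step_leak(self):
        # one leaky step from -60 mV: 0.95*(-60) + 0.05*(-65)
        assert membrane_step(-60.0, 0.0, PARAMS) == pytest.approx(-60.25)

    def test_free_relaxation_matches_closed_form(self):
        v0 = -45.0
        v = v0
        a = PARAMS.dt / PARAMS.tau
        for t in range(1, 101):
            v = membrane_step(v, 0.0, PARAMS)
            expected = PARAMS.v_rest + (v0 - PARAMS.v_rest) * (1 - a) ** t
            assert v == pytest.approx(expected, rel=1e-12)

    @given(v=st.floats(-80, -40), gamma=st.floats(-10, 10))
    @settings(max_examples=50, deadline=None)
    def test_leak_compensated_drive_moves_v_by_exactly_gamma(self, v, gamma):
        i = psp_current(gamma, v, PARAMS)
        assert membrane_step(v, i, PARAMS) == pytest.approx(v + gamma, abs=1e-9)

    def test_no_drive_at_rest_means_no_current(self):
        assert psp_current(0.0, PARAMS.v_rest, PARAMS) == pytest.approx(0.0)

    def test_synaptic_psp_full_only_at_rest(self):
        i = synaptic_current(5.0, PARAMS)
        assert membrane_step(PARAMS.v_rest, i, PARAMS) == pytest.approx(-60.0)
        i = synaptic_current(-1.5, PARAMS)
        assert membrane_step(PARAMS.v_rest, i, PARAMS) == pytest.approx(-66.5)
        assert synaptic_current(0.0, PARAMS) == 0.0


class TestSingleNeuronFiring:
    def test_constant_drive_fires_at_166hz(self):
        # 5 mV/ms leak-compensated drive: 5 integration steps rest->threshold
        # plus 1 ms refractory = 6 ms period
        sim = _quiet_simulator(**{"inputs.p_active": 1.0})
        res = sim.run(n_steps=1200)
        isi = np.diff(res.raster.spike_times_of(0))
        assert np.all(isi == 6.0)
        assert 1000.0 / isi.mean() == pytest.approx(1000.0 / 6.0)

    def test_no_input_no_spikes(self):
        sim = _quiet_simulator(**{"inputs.p_active": 0.0})
        res = sim.run(n_steps=500)
        assert res.raster.n_spikes == 0


class TestNetworkStep:
    def test_lbc_linked_spike_delivers_ipsp_next_step(self):
        sim = _quiet_simulator(**{"inputs.p_active": 0.0})
        sim.synapses.lbc_adj[0, 1] = sim.synapses.lbc_adj[1, 0] = True
        sim._refresh_synaptic_matrix()
        sim.v[0] = -41.0
        sim.input_pattern = np.zeros(8, dtype=bool)
        # drive neuron 0 well over threshold (the leak acts before the test)
        sim.v[0] = sim.config.neuron.v_thresh + 5.0
        spikers = sim.step()
        assert 0 in spikers
        sim.step()
        # neuron 1 received -1.5 mV while at rest
        assert sim.v[1] == pytest.approx(-66.5)

    def test_excitatory_spike_delivers_weighted_epsp(self):
        sim = _quiet_simulator(**{"inputs.p_active": 0.0})
        sim.weights[0, 2] = 7.0
        sim._refresh_synaptic_matrix()
        sim.v[0] = sim.config.neuron.v_thresh + 5.0
        sim.step()
        sim.step()
        assert sim.v[2] == pytest.approx(-58.0)

    def test_mc_window_blocks_spiking_240_to_360ms(self):
        # constant suprathreshold drive; MC enabled: the first spike at t=5
        # must silence the spiker (and its neighbourhood) during
        # [245, 365) and nowhere else in the first cycle
        cfg = l5sim.small_config(8, **{"connectivity.lbc_peak_prob": 0.0,
                                       "inputs.p_active": 1.0})
        sim = NetworkSimulator(cfg, seed=1)
        sim.weights[:] = 0.0
        sim._refresh_synaptic_matrix()
        res = sim.run(n_steps=400)
        tr = res.raster.spike_times_of(0)
        first = tr[0]
        onset, offset = first + 240, first + 360
        in_window = tr[(tr >= onset) & (tr < offset)]
        assert in_window.size == 0
        # firing resumes promptly after the window
        assert np.any((tr >= offset) & (tr < offset + 10))

    def test_no_spike_during_refractory_anywhere(self, small_run):
        for i in range(small_run.raster.n_neurons):
            isi = np.diff(small_run.raster.spike_times_of(i))
            assert np.all(isi >= 2.0)  # 1 ms refractory step after each spike

    def test_mc_event_bookkeeping_counts_onsets_only(self):
        cfg = l5sim.small_config(8, **{"connectivity.lbc_peak_prob": 0.0,
                                       "inputs.p_active": 1.0})
        sim = NetworkSimulator(cfg, seed=1)
        sim.weights[:] = 0.0
        sim._refresh_synaptic_matrix()
        res = sim.run(n_steps=500)
        # one onset per ~360 ms cycle per neuron, never one per spike
        assert 0 < res.n_mc_events < res.raster.n_spikes
        assert res.n_mc_events % 8 == 0  # identical isolated neurons

    def test_membrane_never_below_floor(self):
        sim = _quiet_simulator(**{"inputs.p_active": 0.0})
        sim.synapses.lbc_adj[:, :] = True
        np.fill_diagonal(sim.synapses.lbc_adj, False)
        sim._refresh_synaptic_matrix()
        cfg = sim.config
        for _ in range(50):
            sim.v[0] = cfg.neuron.v_thresh + 1.0  # force repeated spiking
            sim.step()
            assert np.all(sim.v >= cfg.neuron.v_floor - 1e-9)

    def test_determinism_same_seed_same_raster(self):
        cfg = l5sim.small_config(27)
        a = l5sim.run_simulation(cfg, seed=9, n_steps=2000)
        b = l5sim.run_simulation(cfg, seed=9, n_steps=2000)
        assert np.array_equal(a.raster.neuron_ids, b.raster.neuron_ids)
        assert np.array_equal(a.raster.times, b.raster.times)
        assert np.array_equal(a.weights_final, b.weights_final)

    def test_unknown_ablation_rejected(self):
        with pytest.raises(ValueError):
            NetworkSimulator(l5sim.small_config(8), seed=0, ablation="nope")


class TestAblations:
    def test_mc_fraction_limits_enabled_population(self):
        cfg = l5sim.small_config(64)
        sim = NetworkSimulator(cfg, seed=2, mc_fraction=0.25)
        assert sim.mc_enabled.sum() == 16
        sim = NetworkSimulator(cfg, seed=2, ablation="no_mc")
        assert sim.mc_enabled.sum() == 0

    def test_no_lbc_removes_inhibition_from_psp_matrix(self):
        cfg = l5sim.small_config(27)
        sim = NetworkSimulator(cfg, seed=2, ablation="no_lbc")
        assert np.all(sim._syn_matrix >= 0)
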
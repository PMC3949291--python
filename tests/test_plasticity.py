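"""STDP rule, pairing, learning-rate schedule, bounds and batch semantics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import l5sim
from l5sim.plasticity import (_pair_events, _padded_spike_times, apply_bounds,
                              apply_iteration_batch, learning_rate, pair_spikes,
                              stdp_factor, stdp_update)

P = l5sim.PlasticityParams()


class TestLearningRate:
    def test_starts_at_one(self):
        assert learning_rate(0, P) == pytest.approx(1.0)

    def test_e_folding_at_decay_constant(self):
        assert learning_rate(550, P) == pytest.approx(np.exp(-1.0))

    def test_strictly_decreasing_over_schedule(self):
        deltas = learning_rate(np.arange(P.total_iterations), P)
        assert deltas.shape == (885,)
        assert np.all(np.diff(deltas) < 0)

    def test_out_of_schedule_rejected(self):
        with pytest.raises(ValueError):
            learning_rate(-1, P)
        with pytest.raises(ValueError):
            learning_rate(885, P)


class TestStdpUpdate:
    def test_ltp_branch_value(self):
        # dt=5, r=1, delta=1: 2 * (1 + 0.05*e^{-1/6})
        assert stdp_update(2.0, 5.0, 1.0, 1.0, P) == \
            pytest.approx(2.0 + 0.1 * np.exp(-1.0 / 6.0))

    def test_ltd_branch_value(self):
        # dt=-10: 2 * (1 - 0.05*e^{-(1/3)^2})
        assert stdp_update(2.0, -10.0, 1.0, 1.0, P) == \
            pytest.approx(2.0 - 0.1 * np.exp(-(1.0 / 3.0) ** 2))

    def test_outside_windows_unchanged(self):
        assert stdp_update(2.0, 30.0, 1.0, 1.0, P) == 2.0
        assert stdp_update(2.0, -40.0, 1.0, 1.0, P) == 2.0
        assert stdp_update(2.0, 20.0, 1.0, 1.0, P) == 2.0

    def test_synchronous_pair_potentiates(self):
        # dt = 0 falls in the potentiation branch
        assert stdp_update(2.0, 0.0, 1.0, 1.0, P) > 2.0

    @given(dt=st.floats(-39.9, 19.9), r=st.floats(0.001, 1.0),
           delta=st.floats(0.001, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_change_direction_and_five_percent_bound(self, dt, r, delta):
        f = stdp_factor(dt, r, delta, P)
        assert abs(f - 1.0) <= 0.05 * r * delta + 1e-12
        if dt >= 0:
            assert f > 1.0
        else:
            assert f < 1.0


class TestPairing:
    def test_disjoint_trains_no_pairs(self):
        assert pair_spikes([0.0, 5.0], [100.0, 105.0], P).size == 0

    def test_single_pair(self):
        assert pair_spikes([10.0], [15.0], P).tolist() == [5.0]

    def test_nearest_pre_wins(self):
        assert pair_spikes([10.0, 14.0], [15.0], P).tolist() == [1.0]

    def test_each_post_spike_contributes_once(self):
        dts = pair_spikes([10.0], [12.0, 14.0, 16.0], P)
        assert dts.tolist() == [2.0, 4.0, 6.0]

    def test_batch_kernel_matches_pairwise_oracle(self):
        # the vectorised/jitted batch pairing must agree with pair_spikes
        rng = np.random.default_rng(3)
        n = 12
        for _ in range(5):
            n_spk = rng.integers(20, 60)
            ids = rng.integers(0, n, n_spk).astype(np.intp)
            times = np.sort(rng.uniform(0, 40, n_spk))
            table, counts = _padded_spike_times(ids, times, n)
            pre = np.repeat(np.arange(n), n)
            post = np.tile(np.arange(n), n)
            keep = pre != post
            pre, post = pre[keep].astype(np.intp), post[keep].astype(np.intp)
            syn, dts = _pair_events(pre, post, table, counts, P)
            trains = [np.sort(times[ids == i]) for i in range(n)]
            for s in range(pre.size):
                expected = pair_spikes(trains[pre[s]], trains[post[s]], P)
                got = np.sort(dts[syn == s])
                assert np.allclose(np.sort(expected), got)


class TestBounds:
    def test_saturation_pruning_interior(self):
        w = np.array([[0.0, 13.0], [0.04, 5.0]])
        apply_bounds(w, P)
        assert w[0, 1] == 12.0
        assert w[1, 0] == 0.0
        assert w[1, 1] == 5.0
        assert w[0, 0] == 0.0


class TestIterationBatch:
    def _weights(self):
        w = np.zeros((4, 4))
        w[0, 1], w[1, 2], w[2, 3] = 2.0, 3.0, 4.0
        return w

    def test_silent_window_decays_everything(self):
        w = self._weights()
        rng = np.random.default_rng(0)
        empty = (np.empty(0, dtype=np.intp), np.empty(0))
        w2, counts = apply_iteration_batch(w, empty, 1.0, P, rng)
        assert np.allclose(w2[w2 > 0], np.array([2.0, 3.0, 4.0]) * (1 - P.inactive_decay_coeff))
        assert counts.sum() == 0

    def test_zero_learning_rate_freezes_weights(self):
        w = self._weights()
        orig = w.copy()
        rng = np.random.default_rng(0)
        ids = np.array([0, 1, 1, 2], dtype=np.intp)
        times = np.array([1.0, 3.0, 9.0, 5.0])
        w2, _ = apply_iteration_batch(w, (ids, times), 0.0, P, rng)
        assert np.allclose(w2, orig)

    def test_decay_prunes_below_lower_bound(self):
        w = np.zeros((2, 2))
        w[0, 1] = 0.0502
        rng = np.random.default_rng(0)
        empty = (np.empty(0, dtype=np.intp), np.empty(0))
        w2, _ = apply_iteration_batch(w, empty, 1.0, P, rng)
        assert w2[0, 1] == 0.0  # 0.0502*(1-0.0092) < 0.05 -> pruned

    def test_paired_window_potentiates_causal_synapse(self):
        w = self._weights()
        rng = np.random.default_rng(0)
        ids = np.array([0, 1], dtype=np.intp)
        times = np.array([10.0, 13.0])  # pre 0 at 10, post 1 at 13
        w2, counts = apply_iteration_batch(w, (ids, times), 1.0, P, rng)
        assert w2[0, 1] > 2.0 * (1 - P.inactive_decay_coeff)
        assert counts[0, 1] == 1

    def test_event_count_conservation(self, small_run):
        # total counted events equals the sum over synapses
        assert small_run.stdp_counts.sum() >= 0
        assert small_run.stdp_counts.min() >= 0

    def test_zero_weights_never_revive_and_count_monotone(self):
        # multiplicative rule: no synaptogenesis, synapse set only shrinks
        cfg = l5sim.small_config(27)
        sim = l5sim.NetworkSimulator(cfg, seed=4)
        prev = np.count_nonzero(sim.weights)
        born = sim.weights == 0
        for _ in range(20):
            for _ in range(40):
                sim.step()
            now = np.count_nonzero(sim.weights)
            assert now <= prev
            assert not np.any(sim.weights[born] > 0)
            prev = now
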
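"""Leaky integrate-and-fire network dynamics.

The network advances in 1 ms steps.  Each step a neuron either sits in a
suppressed state (absolute refractory, or inside a Martinotti inhibition
window) clamped at rest, or integrates its currents: the leak-compensated
external drive of active input channels, EPSPs from last step's
presynaptic spikes, and -1.5 mV IPSPs from last step's spikes of
basket-cell-linked neighbours.  Crossing threshold emits a spike, resets
the membrane to rest, starts the refractory period and — for MC-enabled
neurons — schedules a paralysing window over the spiker's 50 um
neighbourhood, arriving 240 ms later and lasting 120 ms.

Current units: with the PSP-based current definitions the capacitance
cancels, so a "current" here is the membrane increment it produces through
the update equation in one step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .config import SimConfig, NeuronParams
from .geometry import NetworkGeometry, SynapticState, build_network
from .inputs import generate_pattern
from .plasticity import apply_iteration_batch, learning_rate

ABLATIONS = ("full", "no_lbc", "no_mc")


@dataclass
class SpikeRaster:
    """All spike events of a run: parallel (neuron id, time ms) arrays."""

    neuron_ids: np.ndarray
    times: np.ndarray
    n_neurons: int
    duration: float

    @classmethod
    def from_events(cls, events, n_neurons: int, duration: float) -> "SpikeRaster":
        events = list(events)
        ids = np.array([e[0] for e in events], dtype=np.int32)
        ts = np.array([e[1] for e in events], dtype=float)
        order = np.lexsort((ids, ts))
        return cls(ids[order], ts[order], n_neurons, duration)

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def spike_counts(self, t_start: float = 0.0, t_stop: float | None = None) -> np.ndarray:
        """Per-neuron spike counts within [t_start, t_stop)."""
        t_stop = self.duration if t_stop is None else t_stop
        sel = (self.times >= t_start) & (self.times < t_stop)
        return np.bincount(self.neuron_ids[sel], minlength=self.n_neurons)

    def spike_times_of(self, neuron: int) -> np.ndarray:
        return self.times[self.neuron_ids == neuron]

    def per_neuron_trains(self) -> list:
        order = np.argsort(self.neuron_ids, kind="stable")
        counts = np.bincount(self.neuron_ids, minlength=self.n_neurons)
        return np.split(self.times[order], np.cumsum(counts)[:-1])

    def window(self, t_start: float, t_stop: float) -> "SpikeRaster":
        sel = (self.times >= t_start) & (self.times < t_stop)
        return SpikeRaster(self.neuron_ids[sel], self.times[sel],
                           self.n_neurons, self.duration)

    def binned(self, bin_ms: float = 1.0, t_start: float = 0.0,
               t_stop: float | None = None) -> np.ndarray:
        """Binary (N, n_bins) matrix: did neuron i spike in bin b."""
        t_stop = self.duration if t_stop is None else t_stop
        n_bins = int(np.ceil((t_stop - t_start) / bin_ms))
        sel = (self.times >= t_start) & (self.times < t_stop)
        bins = ((self.times[sel] - t_start) // bin_ms).astype(np.intp)
        mat = np.zeros((self.n_neurons, n_bins), dtype=np.uint8)
        mat[self.neuron_ids[sel], bins] = 1
        return mat


@dataclass
class MCEvent:
    """One scheduled Martinotti inhibition window."""

    trigger_neuron: int
    onset: float       # spike time + delay (240 ms)
    offset: float      # onset + duration (120 ms)
    targets: np.ndarray


@dataclass
class SimResult:
    """Everything a finished run produces."""

    config: SimConfig
    seed: int
    ablation: str
    mc_fraction: float | None
    geometry: NetworkGeometry
    raster: SpikeRaster
    weights_initial: np.ndarray
    weights_final: np.ndarray
    stdp_counts: np.ndarray
    lbc_adj: np.ndarray
    mc_enabled: np.ndarray
    n_mc_events: int
    weight_snapshots: dict = field(default_factory=dict)

    @property
    def synapse_elimination_fraction(self) -> float:
        """Fraction of initial synapses pruned away over the run."""
        n0 = np.count_nonzero(self.weights_initial)
        n1 = np.count_nonzero(self.weights_final)
        return 1.0 - n1 / n0 if n0 else 0.0


def membrane_step(v, i_total, params: NeuronParams):
    """One leaky-integrator update of the membrane potential.

    ``V(t+dt) = (1 - dt/tau) V(t) + (dt/C) I(t) + (dt/tau) V_rest``
    """
    a = params.dt / params.tau
    return (1.0 - a) * np.asarray(v) + (params.dt / params.capacitance) * np.asarray(i_total) \
        + a * params.v_rest


def psp_current(gamma, v, params: NeuronParams):
    """Leak-compensated external drive producing an exact PSP of ``gamma`` mV.

    ``I = {gamma + (dt/tau) V - (dt/tau) V_rest} C/dt`` — feeding this into
    the membrane update changes the voltage by exactly ``gamma`` whatever
    the current voltage.
    """
    a = params.dt / params.tau
    return (np.asarray(gamma) + a * np.asarray(v) - a * params.v_rest) \
        * params.capacitance / params.dt


def synaptic_current(weight, params: NeuronParams):
    """Synaptic current ``I = gamma C / dt`` for a PSP amplitude in mV.

    Not leak-compensated: a single presynaptic spike delivers the full
    ``weight`` PSP only when the target sits at rest.
    """
    return np.asarray(weight) * params.capacitance / params.dt


class NetworkSimulator:
    """Stateful stepper for one network; drives LIF, inhibition and STDP.

    Martinotti windows are tracked with a rolling buffer of
    "neighbourhood hits": ``hit[t', i]`` counts spiking MC-enabled neurons
    whose neighbourhood contains i at step t', and neuron i is suppressed
    at step t when any hit falls in ``[t - delay - duration + 1, t - delay]``.
    """

    def __init__(self, config: SimConfig, seed: int, ablation: str = "full",
                 mc_fraction: float | None = None,
                 geometry: NetworkGeometry | None = None,
                 synapses: SynapticState | None = None):
        if ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}")
        config.validate()
        self.config = config
        self.seed = seed
        self.ablation = ablation
        self.mc_fraction = mc_fraction

        ss = np.random.SeedSequence(seed)
        s_net, s_input, s_plast, s_subset = ss.spawn(4)
        if geometry is None or synapses is None:
            geometry, synapses = build_network(config.geometry, config.connectivity,
                                               seed=s_net)
        if geometry.n_neurons != config.geometry.n_neurons:
            raise ValueError("geometry inconsistent with configured network size")
        if synapses.exc_weights.shape != (geometry.n_neurons,) * 2:
            raise ValueError("synaptic state inconsistent with geometry")
        self.geometry = geometry
        self.synapses = synapses
        self.n = geometry.n_neurons

        self.rng_input = np.random.default_rng(s_input)
        self.rng_plast = np.random.default_rng(s_plast)

        np_ = config.neuron
        self.dt = np_.dt
        self.v = np.full(self.n, np_.v_rest)
        self.refrac_left = np.zeros(self.n, dtype=np.int32)
        self._refrac_steps = int(round(np_.refractory / np_.dt))

        # MC machinery
        self.mc_enabled = np.ones(self.n, dtype=bool)
        if ablation == "no_mc":
            self.mc_enabled[:] = False
        elif mc_fraction is not None:
            rng = np.random.default_rng(s_subset)
            k = int(round(mc_fraction * self.n))
            self.mc_enabled[:] = False
            if k > 0:
                self.mc_enabled[rng.choice(self.n, size=k, replace=False)] = True
        self._mc_adj = synapses.mc_adjacency()
        self._mc_delay = int(round(config.mc.delay / np_.dt))
        self._mc_dur = int(round(config.mc.duration / np_.dt))
        self._mc_buflen = self._mc_delay + self._mc_dur
        self._mc_hits = np.zeros((self._mc_buflen, self.n), dtype=np.int32)
        self.mc_active = np.zeros(self.n, dtype=np.int32)  # active windows covering now
        # onset gating: a spike triggers a window only if the neuron's
        # previous window (delay + duration after its trigger) has expired,
        # so sustained firing yields one 120 ms window per activity onset
        self._mc_next_trigger = np.zeros(self.n, dtype=np.int64)
        self.n_mc_events = 0

        self.weights = synapses.exc_weights.copy()
        self.weights_initial = synapses.exc_weights.copy()
        self.stdp_counts = np.zeros((self.n, self.n), dtype=np.int32)
        self._refresh_synaptic_matrix()

        self.t = 0  # current step (ms)
        self.iteration = 0
        self._prev_spikers = np.empty(0, dtype=np.intp)
        self._input_steps = int(round(config.inputs.window_ms / np_.dt))
        self._iter_steps = int(round(config.plasticity.iteration_ms / np_.dt))
        self.input_pattern = np.zeros(self.n, dtype=bool)
        self._window_ids: list = []
        self._window_times: list = []
        self._events_ids: list = []
        self._events_times: list = []

    # -- internals ---------------------------------------------------------

    def _refresh_synaptic_matrix(self) -> None:
        """Combined PSP matrix: EPSP weights minus LBC IPSPs (if present)."""
        m = self.weights.copy()
        if self.ablation != "no_lbc":
            m -= self.config.connectivity.lbc_ipsp * self.synapses.lbc_adj
        self._syn_matrix = np.ascontiguousarray(m)

    def step(self) -> np.ndarray:
        """Advance one ms; returns the indices of neurons spiking this step."""
        cfg = self.config
        np_ = cfg.neuron
        t = self.t
        if t % self._input_steps == 0:
            self.input_pattern = generate_pattern(self.n, cfg.inputs.p_active,
                                                  self.rng_input)

        suppressed = (self.refrac_left > 0) | (self.mc_active > 0)

        # currents from last step's spikes (1 ms transmission delay)
        if self._prev_spikers.size:
            if self._prev_spikers.size > self.n // 8:
                s = np.zeros(self.n)
                s[self._prev_spikers] = 1.0
                syn_psp = s @ self._syn_matrix
            else:
                syn_psp = self._syn_matrix[self._prev_spikers].sum(axis=0)
        else:
            syn_psp = 0.0

        a = np_.dt / np_.tau
        drive = np.where(self.input_pattern,
                         cfg.inputs.drive_mv + a * (self.v - np_.v_rest), 0.0)
        v_new = (1.0 - a) * self.v + a * np_.v_rest + drive + syn_psp
        np.maximum(v_new, np_.v_floor, out=v_new)  # inhibitory reversal bound
        v_new[suppressed] = np_.v_rest
        self.refrac_left[suppressed] = np.maximum(self.refrac_left[suppressed] - 1, 0)

        spiking = ~suppressed & (v_new >= np_.v_thresh)
        spikers = np.flatnonzero(spiking)
        v_new[spikers] = np_.v_rest
        self.refrac_left[spikers] = self._refrac_steps
        self.v = v_new

        # schedule MC windows for MC-enabled spikers at an activity onset
        mc_spikers = spikers[self.mc_enabled[spikers]
                             & (self._mc_next_trigger[spikers] <= t)]
        self._mc_next_trigger[mc_spikers] = t + self._mc_buflen
        self.n_mc_events += mc_spikers.size
        slot = t % self._mc_buflen
        if mc_spikers.size:
            self._mc_hits[slot] = self._mc_adj[mc_spikers].sum(axis=0)
        else:
            self._mc_hits[slot] = 0
        # windows covering step t+1: triggers in [t+1-delay-dur, t-delay]
        add_t = t + 1 - self._mc_delay
        drop_t = t + 1 - self._mc_buflen
        if add_t >= 0:
            self.mc_active += self._mc_hits[add_t % self._mc_buflen]
        if drop_t >= 0:
            self.mc_active -= self._mc_hits[drop_t % self._mc_buflen]

        if spikers.size:
            self._window_ids.append(spikers)
            self._window_times.append(np.full(spikers.size, float(t)))
        self._prev_spikers = spikers
        self.t += 1

        # end of a learning iteration -> plasticity batch
        if self.t % self._iter_steps == 0 and self.iteration < cfg.plasticity.total_iterations:
            self._apply_plasticity()
        return spikers

    def _apply_plasticity(self) -> None:
        cfg = self.config
        delta = float(learning_rate(self.iteration, cfg.plasticity))
        if self._window_ids:
            ids = np.concatenate(self._window_ids)
            ts = np.concatenate(self._window_times)
        else:
            ids = np.empty(0, dtype=np.intp)
            ts = np.empty(0)
        apply_iteration_batch(self.weights, (ids, ts), delta, cfg.plasticity,
                              self.rng_plast, counts=self.stdp_counts)
        self._refresh_synaptic_matrix()
        self._events_ids.extend(self._window_ids)
        self._events_times.extend(self._window_times)
        self._window_ids = []
        self._window_times = []
        self.iteration += 1

    # -- public API --------------------------------------------------------

    def run(self, n_steps: int | None = None,
            snapshot_every: int | None = None) -> SimResult:
        """Run the full simulation (default: all configured iterations)."""
        cfg = self.config
        total = int(cfg.plasticity.total_iterations * self._iter_steps) \
            if n_steps is None else n_steps
        snapshots = {}
        while self.t < total:
            self.step()
            if snapshot_every and self.t % snapshot_every == 0:
                snapshots[self.t] = self.weights.copy()
        # flush any partial window's spikes into the raster
        self._events_ids.extend(self._window_ids)
        self._events_times.extend(self._window_times)
        self._window_ids, self._window_times = [], []
        if self._events_ids:
            ids = np.concatenate(self._events_ids)
            ts = np.concatenate(self._events_times)
        else:
            ids = np.empty(0, dtype=np.int32)
            ts = np.empty(0)
        raster = SpikeRaster(ids.astype(np.int32), ts, self.n, float(self.t * self.dt))
        return SimResult(
            config=cfg, seed=self.seed, ablation=self.ablation,
            mc_fraction=self.mc_fraction, geometry=self.geometry, raster=raster,
            weights_initial=self.weights_initial, weights_final=self.weights.copy(),
            stdp_counts=self.stdp_counts.copy(), lbc_adj=self.synapses.lbc_adj,
            mc_enabled=self.mc_enabled.copy(), n_mc_events=self.n_mc_events,
            weight_snapshots=snapshots,
        )


def run_simulation(config: SimConfig, seed: int, ablation: str = "full",
                   mc_fraction: float | None = None,
                   n_steps: int | None = None,
                   snapshot_every: int | None = None) -> SimResult:
    """Build a network from ``seed`` and run it to completion.

    ``ablation`` switches off basket-cell lateral inhibition (``no_lbc``)
    or the Martinotti pathway (``no_mc``); ``mc_fraction`` instead equips
    only a random fraction of PCs with the MC pathway.
    """
    sim = NetworkSimulator(config, seed, ablation=ablation, mc_fraction=mc_fraction)
    return sim.run(n_steps=n_steps, snapshot_every=snapshot_every)
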
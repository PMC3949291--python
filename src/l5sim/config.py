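"""Parameter containers for the layer-5 circuit simulation.

Defaults follow the standard configuration of the model: 1000 pyramidal
cells on a jittered cubic lattice, distance-dependent excitatory wiring,
basket-cell (LBC) lateral inhibition, Martinotti (MC) delayed
self-inhibition and stochastic STDP with exponentially declining learning
rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised for invalid or inconsistent configuration values."""


@dataclass
class GeometryParams:
    """Placement of pyramidal somata in a 3D cube of tissue.

    Neurons sit on a cubic lattice (36 um average spacing) with an
    independent uniform positional jitter of up to ``jitter_max`` um per
    coordinate.
    """

    n_neurons: int = 1000
    lattice_spacing: float = 36.0   # um
    jitter_max: float = 30.0        # um
    seed: int = 0

    def validate(self) -> None:
        if self.n_neurons < 8:
            raise ConfigError("n_neurons must be at least 8")
        if self.lattice_spacing <= 0:
            raise ConfigError("lattice_spacing must be positive")
        if self.jitter_max < 0:
            raise ConfigError("jitter_max must be non-negative")


@dataclass
class ConnectivityParams:
    """Wiring rules for the three connectivity structures.

    PC->PC synapses are sampled per ordered pair with probability
    ``((maxDist - d) / maxDist) ** pc_exponent`` and initialised uniformly
    in ``[init_weight_min, init_weight_max]`` mV EPSP.  LBC lateral
    inhibition links are sampled per unordered pair from a Gaussian kernel
    of the inter-somatic distance centred on ``lbc_mean_dist`` with spread
    maxDist/3 (or ``lbc_spread`` um if given), scaled to ``lbc_peak_prob``
    at the centre.  MC neighbourhoods are distance balls of radius
    ``mc_radius``.
    """

    pc_exponent: float = 5.0
    init_weight_min: float = 1.0    # mV EPSP
    init_weight_max: float = 4.0    # mV EPSP
    lbc_mean_dist: float = 40.0     # um
    lbc_spread: float | None = None  # um; None -> maxDist / 3
    lbc_peak_prob: float = 0.5
    lbc_ipsp: float = 1.5           # mV IPSP (applied with negative sign)
    mc_radius: float = 50.0         # um

    def validate(self) -> None:
        if self.pc_exponent <= 0:
            raise ConfigError("pc_exponent must be positive")
        if not (0 < self.init_weight_min <= self.init_weight_max):
            raise ConfigError("initial weight range must be positive and ordered")
        if self.lbc_mean_dist <= 0 or self.lbc_ipsp <= 0 or self.mc_radius <= 0:
            raise ConfigError("LBC/MC parameters must be positive")
        if not (0 <= self.lbc_peak_prob <= 1):
            raise ConfigError("lbc_peak_prob must lie in [0, 1]")


@dataclass
class NeuronParams:
    """Leaky integrate-and-fire membrane parameters for pyramidal cells."""

    v_rest: float = -65.0       # mV
    v_thresh: float = -40.0     # mV
    tau: float = 20.0           # ms, membrane time constant
    refractory: float = 1.0     # ms, absolute refractory period
    capacitance: float = 1.0    # arbitrary; cancels in the PSP-based currents
    dt: float = 1.0             # ms, integration step
    v_floor: float = -80.0      # mV; inhibitory reversal — summed IPSPs cannot
                                # drive the membrane below this bound

    def validate(self) -> None:
        if self.v_thresh <= self.v_rest:
            raise ConfigError("v_thresh must exceed v_rest")
        if self.v_floor > self.v_rest:
            raise ConfigError("v_floor must not exceed v_rest")
        if not (self.tau > self.dt > 0):
            raise ConfigError("need tau > dt > 0")
        if self.refractory < self.dt:
            raise ConfigError("refractory must be at least one step")


@dataclass
class McParams:
    """Timing of the Martinotti delayed self-inhibition window.

    A spike at time t paralyses the spiker's 50-um neighbourhood during
    [t + delay, t + delay + duration), i.e. 120 ms of suppression arriving
    240 ms after activity onset.
    """

    delay: float = 240.0        # ms from trigger spike to window onset
    duration: float = 120.0     # ms of suppression

    def validate(self) -> None:
        if self.delay <= 0 or self.duration <= 0:
            raise ConfigError("MC delay and duration must be positive")


@dataclass
class PlasticityParams:
    """Stochastic STDP rule, weight bounds and learning-rate schedule."""

    ltp_window: float = 20.0        # ms, phi_1
    ltd_window: float = 40.0        # ms, phi_2
    amplitude: float = 0.05         # maximal relative change per spike pair
    kernel_tau: float = 30.0        # ms, STDP kernel time scale
    weight_min: float = 0.05        # mV; below -> synapse pruned
    weight_max: float = 12.0        # mV; saturation
    iteration_ms: float = 40.0      # length of one learning iteration
    decay_constant: float = 550.0   # iterations; learning-rate e-folding
    total_iterations: int = 885
    # Per-iteration multiplicative weakening (1 - c*delta) of synapses untouched
    # by STDP.  c is calibrated analytically so the cumulative factor over the
    # declining learning-rate schedule prunes a little under half of all
    # synapses given the uniform 1-4 mV initialisation (see docs/methods.md).
    inactive_decay_coeff: float = 0.0092

    def validate(self) -> None:
        if not (self.ltd_window > self.ltp_window > 0):
            raise ConfigError("need ltd_window > ltp_window > 0")
        if not (self.weight_max > self.weight_min > 0):
            raise ConfigError("need weight_max > weight_min > 0")
        if self.total_iterations <= 0 or self.decay_constant <= 0:
            raise ConfigError("schedule parameters must be positive")


@dataclass
class InputParams:
    """Random binary drive: every neuron is an input channel.

    A binary pattern (independent Bernoulli(``p_active``) per channel) is
    held for ``window_ms`` and then regenerated.  Active channels receive a
    leak-compensated drive of ``drive_mv`` mV per step.
    """

    window_ms: float = 160.0
    drive_mv: float = 5.0
    p_active: float = 0.5

    def validate(self) -> None:
        if self.window_ms <= 0:
            raise ConfigError("window_ms must be positive")
        if not (0 <= self.p_active <= 1):
            raise ConfigError("p_active must lie in [0, 1]")


@dataclass
class SimConfig:
    """Full configuration of one simulation run."""

    geometry: GeometryParams = field(default_factory=GeometryParams)
    connectivity: ConnectivityParams = field(default_factory=ConnectivityParams)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    mc: McParams = field(default_factory=McParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    inputs: InputParams = field(default_factory=InputParams)

    def validate(self) -> None:
        for section in (self.geometry, self.connectivity, self.neuron,
                        self.mc, self.plasticity, self.inputs):
            section.validate()
        if self.inputs.window_ms % self.plasticity.iteration_ms != 0:
            raise ConfigError(
                "input window_ms must be a multiple of the learning iteration length")

    @property
    def duration_ms(self) -> float:
        return self.plasticity.total_iterations * self.plasticity.iteration_ms

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        sections = {
            "geometry": GeometryParams,
            "connectivity": ConnectivityParams,
            "neuron": NeuronParams,
            "mc": McParams,
            "plasticity": PlasticityParams,
            "inputs": InputParams,
        }
        kwargs = {}
        for name, klass in sections.items():
            if name in d:
                kwargs[name] = klass(**d[name]) if isinstance(d[name], dict) else d[name]
        extra = set(d) - set(sections)
        if extra:
            raise ConfigError(f"unknown config sections: {sorted(extra)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def small_config(n_neurons: int = 64, **overrides: Any) -> SimConfig:
    """Convenience constructor for small demonstration networks (e.g. 64 PCs)."""
    cfg = SimConfig()
    cfg.geometry.n_neurons = n_neurons
    for key, value in overrides.items():
        obj = cfg
        *parents, leaf = key.split(".")
        for p in parents:
            obj = getattr(obj, p)
        setattr(obj, leaf, value)
    cfg.validate()
    return cfg
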
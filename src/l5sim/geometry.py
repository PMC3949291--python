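"""Neuron placement and the three connectivity structures.

The network is a cube of simulated tissue: pyramidal cells (PCs) occupy a
jittered cubic lattice, excitatory PC->PC synapses are drawn with a
distance-dependent probability, large-basket-cell (LBC) lateral-inhibition
links are drawn from a Gaussian distance kernel, and each PC owns a
Martinotti (MC) neighbourhood — the ball of tissue it paralyses when
active.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .config import ConnectivityParams, GeometryParams


class InvalidGeometryError(ValueError):
    """Raised when a geometry cannot be constructed."""


@dataclass
class NetworkGeometry:
    """3D somatic positions plus the full pairwise distance structure.

    Attributes
    ----------
    positions : (N, 3) float array, um
    distances : (N, N) symmetric float array with zero diagonal, um
    max_dist : float
        Largest pairwise distance in the network (``maxDist``), the length
        scale of the excitatory wiring rule.
    """

    positions: np.ndarray
    distances: np.ndarray
    max_dist: float

    @property
    def n_neurons(self) -> int:
        return self.positions.shape[0]


@dataclass
class SynapticState:
    """The three connectivity structures of the circuit.

    ``exc_weights[i, j]`` is the EPSP amplitude (mV) of the directed
    synapse i -> j, zero meaning no synapse.  ``lbc_adj`` is the symmetric
    boolean lateral-inhibition adjacency.  ``mc_neighborhoods[i]`` lists
    the neurons (including i itself) paralysed when neuron i triggers its
    Martinotti pathway.
    """

    exc_weights: np.ndarray
    lbc_adj: np.ndarray
    mc_neighborhoods: list = field(default_factory=list)

    @property
    def n_neurons(self) -> int:
        return self.exc_weights.shape[0]

    @property
    def n_synapses(self) -> int:
        return int(np.count_nonzero(self.exc_weights))

    def mc_adjacency(self) -> np.ndarray:
        """Boolean (N, N) matrix: row i marks the targets of i's MC window."""
        n = self.n_neurons
        adj = np.zeros((n, n), dtype=bool)
        for i, nbhd in enumerate(self.mc_neighborhoods):
            adj[i, nbhd] = True
        return adj


def place_neurons(params: GeometryParams) -> NetworkGeometry:
    """Place N pyramidal cells on a jittered cubic lattice.

    The lattice is the smallest cube enclosing ``n_neurons`` sites,
    truncated to N in row-major order; each coordinate is then jittered
    independently by Uniform(-jitter_max, +jitter_max).
    """
    params.validate()
    n = params.n_neurons
    if n < 8:
        raise InvalidGeometryError("need at least 8 neurons for a 3D lattice")
    side = math.ceil(round(n ** (1.0 / 3.0), 9))
    grid = np.indices((side, side, side)).reshape(3, -1).T[:n].astype(float)
    positions = grid * params.lattice_spacing
    if params.jitter_max > 0:
        rng = np.random.default_rng(params.seed)
        positions = positions + rng.uniform(
            -params.jitter_max, params.jitter_max, size=positions.shape)
    distances = squareform(pdist(positions))
    return NetworkGeometry(
        positions=positions,
        distances=distances,
        max_dist=float(distances.max()),
    )


def connection_probability(distances: np.ndarray, max_dist: float,
                           exponent: float = 5.0) -> np.ndarray:
    """Distance-dependent PC->PC wiring probability.

    ``P = ((maxDist - d) / maxDist) ** exponent`` — exactly 1 at zero
    distance, exactly 0 at ``maxDist``, monotone non-increasing in d.
    """
    frac = np.clip((max_dist - np.asarray(distances, dtype=float)) / max_dist, 0.0, 1.0)
    return frac ** exponent


def init_pc_connectivity(geom: NetworkGeometry, params: ConnectivityParams,
                         seed: int | np.random.Generator = 0) -> np.ndarray:
    """Sample the initial excitatory weight matrix.

    Each ordered pair (i, j), i != j, is connected independently with the
    distance-dependent probability; created synapses get a uniform initial
    strength in ``[init_weight_min, init_weight_max]`` mV EPSP.
    """
    params.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = geom.n_neurons
    prob = connection_probability(geom.distances, geom.max_dist, params.pc_exponent)
    connected = rng.random((n, n)) < prob
    np.fill_diagonal(connected, False)
    weights = np.zeros((n, n))
    k = int(connected.sum())
    weights[connected] = rng.uniform(params.init_weight_min, params.init_weight_max, size=k)
    return weights


def lbc_link_probability(distances: np.ndarray, max_dist: float,
                         params: ConnectivityParams) -> np.ndarray:
    """Gaussian distance kernel for basket-cell lateral-inhibition links.

    Peaks at ``lbc_mean_dist`` (40 um) with spread maxDist/3, scaled so the
    peak probability equals ``lbc_peak_prob``.  The broad spread gives LBC
    links a longer reach than excitatory synapses, the precondition for
    Mexican-hat competition.
    """
    sigma = params.lbc_spread if params.lbc_spread is not None else max_dist / 3.0
    d = np.asarray(distances, dtype=float)
    return params.lbc_peak_prob * np.exp(-((d - params.lbc_mean_dist) ** 2) / (2.0 * sigma ** 2))


def init_lbc_connectivity(geom: NetworkGeometry, params: ConnectivityParams,
                          seed: int | np.random.Generator = 0) -> np.ndarray:
    """Sample the symmetric LBC lateral-inhibition adjacency.

    One Bernoulli draw per unordered pair, applied both ways: an
    interposed basket cell inhibits reciprocally.
    """
    params.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = geom.n_neurons
    prob = lbc_link_probability(geom.distances, geom.max_dist, params)
    upper = np.triu(rng.random((n, n)) < prob, k=1)
    return upper | upper.T


def mc_neighborhoods(geom: NetworkGeometry, radius: float) -> list:
    """Martinotti neighbourhood of each PC: all neurons within ``radius`` um.

    Every PC is the centre of its own neighbourhood (so it always contains
    itself), avoiding any built-in bias toward particular regions.
    """
    if radius <= 0:
        raise ValueError("MC neighbourhood radius must be positive")
    within = geom.distances <= radius
    return [np.flatnonzero(row) for row in within]


def build_network(geometry_params: GeometryParams, conn_params: ConnectivityParams,
                  seed=None) -> tuple[NetworkGeometry, SynapticState]:
    """Build geometry and all three connectivity structures from one seed."""
    if seed is None:
        seed = geometry_params.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_geom, s_pc, s_lbc = ss.spawn(3)
    geom = place_neurons(GeometryParams(
        n_neurons=geometry_params.n_neurons,
        lattice_spacing=geometry_params.lattice_spacing,
        jitter_max=geometry_params.jitter_max,
        seed=s_geom,
    ))
    weights = init_pc_connectivity(geom, conn_params, np.random.default_rng(s_pc))
    lbc = init_lbc_connectivity(geom, conn_params, np.random.default_rng(s_lbc))
    nbhds = mc_neighborhoods(geom, conn_params.mc_radius)
    return geom, SynapticState(exc_weights=weights, lbc_adj=lbc, mc_neighborhoods=nbhds)
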
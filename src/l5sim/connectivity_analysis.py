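"""Clustering and statistics of the evolved excitatory graph.

The developed network is compared against cortical slice findings with
the same toolchain used there: similarity between two neurons is their
number of common neighbors (NCN) in the (direction-agnostic) excitatory
graph, and affinity propagation with the common preference value of 2
carves the network into exemplar-based clusters.  Per-cluster statistics
(size, inner connectivity ratio, inner/outer synaptic strength, spatial
extent) and the common-neighbor rule (connection probability and strength
as functions of NCN) quantify how clustered the wiring has become.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning


@dataclass
class ClusterResult:
    """Exemplar-based partition of the network."""

    exemplars: np.ndarray          # neuron ids of the cluster exemplars
    labels: np.ndarray             # neuron -> cluster index
    converged: bool = True
    damping: float = 0.9

    @property
    def n_clusters(self) -> int:
        return self.exemplars.size

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)

    @property
    def mean_size(self) -> float:
        return float(self.sizes.mean())

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)


def undirected_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Either-direction neighbour relation of a (possibly directed) graph."""
    a = np.asarray(adjacency) != 0
    a = a | a.T
    np.fill_diagonal(a, False)
    return a


def ncn_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Number of common neighbors of every neuron pair.

    A neighbour is any neuron connected in either direction; the pair's
    own members never count as common neighbours (the adjacency carries no
    self-loops).  The diagonal is zeroed.
    """
    und = undirected_adjacency(adjacency).astype(np.int32)
    s = und @ und
    np.fill_diagonal(s, 0)
    return s


def ap_cluster(similarity: np.ndarray, preference: float = 2.0,
               damping: float = 0.9, max_iter: int = 1000,
               convergence_iter: int = 50, seed: int = 0) -> ClusterResult:
    """Affinity propagation on a precomputed similarity matrix.

    Frey-Dueck message passing (responsibilities/availabilities with
    damping) as implemented in scikit-learn.  On non-convergence the run
    is retried once with stronger damping (0.95); if that also fails the
    last partition is returned with ``converged=False``.
    """
    s = np.asarray(similarity, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("similarity must be a square matrix")
    if not np.allclose(s, s.T):
        raise ValueError("similarity must be symmetric")
    for attempt, damp in enumerate((damping, 0.95)):
        ap = AffinityPropagation(
            affinity="precomputed", preference=preference, damping=damp,
            max_iter=max_iter, convergence_iter=convergence_iter,
            random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            ap.fit(s)
        converged = ap.n_iter_ < max_iter
        ok = ap.cluster_centers_indices_ is not None and \
            len(ap.cluster_centers_indices_) > 0 and np.all(ap.labels_ >= 0)
        if ok and (converged or attempt == 1):
            return ClusterResult(
                exemplars=np.asarray(ap.cluster_centers_indices_),
                labels=np.asarray(ap.labels_), converged=converged, damping=damp)
        if ok and not converged:
            last = ClusterResult(
                exemplars=np.asarray(ap.cluster_centers_indices_),
                labels=np.asarray(ap.labels_), converged=False, damping=damp)
    if "last" in locals():
        warnings.warn("affinity propagation did not converge; returning last partition")
        return last
    raise RuntimeError("affinity propagation failed to produce a partition")


@dataclass
class ClusterStats:
    """Per-cluster table and pooled statistics of a connectivity partition."""

    per_cluster: pd.DataFrame
    mean_inner_ratio_pct: float          # mean over clusters of realized/possible, %
    pooled_inner_ratio_pct: float        # pooled over all within-cluster pairs, %
    overall_density_pct: float           # directed density of the whole graph, %
    mean_inner_strength: float           # mV, pooled over within-cluster synapses
    mean_outer_strength: float           # mV, pooled over between-cluster synapses
    n_inner_synapses: int
    n_outer_synapses: int
    strong_fraction_inner: float         # share of inner synapses above threshold
    strong_fraction_outer: float
    strong_threshold: float


def cluster_stats(clusters: ClusterResult, weights: np.ndarray,
                  positions: np.ndarray,
                  strong_threshold: float = 6.0) -> ClusterStats:
    """Connectivity statistics of an exemplar-based partition.

    The inner connectivity ratio of a cluster counts realized directed
    synapses among its members over all ordered member pairs; clusters of
    one neuron have no pairs and are excluded (with a warning).  Strength
    statistics pool synapses across clusters.  ``strong_threshold``
    (default 6 mV, half saturation) defines the "strong synapse" fraction.
    """
    w = np.asarray(weights)
    n = w.shape[0]
    labels = clusters.labels
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)
    conn = w > 0
    off_diag = n * (n - 1)

    inner_mask = conn & same
    outer_mask = conn & ~same
    np.fill_diagonal(outer_mask, False)
    n_inner = int(inner_mask.sum())
    n_outer = int(outer_mask.sum())
    inner_w = w[inner_mask]
    outer_w = w[outer_mask]

    rows = []
    for k in range(clusters.n_clusters):
        members = clusters.members(k)
        size = members.size
        if size < 2:
            warnings.warn(f"cluster {k} has fewer than two members; "
                          "excluded from ratio statistics")
            ratio = np.nan
            strength = np.nan
        else:
            sub = w[np.ix_(members, members)]
            possible = size * (size - 1)
            realized = int(np.count_nonzero(sub))
            ratio = 100.0 * realized / possible
            strength = float(sub[sub > 0].mean()) if realized else np.nan
        pos = positions[members]
        center = pos.mean(axis=0)
        diameter = 2.0 * float(np.linalg.norm(pos - center, axis=1).mean())
        rows.append({
            "cluster": k, "exemplar": int(clusters.exemplars[k]), "size": size,
            "inner_ratio_pct": ratio, "mean_inner_strength_mv": strength,
            "center_x": center[0], "center_y": center[1], "center_z": center[2],
            "diameter_um": diameter,
        })
    table = pd.DataFrame(rows)

    ratios = table["inner_ratio_pct"].dropna()
    return ClusterStats(
        per_cluster=table,
        mean_inner_ratio_pct=float(ratios.mean()) if len(ratios) else np.nan,
        pooled_inner_ratio_pct=100.0 * n_inner / max(int(same.sum()), 1),
        overall_density_pct=100.0 * int(conn.sum()) / off_diag,
        mean_inner_strength=float(inner_w.mean()) if n_inner else np.nan,
        mean_outer_strength=float(outer_w.mean()) if n_outer else np.nan,
        n_inner_synapses=n_inner,
        n_outer_synapses=n_outer,
        strong_fraction_inner=float((inner_w > strong_threshold).mean()) if n_inner else np.nan,
        strong_fraction_outer=float((outer_w > strong_threshold).mean()) if n_outer else np.nan,
        strong_threshold=strong_threshold,
    )


def ncn_rule(adjacency: np.ndarray, weights: np.ndarray) -> pd.DataFrame:
    """Connection probability and strength as functions of common neighbours.

    For every unordered neuron pair, tabulates by NCN value the empirical
    probability that the pair is connected (either direction) and the mean
    strength of the directed synapses between connected pairs.  NCN values
    with no pairs are omitted.
    """
    s = ncn_similarity(adjacency)
    w = np.asarray(weights)
    und = undirected_adjacency(adjacency)
    iu = np.triu_indices(s.shape[0], k=1)
    ncn = s[iu]
    connected = und[iu]
    # mean of the existing directed weights between each pair
    wsum = w[iu] + w.T[iu]
    wcnt = (w[iu] > 0).astype(int) + (w.T[iu] > 0).astype(int)
    pair_strength = np.divide(wsum, wcnt, out=np.full(wsum.shape, np.nan),
                              where=wcnt > 0)
    rows = []
    for value in np.unique(ncn):
        sel = ncn == value
        n_pairs = int(sel.sum())
        conn_sel = connected & sel
        n_conn = int(conn_sel.sum())
        rows.append({
            "ncn": int(value),
            "n_pairs": n_pairs,
            "p_connect": n_conn / n_pairs,
            "mean_strength_mv": float(np.nanmean(pair_strength[conn_sel]))
            if n_conn else np.nan,
        })
    return pd.DataFrame(rows)


def gini_coefficient(values: np.ndarray) -> float:
    """Gini coefficient of a non-negative sample; 0 for uniform, ->1 degenerate."""
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0 or np.any(x < 0):
        raise ValueError("need a non-empty, non-negative sample")
    total = x.sum()
    if total == 0:
        return 0.0
    n = x.size
    ranks = np.arange(1, n + 1)
    return float((2.0 * (ranks * x).sum() / (n * total)) - (n + 1.0) / n)


@dataclass
class StdpSpread:
    """Concentration metrics of STDP events across the network."""

    gini: float
    top_region_fraction: float
    n_regions: int
    total_events: int


def stdp_event_spread(stdp_counts: np.ndarray, positions: np.ndarray,
                      synapse_mask: np.ndarray | None = None,
                      n_regions_per_axis: int = 2) -> StdpSpread:
    """How evenly plasticity events spread over synapses and space.

    ``gini`` measures inequality of per-synapse event counts over
    ``synapse_mask`` (default: every synapse that saw at least one event
    or still exists in the counts' support).  ``top_region_fraction`` is
    the share of all events falling in the single busiest spatial block
    when the tissue cube is split into ``n_regions_per_axis**3`` blocks
    (events located at the presynaptic soma).
    """
    counts = np.asarray(stdp_counts)
    if synapse_mask is None:
        synapse_mask = counts > 0
    values = counts[synapse_mask]
    g = gini_coefficient(values) if values.size else 0.0

    pos = np.asarray(positions, dtype=float)
    lo = pos.min(axis=0)
    hi = pos.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    cell = np.minimum(((pos - lo) / span * n_regions_per_axis).astype(int),
                      n_regions_per_axis - 1)
    block = cell[:, 0] * n_regions_per_axis ** 2 + cell[:, 1] * n_regions_per_axis + cell[:, 2]
    per_neuron_events = counts.sum(axis=1)  # events at the presynaptic soma
    total = int(per_neuron_events.sum())
    if total == 0:
        frac = 0.0
    else:
        per_block = np.bincount(block, weights=per_neuron_events,
                                minlength=n_regions_per_axis ** 3)
        frac = float(per_block.max() / total)
    return StdpSpread(gini=g, top_region_fraction=frac,
                      n_regions=n_regions_per_axis ** 3, total_events=total)
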
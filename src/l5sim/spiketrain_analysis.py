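"""Firing-pattern analysis: who fires with whom, and when.

Neurons are compared by their binned spike trains over the last quarter
of a run (the evolved regime): Manhattan distance between binary trains,
PCA of the distance matrix down to five components (which capture ~99% of
its variance), and a Gaussian-mixture model whose component count is
chosen by minimal BIC.  Clusters whose members almost never fire are
flagged silent and dropped from downstream analysis.  Oscillation and
alternation between the surviving clusters are read off auto- and
cross-correlograms of each cluster's most active unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .dynamics import SpikeRaster


def _resolve_window(raster: SpikeRaster, window) -> tuple[float, float]:
    """Default analysis window: the last quarter of the run."""
    if window is None:
        return 0.75 * raster.duration, raster.duration
    return float(window[0]), float(window[1])


def spike_distance_matrix(raster: SpikeRaster, bin_ms: float = 1.0,
                          window: tuple[float, float] | None = None) -> np.ndarray:
    """Manhattan distance between binned binary spike trains.

    Trains are binned at ``bin_ms`` (default the 1 ms simulation
    resolution) into 0/1 vectors; the distance between two neurons is the
    number of bins where exactly one of them spiked — on binary vectors
    Manhattan and Hamming distances coincide.
    """
    t0, t1 = _resolve_window(raster, window)
    if t1 <= t0:
        raise ValueError("empty analysis window")
    b = raster.binned(bin_ms=bin_ms, t_start=t0, t_stop=t1).astype(np.float32)
    counts = b.sum(axis=1)
    overlap = b @ b.T
    d = counts[:, None] + counts[None, :] - 2.0 * overlap
    d = np.maximum(d, 0.0)
    np.fill_diagonal(d, 0.0)
    return d.astype(float)


@dataclass
class ActivityClusterResult:
    """Gaussian-mixture partition of neurons by firing similarity."""

    labels: np.ndarray              # neuron -> cluster
    n_components: int               # BIC-selected k
    bic_by_k: dict = field(default_factory=dict)
    embedding: np.ndarray | None = None          # (N, 5) principal components
    explained_variance_ratio: np.ndarray | None = None
    silent: np.ndarray | None = None             # per-cluster: almost never fired
    cluster_rates_hz: np.ndarray | None = None   # per-cluster mean rate in window

    @property
    def active_clusters(self) -> np.ndarray:
        if self.silent is None:
            return np.arange(self.n_components)
        return np.flatnonzero(~self.silent)

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)


def embed_and_cluster(distances: np.ndarray, rates_hz: np.ndarray | None = None,
                      n_components_pca: int = 5, k_range: tuple[int, int] = (2, 12),
                      silent_rate_hz: float = 1.0, n_init: int = 10,
                      seed: int = 0) -> ActivityClusterResult:
    """PCA embedding of the distance matrix plus BIC-selected mixture model.

    The rows of the distance matrix are the feature vectors; the first
    ``n_components_pca`` (5) principal components span the embedding.
    Gaussian mixtures with k in ``k_range`` are fitted (full covariance,
    ``n_init`` seeded restarts, with a diagonal-covariance retry under
    degeneracy) and the k of minimal BIC wins.  If per-neuron firing
    ``rates_hz`` are given, clusters with mean rate below
    ``silent_rate_hz`` are flagged silent.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distances must be a square matrix")
    # whitened components: distance-matrix rows are strongly correlated, so the
    # raw embedding has near-degenerate covariance slivers that inflate mixture
    # likelihoods; unit-scale features with a fixed covariance floor keep the
    # BIC minimum interior
    pca = PCA(n_components=n_components_pca, whiten=True, random_state=seed)
    emb = pca.fit_transform(d)

    best = None
    bic_by_k = {}
    # degenerate (collapsed) embeddings fall back to ever-stronger regularisation
    attempts = (("full", 1e-2), ("diag", 1e-2), ("diag", 1e-1), ("spherical", 1e-1))
    for k in range(k_range[0], k_range[1] + 1):
        if k >= d.shape[0]:
            break
        gmm = None
        for cov_type, reg in attempts:
            try:
                cand = GaussianMixture(n_components=k, covariance_type=cov_type,
                                       n_init=n_init, random_state=seed,
                                       reg_covar=reg)
                cand.fit(emb)
                gmm = cand
                if (cov_type, reg) != attempts[0]:
                    warnings.warn(f"degenerate covariance at k={k}; used "
                                  f"{cov_type} covariance with reg_covar={reg}")
                break
            except ValueError:
                continue
        if gmm is None:
            continue
        bic = gmm.bic(emb)
        bic_by_k[k] = float(bic)
        if best is None or bic < best[0]:
            best = (bic, k, gmm)
    if best is None:
        warnings.warn("all mixture fits failed; returning a single cluster")
        return ActivityClusterResult(
            labels=np.zeros(d.shape[0], dtype=int), n_components=1,
            bic_by_k={}, embedding=emb,
            explained_variance_ratio=pca.explained_variance_ratio_,
            silent=None if rates_hz is None else
            np.array([np.asarray(rates_hz).mean() < silent_rate_hz]),
            cluster_rates_hz=None if rates_hz is None else
            np.array([float(np.asarray(rates_hz).mean())]))
    _, k_best, gmm = best
    labels = gmm.predict(emb)

    silent = None
    cluster_rates = None
    if rates_hz is not None:
        rates_hz = np.asarray(rates_hz, dtype=float)
        cluster_rates = np.array([
            rates_hz[labels == k].mean() if np.any(labels == k) else 0.0
            for k in range(k_best)])
        silent = cluster_rates < silent_rate_hz
    return ActivityClusterResult(
        labels=labels, n_components=k_best, bic_by_k=bic_by_k, embedding=emb,
        explained_variance_ratio=pca.explained_variance_ratio_,
        silent=silent, cluster_rates_hz=cluster_rates)


def mean_firing_rate(raster: SpikeRaster, window: tuple[float, float] | None = None,
                     active_only: bool = False, active_threshold_hz: float = 1.0) -> float:
    """Mean firing rate in Hz over the analysis window.

    Total spikes divided by (number of neurons x window length); with
    ``active_only`` the average runs over neurons exceeding
    ``active_threshold_hz`` only.
    """
    t0, t1 = _resolve_window(raster, window)
    span_s = (t1 - t0) / 1000.0
    if span_s <= 0:
        return 0.0
    rates = raster.spike_counts(t0, t1) / span_s
    if active_only:
        rates = rates[rates > active_threshold_hz]
        if rates.size == 0:
            return 0.0
    return float(rates.mean())


def per_neuron_rates(raster: SpikeRaster,
                     window: tuple[float, float] | None = None) -> np.ndarray:
    t0, t1 = _resolve_window(raster, window)
    return raster.spike_counts(t0, t1) / ((t1 - t0) / 1000.0)


def cluster_representatives(raster: SpikeRaster, result: ActivityClusterResult,
                            window: tuple[float, float] | None = None) -> dict:
    """Most active unit of each retained (non-silent) cluster."""
    counts = raster.spike_counts(*_resolve_window(raster, window))
    reps = {}
    for k in result.active_clusters:
        members = result.members(k)
        if members.size:
            reps[int(k)] = int(members[np.argmax(counts[members])])
    return reps


def activity_shares(raster: SpikeRaster, labels: np.ndarray,
                    window: tuple[float, float] | None = None) -> np.ndarray:
    """Per-cluster percentage of all network spikes in the window."""
    counts = raster.spike_counts(*_resolve_window(raster, window))
    n_clusters = int(labels.max()) + 1 if labels.size else 0
    shares = np.array([counts[labels == k].sum() for k in range(n_clusters)], dtype=float)
    total = shares.sum()
    return 100.0 * shares / total if total > 0 else shares


def top_fraction_share(raster: SpikeRaster, fraction: float = 0.05,
                       window: tuple[float, float] | None = None) -> float:
    """Share of all spikes produced by the most active ``fraction`` of neurons."""
    counts = raster.spike_counts(*_resolve_window(raster, window))
    total = counts.sum()
    if total == 0:
        return 0.0
    k = max(int(round(fraction * raster.n_neurons)), 1)
    top = np.sort(counts)[::-1][:k].sum()
    return float(top / total)


def mean_within_cluster_distance(result: ActivityClusterResult,
                                 positions: np.ndarray,
                                 clusters: np.ndarray | None = None) -> float:
    """Mean pairwise inter-somatic distance within the given clusters (um).

    Defaults to the retained (non-silent) clusters; the per-cluster mean
    pairwise distances are averaged with equal cluster weight.
    """
    if clusters is None:
        clusters = result.active_clusters
    pos = np.asarray(positions, dtype=float)
    per_cluster = []
    for k in clusters:
        members = result.members(int(k))
        if members.size < 2:
            continue
        p = pos[members]
        diff = p[:, None, :] - p[None, :, :]
        d = np.linalg.norm(diff, axis=2)
        iu = np.triu_indices(members.size, k=1)
        per_cluster.append(float(d[iu].mean()))
    return float(np.mean(per_cluster)) if per_cluster else np.nan


def correlogram(train_a: np.ndarray, train_b: np.ndarray | None = None,
                max_lag_ms: float = 500.0, bin_ms: float = 10.0):
    """Auto- or cross-correlogram of spike trains.

    Histogram of all pairwise spike-time differences ``t_b - t_a`` within
    ``+-max_lag_ms``; for the auto-correlogram (``train_b`` omitted) the
    zero-difference self pairs are excluded.  Returns (bin centers, counts).
    """
    a = np.sort(np.asarray(train_a, dtype=float))
    auto = train_b is None
    b = a if auto else np.sort(np.asarray(train_b, dtype=float))
    edges = np.arange(-max_lag_ms, max_lag_ms + bin_ms, bin_ms)
    counts = np.zeros(edges.size - 1)
    lo = np.searchsorted(b, a - max_lag_ms, side="left")
    hi = np.searchsorted(b, a + max_lag_ms, side="right")
    diffs = []
    for t, i0, i1 in zip(a, lo, hi):
        d = b[i0:i1] - t
        diffs.append(d)
    if diffs:
        d = np.concatenate(diffs)
        if auto:
            d = d[d != 0]
        counts, _ = np.histogram(d, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts


@dataclass
class CorrelogramSet:
    """Auto- and cross-correlograms of the cluster representatives."""

    lags_ms: np.ndarray
    auto: dict                      # rep id -> counts
    cross: dict                     # (rep a, rep b) -> counts

    def auto_peak_lag(self, rep: int, min_lag_ms: float = 0.0) -> float:
        """Lag (>min_lag_ms) of the highest auto-correlogram peak."""
        counts = self.auto[rep]
        mask = self.lags_ms > min_lag_ms
        idx = np.flatnonzero(mask)[np.argmax(counts[mask])]
        return float(self.lags_ms[idx])


def correlograms(raster: SpikeRaster, representatives: dict,
                 max_lag_ms: float = 500.0, bin_ms: float = 10.0,
                 window: tuple[float, float] | None = None) -> CorrelogramSet:
    """Correlograms of each retained cluster's most active unit.

    ``representatives`` maps cluster -> neuron id (see
    :func:`cluster_representatives`).  Representatives with fewer than two
    spikes in the window are skipped with a warning.
    """
    t0, t1 = _resolve_window(raster, window)
    trains = {}
    for k, rep in representatives.items():
        tr = raster.spike_times_of(rep)
        tr = tr[(tr >= t0) & (tr < t1)]
        if tr.size < 2:
            warnings.warn(f"representative {rep} of cluster {k} has fewer than "
                          "two spikes in the window; skipped")
            continue
        trains[rep] = tr
    lags = None
    auto = {}
    cross = {}
    reps = sorted(trains)
    for rep in reps:
        lags, counts = correlogram(trains[rep], max_lag_ms=max_lag_ms, bin_ms=bin_ms)
        auto[rep] = counts
    for i, ra in enumerate(reps):
        for rb in reps[i + 1:]:
            lags, counts = correlogram(trains[ra], trains[rb],
                                       max_lag_ms=max_lag_ms, bin_ms=bin_ms)
            cross[(ra, rb)] = counts
    if lags is None:
        edges = np.arange(-max_lag_ms, max_lag_ms + bin_ms, bin_ms)
        lags = 0.5 * (edges[:-1] + edges[1:])
    return CorrelogramSet(lags_ms=lags, auto=auto, cross=cross)
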
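"""End-to-end experiments: simulate, analyse, aggregate across seeds.

The named experiments mirror the model's headline analyses: the standard
1000-neuron run, the two ablations (no lateral inhibition, no Martinotti
pathway), the MC-fraction sweep and the 64-neuron demonstration network.
Each experiment runs one simulation per seed, applies both analysis
pipelines and reports every statistic as mean +- SD across seeds.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .config import SimConfig, small_config
from .connectivity_analysis import (ap_cluster, cluster_stats, ncn_similarity,
                                    stdp_event_spread)
from .dynamics import SimResult, run_simulation
from .io import save_run, write_json
from .spiketrain_analysis import (activity_shares, embed_and_cluster,
                                  mean_firing_rate, mean_within_cluster_distance,
                                  per_neuron_rates, spike_distance_matrix,
                                  top_fraction_share)

EXPERIMENTS = ("standard", "ablate_lbc", "ablate_mc", "mc_sweep", "small64")


def analyze_connectivity(result: SimResult, preference: float = 2.0,
                         seed: int = 0) -> dict:
    """Cluster the evolved excitatory graph and extract its statistics."""
    adjacency = result.weights_final > 0
    sim = ncn_similarity(adjacency)
    clusters = ap_cluster(sim, preference=preference, seed=seed)
    stats = cluster_stats(clusters, result.weights_final, result.geometry.positions)
    spread = stdp_event_spread(result.stdp_counts, result.geometry.positions,
                               synapse_mask=result.weights_initial > 0)
    return {
        "n_clusters": clusters.n_clusters,
        "mean_cluster_size": clusters.mean_size,
        "inner_ratio_pct": stats.mean_inner_ratio_pct,
        "pooled_inner_ratio_pct": stats.pooled_inner_ratio_pct,
        "overall_density_pct": stats.overall_density_pct,
        "inner_strength_mv": stats.mean_inner_strength,
        "outer_strength_mv": stats.mean_outer_strength,
        "strong_fraction_inner": stats.strong_fraction_inner,
        "strong_fraction_outer": stats.strong_fraction_outer,
        "elimination_fraction": result.synapse_elimination_fraction,
        "stdp_gini": spread.gini,
        "stdp_top_region_fraction": spread.top_region_fraction,
        "ap_converged": clusters.converged,
    }


def analyze_firing(result: SimResult, seed: int = 0,
                   k_range: tuple[int, int] = (2, 12)) -> dict:
    """Cluster neurons by firing similarity and extract rate statistics."""
    raster = result.raster
    distances = spike_distance_matrix(raster)
    rates = per_neuron_rates(raster)
    act = embed_and_cluster(distances, rates_hz=rates, k_range=k_range, seed=seed)
    shares = activity_shares(raster, act.labels)
    active = act.active_clusters
    top4 = np.sort(shares[active])[::-1][:4] if active.size else np.empty(0)
    return {
        "mean_rate_hz": mean_firing_rate(raster),
        "mean_rate_active_hz": mean_firing_rate(raster, active_only=True),
        "n_activity_clusters": int(act.n_components),
        "n_active_clusters": int(active.size),
        "within_cluster_distance_um": mean_within_cluster_distance(
            act, result.geometry.positions),
        "pca_variance_5": float(act.explained_variance_ratio[:5].sum()),
        "top4_shares_pct": top4,
        "top4_share_dispersion": float(np.std(top4)) if top4.size else np.nan,
        "top5pct_neuron_share": top_fraction_share(raster, 0.05),
        "rate_cv": float(np.std(rates) / np.mean(rates)) if np.mean(rates) > 0 else np.nan,
    }


def analyze_run(result: SimResult, seed: int = 0) -> dict:
    """Both analysis pipelines on one finished run."""
    n = result.geometry.n_neurons
    k_range = (2, 12) if n >= 256 else (2, 8)
    return {"connectivity": analyze_connectivity(result, seed=seed),
            "firing": analyze_firing(result, seed=seed, k_range=k_range)}


def _aggregate(per_seed: list[dict]) -> dict:
    """mean +- SD of every scalar statistic across seeds."""
    out = {}
    keys = per_seed[0].keys()
    for key in keys:
        values = [d[key] for d in per_seed]
        if isinstance(values[0], (bool, np.bool_)):
            out[key] = {"all": bool(np.all(values))}
        elif np.isscalar(values[0]) or isinstance(values[0], (int, float, np.floating, np.integer)):
            arr = np.asarray(values, dtype=float)
            out[key] = {"mean": float(np.nanmean(arr)),
                        "sd": float(np.nanstd(arr, ddof=1)) if arr.size > 1 else 0.0}
        else:
            out[key] = {"values": [np.asarray(v).tolist() for v in values]}
    return out


def run_experiment(name: str, seeds: Sequence[int], config: SimConfig | None = None,
                   out_dir: str | Path | None = None,
                   mc_fractions: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
                   save_runs: bool = False) -> dict:
    """Run a named experiment over seeds and return its report.

    ``standard`` / ``ablate_lbc`` / ``ablate_mc`` run the 1000-neuron
    network with the corresponding circuit configuration; ``small64`` runs
    the 64-neuron demonstration network; ``mc_sweep`` runs the standard
    network with only a fraction of PCs triggering MC inhibition, for each
    fraction in ``mc_fractions``.
    """
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; choose from {EXPERIMENTS}")
    if config is None:
        config = small_config(64) if name == "small64" else SimConfig()
    config.validate()
    ablation = {"ablate_lbc": "no_lbc", "ablate_mc": "no_mc"}.get(name, "full")

    report = {"experiment": name, "seeds": list(map(int, seeds)),
              "n_neurons": config.geometry.n_neurons}
    out = Path(out_dir) if out_dir is not None else None

    if name == "mc_sweep":
        sweep = {}
        for frac in mc_fractions:
            per_seed = []
            for seed in seeds:
                res = run_simulation(config, int(seed), mc_fraction=float(frac))
                stats = analyze_run(res, seed=int(seed))
                per_seed.append(_flatten(stats))
                if save_runs and out is not None:
                    save_run(res, out / f"mc_{frac:.2f}" / f"seed_{seed}")
            sweep[f"{frac:.2f}"] = _aggregate(per_seed)
        report["mc_fractions"] = list(map(float, mc_fractions))
        report["by_fraction"] = sweep
        report["balance_curve"] = {
            f: sweep[f]["firing.top4_share_dispersion"]["mean"] for f in sweep}
    else:
        per_seed = []
        for seed in seeds:
            res = run_simulation(config, int(seed), ablation=ablation)
            stats = analyze_run(res, seed=int(seed))
            per_seed.append(_flatten(stats))
            if save_runs and out is not None:
                save_run(res, out / f"seed_{seed}")
        report["statistics"] = _aggregate(per_seed)

    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        write_json(report, out / "report.json")
    return report


def _flatten(nested: dict, prefix: str = "") -> dict:
    flat = {}
    for key, value in nested.items():
        name = f"{prefix}{key}"
        if isinstance(value, dict):
            flat.update(_flatten(value, prefix=f"{name}."))
        else:
            flat[name] = value
    return flat
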
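"""Develop a network under STDP and cluster what it learned.

Runs a scaled standard simulation (512 neurons, full 885-iteration
schedule, ~1 min), then applies both analysis pipelines: affinity
propagation on common-neighbour similarity for the wiring, and
Manhattan-distance / PCA / Gaussian-mixture clustering for the firing.
"""

import l5sim

cfg = l5sim.SimConfig()
cfg.geometry.n_neurons = 512

print("simulating (512 neurons, 35.4 s biological time) ...")
res = l5sim.run_simulation(cfg, seed=1)
print(f"  {res.raster.n_spikes} spikes; "
      f"{100 * res.synapse_elimination_fraction:.0f}% of synapses eliminated")

conn = l5sim.analyze_connectivity(res, seed=1)
print("wiring analysis (affinity propagation on NCN similarity):")
print(f"  {conn['n_clusters']} clusters, mean size {conn['mean_cluster_size']:.1f}")
print(f"  inner connectivity ratio {conn['inner_ratio_pct']:.1f}% "
      f"(network density {conn['overall_density_pct']:.1f}%)")
print(f"  mean synapse strength inside clusters {conn['inner_strength_mv']:.2f} mV, "
      f"between clusters {conn['outer_strength_mv']:.2f} mV")

fir = l5sim.analyze_firing(res, seed=1, k_range=(2, 10))
print("firing analysis (last quarter of the run):")
print(f"  mean rate {fir['mean_rate_hz']:.1f} Hz "
      f"({fir['mean_rate_active_hz']:.1f} Hz over active neurons)")
print(f"  {fir['n_active_clusters']} active firing clusters; "
      f"within-cluster somatic distance {fir['within_cluster_distance_um']:.0f} um")
print(f"  first five principal components explain "
      f"{100 * fir['pca_variance_5']:.1f}% of distance variance")
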
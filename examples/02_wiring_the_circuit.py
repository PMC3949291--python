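"""Build the standard 1000-neuron circuit and inspect its wiring.

Pyramidal cells sit on a jittered cubic lattice (36 um spacing, up to
30 um jitter).  Excitatory synapses are sampled per ordered pair with
probability ((maxDist - d)/maxDist)^5, basket-cell lateral-inhibition
links from a broad Gaussian distance kernel peaking at 40 um, and each
neuron owns a 50 um Martinotti neighbourhood.
"""

import numpy as np

import l5sim

geom, syn = l5sim.build_network(l5sim.GeometryParams(),
                                l5sim.ConnectivityParams(), seed=1)
n = geom.n_neurons
d = geom.distances
iu = np.triu_indices(n, 1)

density = 100 * syn.n_synapses / (n * (n - 1))
print(f"neurons: {n}, max pairwise distance {geom.max_dist:.0f} um, "
      f"mean {d[iu].mean():.0f} um")
print(f"excitatory synapses: {syn.n_synapses} ({density:.1f}% of ordered pairs), "
      f"initial weights {syn.exc_weights[syn.exc_weights > 0].min():.2f}"
      f"-{syn.exc_weights.max():.2f} mV EPSP")
print(f"mean length of excitatory links: {d[syn.exc_weights > 0].mean():.0f} um")
print(f"LBC lateral-inhibition links: {syn.lbc_adj.sum() // 2} pairs, "
      f"mean length {d[syn.lbc_adj].mean():.0f} um")
print(f"MC neighbourhood size: {np.mean([len(nb) for nb in syn.mc_neighborhoods]):.1f} "
      "neurons (the cell plus its nearby lattice neighbours)")
print("Inhibition reaches farther than excitation -> Mexican-hat competition.")
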
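"""Drive response of one pyramidal cell.

An active input channel injects a leak-compensated current worth exactly
5 mV of depolarisation per millisecond.  From rest (-65 mV) a neuron
needs five such steps to reach threshold (-40 mV); with the 1 ms
refractory step that makes a 6 ms firing period.
"""

import numpy as np

import l5sim

cfg = l5sim.small_config(8, **{"connectivity.lbc_peak_prob": 0.0,
                               "inputs.p_active": 1.0})
sim = l5sim.NetworkSimulator(cfg, seed=1, ablation="no_mc")
sim.weights[:] = 0.0          # isolate the neurons: drive only
sim._refresh_synaptic_matrix()
result = sim.run(n_steps=1200)

train = result.raster.spike_times_of(0)
isi = np.diff(train)
print(f"first spikes at t = {train[:4].astype(int).tolist()} ms")
print(f"inter-spike interval: {isi.mean():.0f} ms "
      f"-> firing rate {1000 / isi.mean():.2f} Hz")
print("The 6 ms period = 5 integration steps (5 mV each, -65 -> -40 mV) "
      "+ 1 ms refractory.")
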
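# l5sim — competitive learning in a model of neocortical layer 5

Layer 5 of the neocortex contains, besides its pyramidal cells (PCs), two
dominant interneuron families with opposite circuit roles: parvalbumin-
expressing large basket cells (LBCs), the canonical *lateral* inhibitors,
and somatostatin-expressing Martinotti cells (MCs), which feed *delayed,
prolonged self-inhibition* back onto the local PC neighbourhood that
excited them.  `l5sim` simulates the development of such a circuit: a
network of leaky integrate-and-fire PCs, driven by random binary input,
rewired by stochastic spike-timing-dependent plasticity (STDP), with LBC
inhibition supplying Mexican-hat competition and the MC pathway acting as
a "conscience" that silences overly successful regions so others can win.
The package is for computational neuroscientists studying how local
inhibitory motifs shape activity-dependent wiring — in particular how
competitive learning can produce the clustered PC connectivity observed
in slice physiology without any innate wiring plan — and, on the machine-
learning side, how a biologically local mechanism addresses the dead-unit
problem of competitive learning.

## Model

Membrane dynamics (per 1 ms step, `dt`):

    V(t+Δt) = (1 − Δt/τ) V(t) + (Δt/C) I(t) + (Δt/τ) V_rest

with `V_rest = −65 mV`, threshold `−40 mV`, `τ = 20 ms`, a 1 ms absolute
refractory period, and a lower bound at the inhibitory reversal
(−80 mV).  Active input channels inject the leak-compensated current
`I = {γ + (Δt/τ)(V − V_rest)} C/Δt` with `γ = 5 mV` (so a driven neuron
fires at exactly 1000/6 ≈ 166.7 Hz); a presynaptic spike across a synapse
of amplitude γ injects `I = γ C/Δt` (the full PSP only at rest).  Each
spiking LBC-linked neighbour contributes a −1.5 mV IPSP; a spike of an
MC-equipped PC paralyses its 50 µm neighbourhood for 120 ms starting
240 ms after the activity onset.

Synaptic development follows a stochastic multiplicative STDP rule for a
pre/post spike-time difference Δt (nearest-spike pairing, asymmetric
windows φ₁ = 20 ms, φ₂ = 40 ms):

    A ← A (1 + 0.05 e^(−Δt/30) r δ)        0 ≤ Δt < φ₁   (LTP)
    A ← A (1 − 0.05 e^(−(Δt/30)²) r δ)    −φ₂ < Δt < 0   (LTD)

with `r ~ U(0,1)` per event and a global learning rate
`δ(i) = exp(−i/550)` over 885 learning iterations of 40 ms.  Synapses
untouched by STDP in an iteration weaken by `(1 − 0.0092 δ)`; weights
saturate at 12 mV and are pruned below 0.05 mV.  Wiring is initialised
distance-dependently, `P(connect) = ((maxDist − d)/maxDist)⁵`, with
uniform 1–4 mV strengths on a jittered cubic lattice (36 µm spacing).

Two analysis pipelines quantify the evolved network: affinity propagation
(preference 2) on number-of-common-neighbours (NCN) similarity for the
wiring, and Manhattan spike-train distance → 5-component PCA →
BIC-selected Gaussian mixtures for the firing patterns, plus correlogram
and activity-share analyses.

## Worked example

`python examples/04_development_and_clustering.py` (512 neurons, full
885-iteration schedule, about a minute):

```
simulating (512 neurons, 35.4 s biological time) ...
  1287561 spikes; 46% of synapses eliminated
wiring analysis (affinity propagation on NCN similarity):
  13 clusters, mean size 39.4
  inner connectivity ratio 15.6% (network density 7.0%)
  mean synapse strength inside clusters 3.20 mV, between clusters 2.87 mV
firing analysis (last quarter of the run):
  mean rate 90.3 Hz (147.2 Hz over active neurons)
  2 active firing clusters; within-cluster somatic distance 170 um
  first five principal components explain 98.8% of distance variance
```

Development prunes just under half of the initial synapses while firing
settles into high-gamma (~90 Hz) alternating synchronized groups; the
surviving graph is denser and stronger within clusters than between
them.  The other examples cover the single-neuron drive response, the
wiring rules, the circuit-ablation regimes of a 64-neuron network, and
oscillation/alternation correlograms.  A thin CLI wraps the same
machinery: `l5sim simulate --seed 1 --out run/`, `l5sim analyze --in
run/`, `l5sim run --experiment standard --seeds 1..5 --out exp/`.

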
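# Methods

## The circuit model

The simulated tissue is a cube of N pyramidal cells (1000 standard) on a
cubic lattice of 36 µm spacing, each coordinate independently jittered by
up to ±30 µm.  Only PCs are spiking units; the two interneuron pathways
are modelled as their effect on PCs:

- **Excitatory wiring.**  Each ordered pair (i, j) is connected with
  probability `((maxDist − d_ij)/maxDist)^5`, where `maxDist` is the
  largest inter-somatic distance in the network.  On the standard
  geometry this realizes ~12–13% directed density with mean link length
  ~150 µm.  Initial strengths are uniform in [1, 4] mV EPSP.  Synapses
  are directed; the sampling is independent per direction.
- **Basket-cell (LBC) lateral inhibition.**  One Bernoulli draw per
  unordered pair from a Gaussian kernel of distance centred at 40 µm with
  spread `maxDist/3`, scaled to a peak probability of 0.5; links act
  symmetrically, delivering a −1.5 mV IPSP to the partner for every
  spike.  The kernel is nearly flat over the cube, so inhibition reaches
  much farther than excitation — the Mexican-hat precondition.
- **Martinotti (MC) self-inhibition.**  Every PC owns the 50 µm ball
  around its soma (itself included).  When an MC-equipped PC starts
  firing, its ball is paralysed — clamped to rest, unable to spike — for
  120 ms beginning 240 ms after the onset.  *Onset* means: a spike
  triggers a window only if the neuron's previous window (trigger +
  360 ms) has expired.  Triggering per spike instead would let every
  spike of a burst extend the suppression to an effective 360 ms and
  slow the network's alternation cycle to ~600 ms; onset triggering
  preserves the pathway's stated 120 ms duration and yields a ~360 ms
  burst/yield cycle.  Ablations: `no_lbc`, `no_mc`, or `mc_fraction`
  (only a random subset of PCs is MC-equipped).

### Membrane dynamics

Per 1 ms step: `V ← (1 − Δt/τ)V + (Δt/C)I + (Δt/τ)V_rest` with
V_rest = −65 mV, threshold −40 mV (tested after the update), reset to
rest, τ = 20 ms, 1 ms absolute refractory.  External drive on active
input channels is leak-compensated (adds exactly 5 mV per step), so a
driven neuron fires with a 6 ms period — 5 integration steps plus the
refractory step — i.e. at 1000/6 ≈ 166.7 Hz.  Synaptic currents are not
leak-compensated: a lone presynaptic spike moves a resting target by
exactly the synaptic amplitude.  Spikes take one step (1 ms) to act.
The membrane is bounded below at −80 mV (an inhibitory-reversal bound):
without it, summed IPSPs from tens of simultaneously spiking LBC
partners drive the linear integrator thousands of mV below rest, a
numerically degenerate regime with no biological counterpart.  The
choice of bound is not critical (−80 and −65 give similar network
statistics); some bound is.

### Input

Every neuron is an input channel.  A binary pattern (independent
Bernoulli(0.5) per channel) is held for 160 ms — four learning
iterations — then redrawn.  Active channels receive the 5 mV/ms
leak-compensated drive.

### Plasticity

STDP events are computed per 40 ms learning iteration from the window's
spikes.  For every existing synapse whose endpoints both spiked, each
postsynaptic spike is paired with its nearest presynaptic spike
(ties resolve to the earlier, potentiating side); pairs within
(−40, +20) ms contribute one multiplicative update

    LTP (0 ≤ Δt < 20):   × (1 + 0.05 · e^(−Δt/30) · r · δ)
    LTD (−40 < Δt < 0):  × (1 − 0.05 · e^(−(Δt/30)²) · r · δ)

with fresh `r ~ U(0,1)` per event and global learning rate
`δ(i) = e^(−i/550)` over 885 iterations.  The LTD kernel is
Gaussian-like so depression stays sensitive across its wider window.
Nearest-spike pairing (one event per postsynaptic spike) was chosen over
all-to-all: with the comb-like 6 ms bursting this network produces,
all-to-all pairing accumulates more depression than potentiation even
for synchronous pairs (the LTD window is twice as wide), collapsing all
weights — inconsistent with the bimodal end state the rule is known to
produce.  Synapses untouched by STDP in an iteration are weakened by
`(1 − c·δ)`; weights saturate at 12 mV and are pruned below 0.05 mV,
and a pruned synapse never returns (the rule is multiplicative).

**Calibration of the weakening coefficient c.**  The magnitude of the
periodic weakening is a free constant with an outsized, nearly
step-like effect: a never-potentiated synapse of initial weight w₀
survives the run iff `w₀ · exp(−c · Σᵢ δ(i)) ≥ 0.05`, and
`Σᵢ δ(i) = 550(1 − e^(−885/550)) ≈ 439.9`.  With c = 0.01 the survival
threshold exceeds 4 mV, so *every* untouched synapse dies (measured
elimination: 74% of all synapses).  We set c by requiring the
developmental outcome this model targets — elimination of a little
under half of all synapses: with w₀ ~ U(1, 4), solving
`untouched_share · (0.05/e^(−439.9c) − 1)/3 ≈ 0.45` gives c = 0.0092.
Measured elimination across seeds is 0.46–0.49.  The constant was fixed
once from this closed-form argument and not revisited.

### Simulation procedure

885 learning iterations × 40 ms = 35,400 steps.  Per step: refresh the
input pattern if at a 160 ms boundary; suppressed neurons (refractory or
inside any MC window) clamp to rest; all others integrate drive plus the
previous step's synaptic PSPs; threshold crossers spike, reset, and
(if MC-equipped, at an onset) schedule an MC window over their ball.
At each iteration boundary the STDP batch, the inactive weakening and
the bounds are applied.  MC windows are tracked with a rolling
360-row buffer of neighbourhood hit counts, so the per-step cost is
O(N) plus one gather over the spikers' rows of the combined PSP matrix.
A full 1000-neuron run takes ~40 s on one CPU (the pairing inner loop is
numba-jitted, with an equivalent vectorised numpy fallback).

## Analysis pipelines

**Wiring.**  Similarity between neurons = number of common neighbours
(NCN) in the either-direction adjacency of the final pruned graph,
excluding the pair itself.  Affinity propagation (scikit-learn's
Frey–Dueck message passing; damping 0.9, retry at 0.95 on
non-convergence; preference 2) partitions the network into
exemplar-based clusters.  Per cluster we report size, inner connectivity
ratio (realized directed synapses over ordered member pairs; singleton
clusters excluded), pooled inner/outer synaptic strengths, the strong-
synapse fraction (threshold 6 mV, half saturation), and center/diameter.
The NCN rule table bins unordered pairs by NCN value and reports
connection probability and mean strength.  STDP-event spread is
summarised by the Gini coefficient over per-synapse event counts and the
share of events in the busiest spatial octant.

**Firing.**  The last quarter of the run is binned at the 1 ms
resolution; Manhattan distance between the binary trains (≡ Hamming) is
embedded with 5 whitened principal components and clustered with
Gaussian mixtures, k ∈ [2, 12], 10 seeded restarts, minimal BIC.
Whitening plus a covariance floor (reg_covar 10⁻², with diag/spherical
fallbacks) is essential: distance-matrix rows are strongly correlated,
and without it mixture likelihoods diverge along near-degenerate
covariance slivers and BIC saturates at the top of the k range (planted
three-population rasters then come back as k = 6 with ARI ≈ 0.8; with
whitening they are recovered exactly, stably across restarts).  Clusters
whose members average < 1 Hz are flagged silent and dropped; activity
shares, top-percentile dominance, within-cluster somatic distance (over
the retained clusters), and auto/cross-correlograms of each retained
cluster's most active unit complete the picture.  A Victor–Purpura-style
metric is deliberately not implemented; Manhattan distance on 1 ms bins
is the operative proxy and is exact for this simulator's integer-ms
spikes.

## What the generator emulates — and what it does not

All inputs are synthetic by design: the random binary drive stands in
for ongoing cortical input, and the jittered lattice for a uniform
tissue volume.  The model omits conductance-based synapses, dendrites,
synaptic delays beyond 1 ms, short-term plasticity, spiking interneuron
dynamics, inhibition of inhibition, and laminar structure.  Passing
tests therefore demonstrate properties of this abstraction, not of
cortex: in particular, millisecond-exact synchrony (all driven neurons
share the same 6 ms comb) is an artifact of the deterministic
integer-ms grid and makes co-active groups potentiate each other
bidirectionally and near-instantly.

## Known limitations

With every stated constant in place, the developed wiring is coarser
than the slice-scale statistics the model family aims at: winner
identity is decided by recurrent EPSP volleys (tens of mV per step at
the network's ~90 spikes/ms) rather than by the 5 mV input drive, so the
same recurrently dense minority wins every input pattern and STDP wires
a handful of large communities (~85–100 members, somatic spread
~130 µm) rather than many small ones.  Cluster counts from affinity
propagation land near 15–25 at mean sizes 40–65, inner connectivity
ratios near 15%, and inner/outer strengths near 4.7/3.5 mV.  This
granularity is insensitive to every free constant we scanned (LBC peak
probability 0.25–1.0, membrane floor, AP damping, directed vs
undirected NCN); the analysis stage itself recovers planted fine
structure correctly.  Mean firing rate (~84–96 Hz), synapse elimination
(0.46–0.49), the drive response, the initial density, and all ablation
contrasts that depend on the LBC pathway are robust.  Reported numbers
in `results/acceptance.json` are computed fresh on every run of
`scripts/acceptance.py`.
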
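"""Stochastic spike-timing-dependent plasticity.

The rule is multiplicative and Hebbian with asymmetric windows: a
pre-before-post interval Delta t in [0, 20) ms potentiates a synapse by up
to 5% of its current strength, a post-before-pre interval in (-40, 0) ms
depresses it, and each event is scaled by an independent uniform random
scalar r in [0, 1] and the global learning rate delta.  The potentiation
kernel is exponential, ``exp(-dt/30)``; the depression kernel is the
Gaussian-like ``exp(-(dt/30)^2)``, decaying more slowly over the wider
40 ms window.

Around the per-pair rule sit three batch mechanisms applied once per 40 ms
learning iteration: nearest-spike pairing of the window's spike trains,
a small multiplicative weakening ``(1 - 0.01*delta)`` of every synapse the
window's STDP left untouched, and the global weight bounds — saturation at
12 mV, pruning below 0.05 mV.  Pruned synapses never return: the
multiplicative rule cannot create a synapse.
"""

from __future__ import annotations

import numpy as np

from .config import PlasticityParams


def learning_rate(iteration: int, params: PlasticityParams) -> float:
    """Global learning rate ``delta(i) = exp(-i / decay_constant)``.

    Starts at 1, declines exponentially with e-folding ``decay_constant``
    (550) iterations over the ``total_iterations`` (885) of a run, so the
    network reorganises early and fine-tunes late, SOM-style.
    """
    it = np.asarray(iteration)
    if np.any(it < 0) or np.any(it >= params.total_iterations):
        raise ValueError(
            f"iteration must lie in [0, {params.total_iterations})")
    return np.exp(-it / params.decay_constant)


def stdp_factor(delta_t, r, delta, params: PlasticityParams):
    """Multiplicative STDP factor for spike-time difference ``delta_t`` ms.

    Vectorised over all arguments.  Outside both windows the factor is 1.
    ``delta_t = 0`` (synchronous) falls in the potentiation branch.
    """
    dt = np.asarray(delta_t, dtype=float)
    r = np.asarray(r, dtype=float)
    scaled = dt / params.kernel_tau
    ltp = (dt >= 0) & (dt < params.ltp_window)
    ltd = (dt < 0) & (dt > -params.ltd_window)
    factor = np.ones(np.broadcast(dt, r).shape)
    amp = params.amplitude * r * delta
    factor = np.where(ltp, 1.0 + amp * np.exp(-scaled), factor)
    factor = np.where(ltd, 1.0 - amp * np.exp(-(scaled ** 2)), factor)
    if factor.ndim == 0:
        return float(factor)
    return factor


def stdp_update(a, delta_t, r, delta, params: PlasticityParams):
    """New strength of a synapse of strength ``a`` after one spike pair."""
    return a * stdp_factor(delta_t, r, delta, params)


def pair_spikes(pre_train, post_train, params: PlasticityParams) -> np.ndarray:
    """Nearest-spike pairing of two sorted spike trains.

    For each postsynaptic spike, the presynaptic spike closest in time
    contributes one ``delta_t = t_post - t_pre``, kept only if it falls in
    the plasticity-sensitive range ``(-ltd_window, ltp_window)``.  A tie in
    ``|delta_t|`` resolves to the earlier presynaptic spike (the
    potentiation side).
    """
    pre = np.asarray(pre_train, dtype=float)
    post = np.asarray(post_train, dtype=float)
    if pre.size == 0 or post.size == 0:
        return np.empty(0)
    idx = np.searchsorted(pre, post)
    left = np.clip(idx - 1, 0, pre.size - 1)
    right = np.clip(idx, 0, pre.size - 1)
    d_left = post - pre[left]      # >= 0 for in-order candidates
    d_right = post - pre[right]
    best = np.where(np.abs(d_left) <= np.abs(d_right), d_left, d_right)
    keep = (best > -params.ltd_window) & (best < params.ltp_window)
    return best[keep]


def apply_bounds(weights: np.ndarray, params: PlasticityParams) -> np.ndarray:
    """Clip to saturation (12 mV) and prune below the lower bound (0.05 mV).

    Operates in place and returns the array.  Zeros stay zero.
    """
    np.minimum(weights, params.weight_max, out=weights)
    weights[weights < params.weight_min] = 0.0
    return weights


try:  # fast pairing kernel; the numpy path below is the portable fallback
    from numba import njit

    @njit(cache=True)
    def _pair_events_kernel(pre_idx, post_idx, table, counts, ltp, ltd,
                            out_syn, out_dt):  # pragma: no cover - numba
        m = 0
        for s in range(pre_idx.size):
            i = pre_idx[s]
            j = post_idx[s]
            ci = counts[i]
            cj = counts[j]
            for q in range(cj):
                tq = table[j, q]
                best = 1e300
                for p in range(ci):
                    d = tq - table[i, p]
                    if abs(d) < abs(best) or (abs(d) == abs(best) and d > best):
                        best = d
                if -ltd < best < ltp:
                    out_syn[m] = s
                    out_dt[m] = best
                    m += 1
        return m

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _pair_events_numpy(pre_idx, post_idx, table, spike_counts, params):
    """Vectorised nearest-spike pairing over a batch of synapses."""
    t_post = table[post_idx]            # (S, K)
    t_pre = table[pre_idx]              # (S, K)
    with np.errstate(invalid="ignore"):
        dt = t_post[:, :, None] - t_pre[:, None, :]
    dt = np.where(np.isnan(dt) | ~np.isfinite(dt), np.inf, dt)
    nearest = np.argmin(np.abs(dt), axis=2)
    s_ix = np.arange(pre_idx.size)[:, None]
    best = dt[s_ix, np.arange(t_post.shape[1])[None, :], nearest]
    valid_post = np.arange(t_post.shape[1])[None, :] < spike_counts[post_idx][:, None]
    events = valid_post & (best > -params.ltd_window) & (best < params.ltp_window)
    syn_of_event, _ = np.nonzero(events)
    return syn_of_event, best[events]


def _pair_events(pre_idx, post_idx, table, spike_counts, params):
    if _HAVE_NUMBA:
        cap = int(spike_counts[post_idx].sum())
        out_syn = np.empty(cap, dtype=np.intp)
        out_dt = np.empty(cap)
        m = _pair_events_kernel(pre_idx, post_idx, table,
                                spike_counts.astype(np.intp),
                                float(params.ltp_window), float(params.ltd_window),
                                out_syn, out_dt)
        return out_syn[:m], out_dt[:m]
    return _pair_events_numpy(pre_idx, post_idx, table, spike_counts, params)


def _padded_spike_times(neuron_ids: np.ndarray, times: np.ndarray, n: int):
    """Per-neuron spike times of one window as a padded (n, K) array.

    Returns (table, counts); padding entries hold +inf so they can never
    win a nearest-spike comparison.
    """
    counts = np.bincount(neuron_ids, minlength=n)
    k = int(counts.max()) if counts.size else 0
    table = np.full((n, max(k, 1)), np.inf)
    order = np.argsort(neuron_ids, kind="stable")  # stable keeps time order
    sorted_ids = neuron_ids[order]
    starts = np.concatenate(([0], np.cumsum(counts)))
    cols = np.arange(neuron_ids.size) - starts[sorted_ids]
    table[sorted_ids, cols] = times[order]
    return table, counts


def apply_iteration_batch(weights: np.ndarray, raster_window, delta: float,
                          params: PlasticityParams, rng: np.random.Generator,
                          counts: np.ndarray | None = None):
    """Apply one 40 ms learning iteration's plasticity to ``weights``.

    ``raster_window`` is an ``(neuron_ids, times)`` pair of equal-length
    arrays holding the window's spikes.  For every existing synapse whose
    pre- and postsynaptic neurons both spiked, each postsynaptic spike is
    paired with its nearest presynaptic spike and, if the interval falls in
    the STDP-sensitive range, contributes one multiplicative update with a
    fresh r ~ Uniform(0, 1).  Synapses untouched by STDP this window are
    weakened by ``(1 - inactive_decay_coeff * delta)``; finally bounds and
    pruning are applied.

    Returns ``(weights, counts)`` where ``counts`` accumulates per-synapse
    STDP event counts (created if not supplied).  ``weights`` is modified
    in place.
    """
    n = weights.shape[0]
    if counts is None:
        counts = np.zeros((n, n), dtype=np.int32)
    neuron_ids = np.asarray(raster_window[0], dtype=np.intp)
    times = np.asarray(raster_window[1], dtype=float)

    decay = 1.0 - params.inactive_decay_coeff * delta
    existing = weights > 0

    if neuron_ids.size:
        table, spike_counts = _padded_spike_times(neuron_ids, times, n)
        spiked = spike_counts > 0
        # synapses whose two endpoints both spiked this window
        cand = existing & spiked[:, None] & spiked[None, :]
        pre_idx, post_idx = np.nonzero(cand)
    else:
        pre_idx = np.empty(0, dtype=np.intp)

    if pre_idx.size:
        syn_of_event, dts = _pair_events(pre_idx, post_idx, table, spike_counts, params)
        r = rng.random(dts.size)
        factors = stdp_factor(dts, r, delta, params)
        log_gain = np.bincount(syn_of_event, weights=np.log(factors),
                               minlength=pre_idx.size)
        n_events = np.bincount(syn_of_event, minlength=pre_idx.size)
        touched = n_events > 0
        # weaken everything, then give touched synapses their STDP product instead
        weights *= decay
        tp, to = pre_idx[touched], post_idx[touched]
        weights[tp, to] *= np.exp(log_gain[touched]) / decay
        counts[tp, to] += n_events[touched].astype(np.int32)
    else:
        weights *= decay

    apply_bounds(weights, params)
    return weights, counts
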
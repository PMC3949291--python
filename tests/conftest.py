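import numpy as np
import pytest

import l5sim


@pytest.fixture(scope="session")
def standard_geometry():
    """Standard 1000-neuron jittered-lattice geometry."""
    return l5sim.place_neurons(l5sim.GeometryParams(seed=1))


@pytest.fixture(scope="session")
def small_run():
    """A short 64-neuron run used by tests that need a realistic raster."""
    cfg = l5sim.small_config(64)
    return l5sim.run_simulation(cfg, seed=5, n_steps=8000)


@pytest.fixture(scope="session")
def standard_run():
    """One full standard 1000-neuron run (shared across the suite)."""
    return l5sim.run_simulation(l5sim.SimConfig(), seed=11)


def make_raster(trains, duration, n_neurons=None):
    """Build a SpikeRaster from per-neuron spike-time lists."""
    ids, times = [], []
    for i, tr in enumerate(trains):
        ids.extend([i] * len(tr))
        times.extend(tr)
    n = n_neurons if n_neurons is not None else len(trains)
    ids = np.asarray(ids, dtype=np.int32)
    times = np.asarray(times, dtype=float)
    order = np.lexsort((ids, times))
    return l5sim.SpikeRaster(ids[order], times[order], n, float(duration))
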
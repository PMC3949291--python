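"""Random binary input drive.

Every neuron doubles as an input channel: the outside world is a binary
vector of length N, redrawn every 160 ms (four learning iterations) with
each channel independently active with probability 0.5.  Active channels
receive a constant leak-compensated drive of 5 mV per millisecond, which
alone pushes a resting neuron to fire at ~166 Hz.
"""

from __future__ import annotations

import numpy as np

from .config import ConfigError


def generate_pattern(n: int, p: float, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw one i.i.d. Bernoulli(p) binary pattern of length n."""
    if not (0.0 <= p <= 1.0):
        raise ConfigError("activation probability must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.random(n) < p


def pattern_schedule(duration_ms: float, window_ms: float,
                     iteration_ms: float) -> np.ndarray:
    """Times (ms) at which the input pattern is regenerated.

    Patterns are held constant for ``window_ms``, which must cover a whole
    number of learning iterations (160 / 40 = 4 in the standard setup).
    """
    if window_ms <= 0 or iteration_ms <= 0:
        raise ConfigError("window and iteration lengths must be positive")
    if window_ms % iteration_ms != 0:
        raise ConfigError(
            f"input window ({window_ms} ms) must be divisible by the learning "
            f"iteration length ({iteration_ms} ms)")
    return np.arange(0.0, duration_ms, window_ms)
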
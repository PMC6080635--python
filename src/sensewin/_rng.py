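"""Deterministic stream splitting for nested Monte-Carlo loops.

Every source of randomness in the package is a ``numpy.random.Generator``
built from a ``SeedSequence`` whose entropy is the user-supplied integer
seed and whose ``spawn_key`` identifies the consumer (tree index,
re-randomization replicate, ...).  Two consumers with different keys draw
from independent streams, and the whole hierarchy is reproducible across
platforms from the single root seed.
"""

from __future__ import annotations

import numpy as np


def spawn_rng(seed: int, *key: int) -> np.random.Generator:
    """Generator for stream ``key`` of the hierarchy rooted at ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def derive_seed(seed: int, *key: int) -> int:
    """A 31-bit integer seed derived deterministically from ``seed`` and ``key``."""
    state = np.random.SeedSequence(entropy=seed, spawn_key=key).generate_state(1, np.uint32)
    return int(state[0] & 0x7FFFFFFF)


def as_rng(rng_state: int | np.random.Generator | None) -> np.random.Generator:
    """Normalize an int seed / Generator / None into a Generator."""
    if isinstance(rng_state, np.random.Generator):
        return rng_state
    return np.random.default_rng(rng_state)
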
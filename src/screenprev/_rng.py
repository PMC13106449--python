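"""Deterministic stream splitting for all randomness in the package.

Every stochastic component derives its generator from a single user seed
through :func:`rng_for`, keyed by a stage name and optional integer
sub-keys.  Streams are independent (``numpy.random.SeedSequence`` spawn
keys), so modules can be exercised in isolation and a recorded seed is
sufficient to re-run any stage bit-identically.
"""

from __future__ import annotations

import numpy as np

# Fixed stage table: the spawn key of a stage never changes between releases,
# otherwise recorded seeds stop reproducing.
_STAGES = {
    "cohort": 0,
    "latent": 1,
    "grid": 2,
    "probabilistic": 3,
    "replicates": 4,
    "pipeline": 5,
}


def rng_for(seed: int, stage: str, *subkeys: int) -> np.random.Generator:
    """Return the PCG64 generator for ``stage`` (and sub-keys) under ``seed``."""
    if stage not in _STAGES:
        raise KeyError(f"unknown RNG stage {stage!r}; known: {sorted(_STAGES)}")
    key = (_STAGES[stage], *subkeys)
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=key)))


def child_seed(seed: int, stage: str, *subkeys: int) -> int:
    """A derived 31-bit integer seed for components that take plain ints."""
    if stage not in _STAGES:
        raise KeyError(f"unknown RNG stage {stage!r}; known: {sorted(_STAGES)}")
    key = (_STAGES[stage], *subkeys)
    state = np.random.SeedSequence(seed, spawn_key=key).generate_state(1)[0]
    return int(state) % (2**31 - 1)
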
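"""Seed management: one root seed, independent named substreams.

Every stochastic component of the engine (environment redraws, move
resolution, demography, migration, observation noise, strategy
randomness) pulls from its own named :class:`numpy.random.Generator`.
Substreams are derived from the root seed with a fixed per-name spawn
key, so adding a new component never perturbs the streams of existing
ones and any component can be replayed in isolation.
"""

from __future__ import annotations

import numpy as np

# Fixed indices; append only, never renumber (replay stability).
STREAM_IDS: dict[str, int] = {
    "environment": 0,
    "moves": 1,
    "demography": 2,
    "migration": 3,
    "observation": 4,
    "strategies": 5,
}

STREAM_NAMES = tuple(STREAM_IDS)


def substream(root_seed: int, name: str) -> np.random.Generator:
    """Return the named generator derived from ``root_seed``."""
    try:
        idx = STREAM_IDS[name]
    except KeyError:
        raise KeyError(f"unknown stream {name!r}; known: {sorted(STREAM_IDS)}") from None
    return np.random.default_rng(np.random.SeedSequence(root_seed, spawn_key=(idx,)))


def make_streams(root_seed: int) -> dict[str, np.random.Generator]:
    """All named substreams for one simulation run."""
    return {name: substream(root_seed, name) for name in STREAM_IDS}


def derive_seed(root_seed: int, index: int) -> int:
    """A child seed (< 2**31) for run ``index`` of a batch.

    Used to give every contest / replicate in a tournament schedule its
    own independent root seed while keeping the whole schedule a pure
    function of the batch seed.
    """
    ss = np.random.SeedSequence(root_seed, spawn_key=(0x5EED, index))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
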
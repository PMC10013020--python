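"""Deterministic seed derivation.

Every source of randomness in the package draws from a generator spawned off
one master seed through a fixed key scheme, so that any reported number can be
reproduced from (inputs, master seed) alone.
"""
from __future__ import annotations

import numpy as np

__all__ = ["spawn_rng", "spawn_seed"]


def _seed_sequence(master: int | None, key: tuple[int, ...]) -> np.random.SeedSequence:
    if master is None:
        # non-reproducible fallback: fresh OS entropy
        return np.random.SeedSequence()
    return np.random.SeedSequence(int(master), spawn_key=tuple(int(k) for k in key))


def spawn_rng(master: int | None, *key: int) -> np.random.Generator:
    """Generator deterministically derived from ``master`` and an integer key path."""
    return np.random.default_rng(_seed_sequence(master, key))


def spawn_seed(master: int | None, *key: int) -> int:
    """A 31-bit integer seed deterministically derived from ``master`` and a key path."""
    return int(_seed_sequence(master, key).generate_state(1)[0] % (2**31))
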
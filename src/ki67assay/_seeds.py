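"""Deterministic seed splitting.

A single run seed expands into independent child streams keyed by string or
integer labels. Keys are hashed into a ``SeedSequence`` spawn key, so adding a
new generator (new key) never perturbs the streams of existing generators.
"""

from __future__ import annotations

import hashlib

import numpy as np


def seed_sequence(seed: int, *keys) -> np.random.SeedSequence:
    """Child seed sequence for ``seed`` under a tuple of hashable labels."""
    spawn_key = tuple(
        int.from_bytes(hashlib.sha256(repr(k).encode("utf8")).digest()[:4], "little")
        for k in keys
    )
    return np.random.SeedSequence(int(seed), spawn_key=spawn_key)


def child_rng(seed: int, *keys) -> np.random.Generator:
    """Independent PCG64 generator for the given seed and key path."""
    return np.random.Generator(np.random.PCG64(seed_sequence(seed, *keys)))
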
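"""Deterministic seed derivation.

Every source of randomness in the package is a ``numpy.random.Generator``
built from a master seed plus a tuple of integer keys (subject index, grid
index, node, repetition, ...) through ``numpy.random.SeedSequence`` spawn
keys.  The derivation is stable: adding a later key value (e.g. one more
subject or repetition) never changes the stream of an earlier one, and
evaluation order is irrelevant.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rng_for", "derive_seed"]


def rng_for(master_seed: int, *keys: int) -> np.random.Generator:
    """Return an independent Generator for (master_seed, *keys)."""
    ss = np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(k) for k in keys))
    return np.random.default_rng(ss)


def derive_seed(master_seed: int, *keys: int) -> int:
    """Return a derived integer seed below 2**31 for (master_seed, *keys)."""
    ss = np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(k) for k in keys))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
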
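"""Deterministic random-stream management.

Every public operation that consumes randomness takes a single integer seed.
Internally a root :class:`numpy.random.SeedSequence` is split into named child
streams so that partial re-runs (e.g. regenerating only the spot field of a
larger simulation) reproduce bit-identical output.  The splitting rule is:
``stream(seed, *keys)`` builds ``SeedSequence(entropy=[seed, crc32(k) for k in
keys])`` — stable across sessions and platforms.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "spawn"]


def stream(seed: int, *keys: str) -> np.random.Generator:
    """Return a :class:`numpy.random.Generator` for a named child stream."""
    entropy = [int(seed)] + [zlib.crc32(k.encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def spawn(seed: int, key: str, n: int) -> list[np.random.Generator]:
    """Return *n* independent generators under one named stream."""
    entropy = [int(seed), zlib.crc32(key.encode())]
    return [np.random.default_rng(s) for s in np.random.SeedSequence(entropy).spawn(n)]
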
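"""Deterministic seed derivation.

One root seed drives everything; every operation derives an independent
stream from (root seed, operation tag, replicate index) so that any
replicate is reproducible in isolation.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "generator"]


def derive_seed(root: int, *tags: object) -> int:
    """Derive a child seed (< 2**31) from a root seed and a tag tuple.

    Hash-based so that unrelated tags give statistically independent
    streams and the mapping is stable across platforms and sessions.
    """
    h = hashlib.blake2b(digest_size=8)
    h.update(str(int(root)).encode())
    for t in tags:
        h.update(b"\x1f")
        h.update(repr(t).encode())
    # keep strictly positive: msprime requires seed >= 1
    return int.from_bytes(h.digest(), "little") % (2**31 - 1) + 1


def generator(root: int, *tags: object) -> np.random.Generator:
    """A numpy Generator on the derived stream."""
    return np.random.default_rng(derive_seed(root, *tags))
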
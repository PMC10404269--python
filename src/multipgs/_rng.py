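"""Deterministic seed derivation.

One master seed per run; every stochastic operation derives a child seed from
(master, operation tag) so that results are reproducible and independent of
execution order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "rng_for"]


def child_seed(master: int, tag: str) -> int:
    """Derive a 31-bit child seed from a master seed and an operation tag."""
    if master < 0:
        raise ValueError("master seed must be non-negative")
    h = zlib.crc32(f"{master}:{tag}".encode())
    return int(h & 0x7FFFFFFF)


def rng_for(master: int, tag: str) -> np.random.Generator:
    """A PCG64 generator keyed by (master seed, operation tag)."""
    return np.random.default_rng(child_seed(master, tag))
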
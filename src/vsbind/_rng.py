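"""Deterministic child-seed derivation.

One global seed drives a whole pipeline; every stochastic operation derives a
child seed from ``(global seed, purpose string, index)``.  The purpose string
is hashed with CRC-32 (stable across platforms and Python processes, unlike
builtin ``hash``) and folded into a :class:`numpy.random.SeedSequence`.
"""
from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def child_seed(seed: int, purpose: str, index: int = 0) -> int:
    """Derive a reproducible 31-bit child seed from (seed, purpose, index)."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(purpose.encode("utf-8")), int(index)])
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


def child_rng(seed: int, purpose: str, index: int = 0) -> np.random.Generator:
    """A Generator seeded by :func:`child_seed`."""
    return np.random.default_rng(child_seed(seed, purpose, index))
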
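"""Boundary-relative positional tags and composite query keys.

Ordinal position is marked by binding an item to a *positional tag* drawn
from a small deterministic family: the k-th tag is the k-th convolutional
power of a unitary base vector (2deg = 1deg (x) 1deg = (1deg)^2, and so on).
Because the base is unitary every tag is unitary, so every tag has an exact
inverse and hierarchical queries are lossless up to superposition noise.

Each hierarchy level ("item", "chunk", "superchunk", ...) gets its own
independent base, giving near-orthogonal tag families across levels.  Tags
depend only on order *within* a chunk, never on absolute sequence position.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product
from typing import Sequence

import numpy as np

from ._rng import child_seed
from .exceptions import CapacityError, DimensionError, KeyStateError, ParameterError
from .hrr_core import bind, inverse, random_vector, similarity

__all__ = ["TagSet", "QueryKey", "make_tagset", "compose_key", "invert_key", "all_keys"]

#: construction-time screen on pairwise tag similarity
ORTHO_THRESHOLD = 0.2
MAX_BASE_RETRIES = 10


@dataclass(frozen=True)
class TagSet:
    """Positional tags 1deg..Kdeg for one hierarchy level.

    ``tags[k-1]`` is the k-th convolutional power of ``base`` (orders are
    1-based, following primary/secondary nomenclature; storage is 0-based).
    """

    level: str
    base: np.ndarray
    tags: tuple[np.ndarray, ...]
    dim: int
    max_order: int
    seed: int

    def tag(self, order: int) -> np.ndarray:
        """The tag for 1-based ordinal ``order``."""
        if not (1 <= order <= self.max_order):
            raise ParameterError(
                f"order {order} out of range 1..{self.max_order} for level {self.level!r}"
            )
        return self.tags[order - 1]


@dataclass(frozen=True)
class QueryKey:
    """A (possibly composite) retrieval key: the bind-product of named tags.

    ``inverted`` records whether the involution has been applied; only
    inverted keys may be used for retrieval.
    """

    level_orders: tuple[tuple[str, int], ...]
    vector: np.ndarray
    inverted: bool = False


def make_tagset(level: str, dim: int, max_order: int, seed: int) -> TagSet:
    """Deterministically build the tag family for one hierarchy level.

    The base is a seeded unitary vector; distinct tags must satisfy
    |cosine| < 0.2 pairwise, otherwise the base is regenerated with the
    next child seed (up to 10 attempts, then a capacity error advises a
    larger dim).  Identical inputs reproduce bit-identical tags.
    """
    if max_order < 1:
        raise ParameterError(f"max_order must be >= 1, got {max_order}")
    if dim < 2:
        raise DimensionError(f"dim must be >= 2, got {dim}")
    for attempt in range(MAX_BASE_RETRIES):
        base = random_vector(dim, child_seed(seed, f"tagset:{level}", attempt), mode="unitary")
        tags = [base]
        for _ in range(1, max_order):
            tags.append(bind(tags[-1], base))
        ok = all(
            abs(similarity(tags[i], tags[j])) < ORTHO_THRESHOLD
            for i in range(max_order)
            for j in range(i + 1, max_order)
        )
        if ok:
            return TagSet(
                level=level,
                base=base,
                tags=tuple(tags),
                dim=dim,
                max_order=max_order,
                seed=seed,
            )
    raise CapacityError(
        f"could not find {max_order} quasi-orthogonal tags at dim={dim} for "
        f"level {level!r} after {MAX_BASE_RETRIES} base regenerations; "
        "increase dim"
    )


def _level_map(tagsets: Sequence[TagSet]) -> dict[str, TagSet]:
    m: dict[str, TagSet] = {}
    for ts in tagsets:
        if ts.level in m:
            raise KeyStateError(f"duplicate tagset level {ts.level!r}")
        m[ts.level] = ts
    return m


def compose_key(tagsets: Sequence[TagSet], orders: Sequence[tuple[str, int]]) -> QueryKey:
    """Bind-product of the named tags, e.g. [("item", 2), ("chunk", 1)].

    Binding commutes, so the product order is immaterial; the key is
    returned un-inverted (apply :func:`invert_key` before retrieval).
    """
    levels = _level_map(tagsets)
    if len(orders) == 0:
        raise KeyStateError("compose_key needs at least one (level, order) pair")
    vec = None
    canonical = []
    for level, order in orders:
        if level not in levels:
            raise KeyStateError(f"unknown level {level!r}; have {sorted(levels)}")
        tag = levels[level].tag(order)  # validates the order range
        canonical.append((level, order))
        vec = tag.copy() if vec is None else bind(vec, tag)
    return QueryKey(level_orders=tuple(canonical), vector=vec, inverted=False)


def invert_key(key: QueryKey) -> QueryKey:
    """Apply the involution to the key vector (exact, since tags are unitary)."""
    if key.inverted:
        raise KeyStateError("key is already inverted")
    return replace(key, vector=inverse(key.vector), inverted=True)


def all_keys(tagsets: Sequence[TagSet]) -> list[QueryKey]:
    """Every composite key over the given levels, each already inverted.

    Tagsets are listed fine-to-coarse (item first, chunk last); enumeration
    varies the coarsest level slowest, i.e. chunk-major / item-minor:
    (1_C,1_I), (1_C,2_I), (2_C,1_I), (2_C,2_I) for two 2-deep levels.
    Iterating these keys over a structure trace retrieves every stored
    constituent in sequence.
    """
    if len(tagsets) == 0:
        raise KeyStateError("all_keys needs at least one tagset")
    ranges = [range(1, ts.max_order + 1) for ts in reversed(tagsets)]
    keys = []
    for combo in product(*ranges):  # coarse..fine
        orders = [
            (ts.level, o) for ts, o in zip(tagsets, reversed(combo))
        ]  # back to fine..coarse
        keys.append(invert_key(compose_key(tagsets, orders)))
    return keys
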
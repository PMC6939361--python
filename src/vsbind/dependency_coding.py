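"""Dependency recoding: salience filtering, chunks, and hierarchical structure.

A *chunk* packages a handful of (possibly non-adjacent) items as an
unweighted superposition of item-tag (x) item bindings.  Salience
filtering first drops irrelevant intervening items and re-indexes the
survivors from 1, so a non-adjacent dependency A-X^n-B encodes to exactly
the same vector as the adjacent pair A-B.

Chunks are themselves bound to chunk-level tags and superposed into a
*superchunk* (a StructureTrace), which represents nested or crossed
dependencies at the atoms' dimensionality.  Constituents are recovered
with composite keys: not-1_C retrieves the whole first chunk, not-2_I the
second item of every chunk, not-(2_I (x) 1_C) one specific slot.

Repeated superposition of structure traces over exposures yields a
grammar memory trace; cosine similarity to it serves as a familiarity
(grammaticality) score.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import (
    CapacityError,
    DimensionError,
    EmptyDependencyError,
    KeyStateError,
    ParameterError,
    StructureSpecError,
    VocabularyError,
)
from .hrr_core import CleanupResult, Vocabulary, bind, cleanup, similarity, superpose, unbind
from .positional_tags import QueryKey, TagSet, all_keys

__all__ = [
    "SalienceMask",
    "StructureSpec",
    "StructureTrace",
    "filter_salient",
    "encode_chunk",
    "encode_structure",
    "query_structure",
    "unpack_structure",
    "accumulate_grammar_trace",
    "familiarity",
]

STRUCTURE_KINDS = ("adjacent", "nonadjacent", "nested", "crossed", "custom")


@dataclass(frozen=True)
class SalienceMask:
    """Which elements survive filtering, by serial position and/or token name.

    An element passes if its 1-based position is in ``positions`` (when
    given) or its name is in ``tokens`` (when given).  At least one
    criterion must be supplied.
    """

    positions: frozenset[int] | None = None
    tokens: frozenset[str] | None = None

    def __post_init__(self):
        if self.positions is None and self.tokens is None:
            raise ParameterError("SalienceMask needs positions and/or tokens")
        if self.positions is not None:
            object.__setattr__(self, "positions", frozenset(self.positions))
        if self.tokens is not None:
            object.__setattr__(self, "tokens", frozenset(self.tokens))

    def is_salient(self, name: str, position: int) -> bool:
        if self.positions is not None and position in self.positions:
            return True
        if self.tokens is not None and name in self.tokens:
            return True
        return False


def _intervals(chunks) -> list[tuple[int, int]]:
    return [(min(c), max(c)) for c in chunks]


def _properly_nested(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """Disjoint, or one span strictly inside the other."""
    if a[1] < b[0] or b[1] < a[0]:
        return True
    return (a[0] < b[0] and b[1] < a[1]) or (b[0] < a[0] and a[1] < b[1])


def _interleaved(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[0] < a[1] < b[1] or b[0] < a[0] < b[1] < a[1]


@dataclass(frozen=True)
class StructureSpec:
    """Declarative chunk layout over 1-based serial positions of a source sequence."""

    chunks: tuple[tuple[int, ...], ...]
    kind: str = "custom"

    def __post_init__(self):
        if self.kind not in STRUCTURE_KINDS:
            raise StructureSpecError(f"kind must be one of {STRUCTURE_KINDS}, got {self.kind!r}")
        chunks = tuple(tuple(int(p) for p in c) for c in self.chunks)
        object.__setattr__(self, "chunks", chunks)
        if len(chunks) == 0:
            raise StructureSpecError("spec needs at least one chunk")
        seen: set[int] = set()
        for c in chunks:
            if len(c) == 0:
                raise StructureSpecError("empty chunk")
            if any(p < 1 for p in c):
                raise StructureSpecError(f"positions are 1-based, got {c}")
            if any(b <= a for a, b in zip(c, c[1:])):
                raise StructureSpecError(f"chunk positions must strictly increase: {c}")
            if seen & set(c):
                raise StructureSpecError(f"position reused across chunks: {c}")
            seen |= set(c)
        spans = _intervals(chunks)
        if self.kind == "nested":
            for i in range(len(spans)):
                for j in range(i + 1, len(spans)):
                    if not _properly_nested(spans[i], spans[j]):
                        raise StructureSpecError(
                            f"chunk spans {spans[i]} and {spans[j]} are not nested/disjoint"
                        )
        elif self.kind == "crossed":
            if len(spans) > 1 and not any(
                _interleaved(spans[i], spans[j])
                for i in range(len(spans))
                for j in range(i + 1, len(spans))
            ):
                raise StructureSpecError("crossed spec requires at least two interleaved spans")

    @property
    def n_chunks(self) -> int:
        return len(self.chunks)

    @property
    def max_positions(self) -> int:
        return max(max(c) for c in self.chunks)

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind, "chunks": [list(c) for c in self.chunks]})

    @classmethod
    def from_json(cls, s: str) -> "StructureSpec":
        d = json.loads(s)
        return cls(chunks=tuple(tuple(c) for c in d["chunks"]), kind=d.get("kind", "custom"))


@dataclass(frozen=True)
class StructureTrace:
    """Encoded superchunk: Sum_c chunk_tag_c (x) (Sum_i item_tag_i (x) item_ci)."""

    vector: np.ndarray
    spec: StructureSpec
    item_tags: TagSet
    chunk_tags: TagSet
    dim: int
    levels: int = 2
    log: tuple[str, ...] | None = None


def filter_salient(tokens: Sequence[str], mask: SalienceMask) -> list[str]:
    """Keep salient tokens in order; survivors are re-indexed from 1, making
    the downstream code boundary-relative (A-X^n-B collapses to A-B)."""
    tokens = list(tokens)
    if len(tokens) == 0:
        raise ParameterError("filter_salient requires a non-empty token list")
    kept = [t for i, t in enumerate(tokens, start=1) if mask.is_salient(t, i)]
    if len(kept) == 0:
        raise EmptyDependencyError("salience mask removed every token")
    return kept


def encode_chunk(tokens: Sequence[str], vocab: Vocabulary, item_tags: TagSet) -> np.ndarray:
    """Unweighted Sum_k item_tag_k (x) item_k.  The dependency buffer holds its
    constituents saliently, so no decay weighting is applied here (and the
    non-adjacent == adjacent identity is exact)."""
    tokens = list(tokens)
    if not (1 <= len(tokens) <= item_tags.max_order):
        raise CapacityError(
            f"chunk length {len(tokens)} outside 1..{item_tags.max_order}"
        )
    for t in tokens:
        if t not in vocab:
            raise VocabularyError(f"unknown token {t!r}")
    if vocab.dim != item_tags.dim:
        raise DimensionError(f"vocabulary dim {vocab.dim} != tag dim {item_tags.dim}")
    return superpose([bind(item_tags.tag(k), vocab[t]) for k, t in enumerate(tokens, start=1)])


def encode_structure(
    tokens: Sequence[str],
    spec: StructureSpec,
    vocab: Vocabulary,
    item_tags: TagSet,
    chunk_tags: TagSet,
) -> StructureTrace:
    """Encode a hierarchical (nested or crossed — only the spec differs)
    structure as a superchunk of chunk-tag (x) chunk bindings."""
    tokens = list(tokens)
    if spec.max_positions > len(tokens):
        raise StructureSpecError(
            f"spec references position {spec.max_positions} but only {len(tokens)} tokens given"
        )
    if spec.n_chunks > chunk_tags.max_order:
        raise CapacityError(
            f"{spec.n_chunks} chunks exceed chunk tag max_order {chunk_tags.max_order}"
        )
    if item_tags.dim != chunk_tags.dim:
        raise DimensionError("item and chunk tag families have different dims")
    parts = []
    for c_order, positions in enumerate(spec.chunks, start=1):
        chunk_vec = encode_chunk([tokens[p - 1] for p in positions], vocab, item_tags)
        parts.append(bind(chunk_tags.tag(c_order), chunk_vec))
    return StructureTrace(
        vector=superpose(parts),
        spec=spec,
        item_tags=item_tags,
        chunk_tags=chunk_tags,
        dim=item_tags.dim,
        log=tuple(tokens),
    )


def query_structure(
    trace: StructureTrace,
    key: QueryKey,
    vocab: Vocabulary,
    threshold: float = 0.1,
) -> list[tuple[tuple[tuple[str, int], ...], CleanupResult | None]]:
    """Retrieve constituents addressed by an (inverted) composite key.

    A fully specified key (item and chunk order) yields one slot.  A
    partially specified key unbinds once, then iterates the unspecified
    level's tags, cleaning up each slot — not-1_C walks the first chunk's
    items, not-2_I walks the second item of every chunk.  Returns
    ``(slot address, cleanup result-or-None)`` pairs in tag order.
    """
    if not key.inverted:
        raise KeyStateError("query keys must be inverted before retrieval")
    by_level = {trace.item_tags.level: trace.item_tags, trace.chunk_tags.level: trace.chunk_tags}
    key_levels = [lv for lv, _ in key.level_orders]
    if len(set(key_levels)) != len(key_levels) or not set(key_levels) <= set(by_level):
        raise KeyStateError(
            f"key levels {key_levels} do not address trace levels {sorted(by_level)}"
        )
    if key.vector.shape[0] != trace.dim:
        raise DimensionError("key dim does not match trace dim")
    released = bind(trace.vector, key.vector)  # key already inverted
    remaining = [lv for lv in (trace.chunk_tags.level, trace.item_tags.level) if lv not in key_levels]
    if not remaining:
        return [(key.level_orders, cleanup(released, vocab, threshold))]
    out = []
    # iterate the one unspecified level (two-level traces)
    (level,) = remaining
    ts = by_level[level]
    for order in range(1, ts.max_order + 1):
        address = tuple(sorted(key.level_orders + ((level, order),)))
        out.append((address, cleanup(unbind(released, ts.tag(order)), vocab, threshold)))
    return out


def unpack_structure(
    trace: StructureTrace,
    vocab: Vocabulary,
    threshold: float = 0.1,
) -> tuple[list[tuple[int, int, str]], int]:
    """Full decode by iterating every composite key (chunk-major).

    Returns ``(triples, n_no_match)`` where each triple is
    (chunk order, item order, token name); no-match slots are omitted and
    counted.
    """
    keys = all_keys([trace.item_tags, trace.chunk_tags])
    triples = []
    n_missing = 0
    for key in keys:
        released = bind(trace.vector, key.vector)
        r = cleanup(released, vocab, threshold)
        orders = dict(key.level_orders)
        if r is None:
            n_missing += 1
        else:
            triples.append(
                (orders[trace.chunk_tags.level], orders[trace.item_tags.level], r.name)
            )
    return triples, n_missing


def accumulate_grammar_trace(
    traces: Sequence[StructureTrace | np.ndarray],
    weights: Sequence[float] | None = None,
) -> np.ndarray:
    """Weighted superposition of structure traces — the slowly built grammar
    memory trace (weights emulate rehearsal).  Familiarity of a new trace is
    its cosine to this accumulation."""
    if len(traces) == 0:
        raise ParameterError("accumulate_grammar_trace requires at least one trace")
    vecs = [t.vector if isinstance(t, StructureTrace) else np.asarray(t, float) for t in traces]
    if weights is None:
        weights = [1.0] * len(vecs)
    if len(weights) != len(vecs):
        raise ParameterError(f"{len(weights)} weights for {len(vecs)} traces")
    if any(w < 0 for w in weights):
        raise ParameterError("weights must be non-negative")
    d = vecs[0].shape[0]
    out = np.zeros(d)
    for w, v in zip(weights, vecs):
        if v.shape[0] != d:
            raise DimensionError("traces have mismatched dims")
        out += w * v
    return out


def familiarity(probe: StructureTrace | np.ndarray, memory: np.ndarray) -> float:
    """Cosine similarity of a probe trace to the accumulated grammar trace."""
    v = probe.vector if isinstance(probe, StructureTrace) else np.asarray(probe, float)
    return similarity(v, memory, metric="cosine")
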
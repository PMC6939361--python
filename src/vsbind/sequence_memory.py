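"""Decaying serial-order working-memory buffer.

A token sequence is stored as a superposition of position-tag (x) item
bindings::

    Sequence = w_1 * (1deg (x) Item1) + w_2 * (2deg (x) Item2) + ...

with two-component weights ``w_i = gamma^(L-i) + rho^(i-1)``: a recency
component (each stored binding decays by ``gamma`` per subsequent item,
as in a leaky recurrent buffer) and a primacy component (early items enter
with a rehearsal-like boost decaying by ``rho``).  With ``gamma < 1`` and
``rho > 0`` serial recall shows the classic U-shaped serial-position curve.
``rho = 0`` means *no* primacy component at all (so ``gamma=1, rho=0``
gives the plain unweighted superposition).

Retrieval unbinds with a positional tag and resolves the noisy result
against the vocabulary's cleanup memory (Item ~= Sequence (x) not-Position).
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .exceptions import CapacityError, DimensionError, ParameterError, VocabularyError
from .hrr_core import CleanupResult, Vocabulary, bind, cleanup, unbind
from .positional_tags import TagSet

__all__ = [
    "SequenceTrace",
    "BLANK_TOKEN",
    "encode_sequence",
    "append_token",
    "recall_item",
    "serial_recall",
    "sequence_weights",
    "DEFAULT_GAMMA",
    "DEFAULT_RHO",
]

#: stands in for a no-match slot during serial recall, keeping output length L
BLANK_TOKEN = "∅"

# calibrated to give a U-shaped serial-position curve at list length 7
DEFAULT_GAMMA = 0.82
DEFAULT_RHO = 0.35


def sequence_weights(length: int, gamma: float, rho: float) -> np.ndarray:
    """w_i = gamma^(L-i) + rho^(i-1) for i = 1..L (primacy term absent if rho == 0)."""
    i = np.arange(1, length + 1, dtype=float)
    w = gamma ** (length - i)
    if rho > 0.0:
        w = w + rho ** (i - 1.0)
    return w


def _check_params(gamma: float, rho: float) -> None:
    if not (0.0 < gamma <= 1.0):
        raise ParameterError(f"gamma must be in (0, 1], got {gamma}")
    if not (0.0 <= rho < 1.0):
        raise ParameterError(f"rho must be in [0, 1), got {rho}")


@dataclass(frozen=True)
class SequenceTrace:
    """Encoded serial-order buffer state.

    ``vector`` is the decodable superposition.  The recency- and
    primacy-weighted parts are kept separately so that appending a token
    re-scales previous contributions exactly as a decaying recurrent
    buffer would.  ``log`` is debugging metadata only and is never read
    by any decoding path.
    """

    vector: np.ndarray
    length: int
    level: str
    dim: int
    gamma: float
    rho: float
    recency_part: np.ndarray
    primacy_part: np.ndarray
    log: tuple[str, ...] | None = None


def encode_sequence(
    tokens: Sequence[str],
    vocab: Vocabulary,
    tags: TagSet,
    gamma: float = DEFAULT_GAMMA,
    rho: float = DEFAULT_RHO,
    keep_log: bool = True,
) -> SequenceTrace:
    """Encode a token list into a decaying position (x) item superposition."""
    _check_params(gamma, rho)
    tokens = list(tokens)
    if len(tokens) > tags.max_order:
        raise CapacityError(
            f"sequence length {len(tokens)} exceeds tag family max_order {tags.max_order}"
        )
    if vocab.dim != tags.dim:
        raise DimensionError(f"vocabulary dim {vocab.dim} != tag dim {tags.dim}")
    for t in tokens:
        if t not in vocab:
            raise VocabularyError(f"unknown token {t!r}")
    L = len(tokens)
    recency = np.zeros(tags.dim)
    primacy = np.zeros(tags.dim)
    for i, t in enumerate(tokens, start=1):
        b = bind(tags.tag(i), vocab[t])
        recency += (gamma ** (L - i)) * b
        if rho > 0.0:
            primacy += rho ** (i - 1.0) * b
    return SequenceTrace(
        vector=recency + primacy,
        length=L,
        level=tags.level,
        dim=tags.dim,
        gamma=gamma,
        rho=rho,
        recency_part=recency,
        primacy_part=primacy,
        log=tuple(tokens) if keep_log else None,
    )


def append_token(
    trace: SequenceTrace, token: str, vocab: Vocabulary, tags: TagSet
) -> SequenceTrace:
    """Incremental encoding: decay the stored recency part by gamma, then add
    the new binding.  Equivalent to re-encoding the full list from scratch."""
    if trace.length + 1 > tags.max_order:
        raise CapacityError(f"buffer full at max_order {tags.max_order}")
    if token not in vocab:
        raise VocabularyError(f"unknown token {token!r}")
    L = trace.length + 1
    b = bind(tags.tag(L), vocab[token])
    recency = trace.gamma * trace.recency_part + b
    primacy = trace.primacy_part
    if trace.rho > 0.0:
        primacy = primacy + trace.rho ** (L - 1.0) * b
    return replace(
        trace,
        vector=recency + primacy,
        length=L,
        recency_part=recency,
        primacy_part=primacy,
        log=(trace.log + (token,)) if trace.log is not None else None,
    )


def recall_item(
    trace: SequenceTrace,
    order: int,
    vocab: Vocabulary,
    tags: TagSet,
    threshold: float = 0.1,
) -> CleanupResult | None:
    """Retrieve the item at a 1-based ordinal position via positional unbinding."""
    if not (1 <= order <= trace.length):
        raise ParameterError(f"order {order} out of range 1..{trace.length}")
    if tags.level != trace.level or tags.dim != trace.dim:
        raise DimensionError(
            f"tag family ({tags.level!r}, dim {tags.dim}) does not match the trace "
            f"({trace.level!r}, dim {trace.dim})"
        )
    return cleanup(unbind(trace.vector, tags.tag(order)), vocab, threshold)


def serial_recall(
    trace: SequenceTrace,
    vocab: Vocabulary,
    tags: TagSet,
    threshold: float = 0.1,
    blank: str = BLANK_TOKEN,
) -> list[str]:
    """Recall positions 1..L in order; no-match slots become the blank token."""
    out = []
    for order in range(1, trace.length + 1):
        r = recall_item(trace, order, vocab, tags, threshold)
        out.append(r.name if r is not None else blank)
    return out
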
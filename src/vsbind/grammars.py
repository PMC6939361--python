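"""Synthetic artificial-grammar generators.

Emulates the classic sequence-learning paradigms: adjacent pairs (AB),
non-adjacent dependencies (A-X^n-B with irrelevant intervening fillers),
and hierarchical nested (A1 A2 B2 B1) and crossed (A1 A2 B1 B2) pair
structures.  Sequences come with the chunk layout that a downstream
parser is assumed to have identified, plus a grammaticality flag.

Ungrammatical adjacent/axb items violate the dependency either by
reversing the pair order (B before A — the default, and the violation a
position-tagged chunk code genuinely detects) or by pairing A with a
mismatched B family.  Family mismatches are indistinguishable *in
expectation* to a superposed grammar memory trace, because items bind
only to positional tags and the trace is therefore linear in
per-position item counts; that at-chance behaviour is itself a model
property worth probing.  All generation is bit-reproducible under
(spec, seed).
"""
from __future__ import annotations

from dataclasses import dataclass

from ._rng import child_rng
from .dependency_coding import StructureSpec
from .exceptions import ParameterError

__all__ = ["GrammarSpec", "gen_grammar_sequences", "grammar_vocabulary_names"]

GRAMMAR_KINDS = ("adjacent", "axb", "nested", "crossed")
VIOLATIONS = ("reversed", "mismatch")


@dataclass(frozen=True)
class GrammarSpec:
    """Parameters of one artificial grammar.

    ``vocab_size`` counts all token names (paired families plus fillers for
    adjacent/axb grammars); ``n_intervening`` is the number of irrelevant X
    fillers in A-X^n-B; ``n_pairs`` the depth of nested/crossed structures.
    """

    kind: str
    vocab_size: int = 16
    n_intervening: int = 2
    n_pairs: int = 2
    seed: int = 0
    violation: str = "reversed"

    def __post_init__(self):
        if self.kind not in GRAMMAR_KINDS:
            raise ParameterError(f"kind must be one of {GRAMMAR_KINDS}, got {self.kind!r}")
        if self.violation not in VIOLATIONS:
            raise ParameterError(f"violation must be one of {VIOLATIONS}, got {self.violation!r}")
        if self.vocab_size < 1 or self.n_pairs < 1 or self.n_intervening < 0:
            raise ParameterError("grammar parameters must be positive (n_intervening >= 0)")

    @property
    def n_families(self) -> int:
        """Number of matched A_i/B_i families for adjacent/axb grammars."""
        if self.kind in ("nested", "crossed"):
            return self.n_pairs
        n = max(2, self.vocab_size // 4)
        if 2 * n >= self.vocab_size and self.kind == "axb":
            raise ParameterError(
                f"vocab_size {self.vocab_size} too small for {n} A/B families plus X fillers"
            )
        return n


def grammar_vocabulary_names(spec: GrammarSpec) -> list[str]:
    """All token names the grammar can emit (build the Vocabulary from these)."""
    if spec.kind in ("nested", "crossed"):
        k = spec.n_pairs
        return [f"A{i}" for i in range(1, k + 1)] + [f"B{i}" for i in range(1, k + 1)]
    m = spec.n_families
    names = [f"A{i}" for i in range(1, m + 1)] + [f"B{i}" for i in range(1, m + 1)]
    n_fill = spec.vocab_size - 2 * m
    names += [f"X{i}" for i in range(1, n_fill + 1)]
    return names


def gen_grammar_sequences(
    spec: GrammarSpec, n: int
) -> list[tuple[list[str], StructureSpec, bool]]:
    """Generate ``n`` (tokens, chunk layout, grammatical) triples.

    adjacent/axb items alternate grammatical and violating (even indices
    grammatical); the violation is reversed pair order or a mismatched B
    family, per ``spec.violation``.  nested/crossed layouts are always
    well-formed, differing only in their chunk spans.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    rng = child_rng(spec.seed, f"grammar:{spec.kind}")
    out: list[tuple[list[str], StructureSpec, bool]] = []
    if spec.kind in ("nested", "crossed"):
        k = spec.n_pairs
        if spec.kind == "nested":
            tokens = [f"A{i}" for i in range(1, k + 1)] + [f"B{i}" for i in range(k, 0, -1)]
            chunks = tuple((i, 2 * k + 1 - i) for i in range(1, k + 1))
        else:
            tokens = [f"A{i}" for i in range(1, k + 1)] + [f"B{i}" for i in range(1, k + 1)]
            chunks = tuple((i, k + i) for i in range(1, k + 1))
        layout = StructureSpec(chunks=chunks, kind=spec.kind)
        return [(list(tokens), layout, True)] * n

    m = spec.n_families
    n_fill = spec.vocab_size - 2 * m if spec.kind == "axb" else 0
    for i in range(n):
        grammatical = i % 2 == 0
        fam = int(rng.integers(1, m + 1))
        b_fam = fam
        if not grammatical and spec.violation == "mismatch":
            b_fam = int(rng.integers(1, m))
            if b_fam >= fam:
                b_fam += 1  # uniform over families != fam
        first, last = f"A{fam}", f"B{b_fam}"
        if not grammatical and spec.violation == "reversed":
            first, last = last, first
        fillers = [f"X{int(rng.integers(1, n_fill + 1))}" for _ in range(spec.n_intervening)] if n_fill else []
        if spec.kind == "adjacent" or spec.n_intervening == 0:
            tokens = [first, last]
            layout = StructureSpec(chunks=((1, 2),), kind="adjacent")
        else:
            tokens = [first] + fillers + [last]
            layout = StructureSpec(
                chunks=((1, len(tokens)),), kind="nonadjacent"
            )
        out.append((tokens, layout, grammatical))
    return out
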
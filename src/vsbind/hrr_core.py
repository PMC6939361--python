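"""Holographic reduced representation (HRR) algebra.

The basic currency is a length-``d`` real vector (a plain ``numpy.ndarray``
of float64).  Symbols are random high-dimensional vectors; composite
structures are built from two operators:

* **superposition** — element-wise addition; the result stays correlated
  with each constituent.
* **binding** — circular convolution; the result is approximately
  orthogonal to both constituents but retains a *reduced representation*
  of the pair at the same dimensionality, recoverable by **unbinding**
  with the (approximate) inverse of one operand.

The approximate inverse is the involution that fixes entry 0 and reverses
the remaining entries; it is exact for *unitary* vectors (all Fourier
magnitudes equal to one).  Noisy unbinding results are resolved against a
:class:`Vocabulary` with a nearest-neighbour :func:`cleanup` memory.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from ._rng import child_rng
from .exceptions import DimensionError, ParameterError, VocabularyError

__all__ = [
    "CleanupResult",
    "Vocabulary",
    "bind",
    "cleanup",
    "identity_vector",
    "inverse",
    "normalize",
    "random_vector",
    "similarity",
    "superpose",
    "unbind",
]

MODES = ("gaussian", "sparse", "unitary")


def _check_vector(a: np.ndarray, name: str = "vector") -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    if a.ndim != 1 or a.shape[0] < 2:
        raise DimensionError(f"{name} must be 1-D with dim >= 2, got shape {a.shape}")
    return a


def _check_same_dim(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape[0] != b.shape[0]:
        raise DimensionError(f"operands have mismatched dims {a.shape[0]} != {b.shape[0]}")


def identity_vector(dim: int) -> np.ndarray:
    """The convolutive identity e0 = (1, 0, ..., 0): bind(e0, x) == x."""
    if dim < 2:
        raise DimensionError(f"dim must be >= 2, got {dim}")
    e = np.zeros(dim)
    e[0] = 1.0
    return e


def normalize(v: np.ndarray) -> np.ndarray:
    """Scale to unit Euclidean norm; zero vectors raise."""
    v = _check_vector(v)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ParameterError("cannot normalize the zero vector")
    return v / n


def random_vector(
    dim: int,
    seed: int,
    mode: str = "gaussian",
    sparsity: float = 0.05,
) -> np.ndarray:
    """Generate a seeded unit-norm symbol vector.

    Parameters
    ----------
    dim : int
        Dimensionality (>= 2).
    seed : int
        Seed for the generator; identical arguments give bit-identical output.
    mode : {"gaussian", "sparse", "unitary"}
        gaussian — i.i.d. N(0, 1/d) entries, then normalized.
        sparse — exactly ``round(sparsity * dim)`` nonzero entries at seeded
        random indices, values i.i.d. normal, then normalized.
        unitary — all Fourier magnitudes 1 with seeded random phases
        (conjugate-symmetric, so the vector is real); exactly invertible
        under the involution, which makes these the tag/key material.
    sparsity : float
        Fraction of nonzero entries in sparse mode, in (0, 1].
    """
    if dim < 2:
        raise DimensionError(f"dim must be >= 2, got {dim}")
    if mode not in MODES:
        raise ParameterError(f"mode must be one of {MODES}, got {mode!r}")
    if not (0.0 < sparsity <= 1.0):
        raise ParameterError(f"sparsity must be in (0, 1], got {sparsity}")
    rng = np.random.default_rng(seed)
    if mode == "gaussian":
        v = rng.normal(0.0, 1.0 / np.sqrt(dim), size=dim)
        return v / np.linalg.norm(v)
    if mode == "sparse":
        k = max(1, int(round(sparsity * dim)))
        idx = rng.choice(dim, size=k, replace=False)
        v = np.zeros(dim)
        v[idx] = rng.normal(size=k)
        return v / np.linalg.norm(v)
    # unitary: unit-magnitude spectrum, random phases on the free bins.
    n_rfft = dim // 2 + 1
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_rfft)
    spec = np.exp(1j * phases)
    spec[0] = 1.0          # DC bin must be real
    if dim % 2 == 0:
        spec[-1] = 1.0     # Nyquist bin must be real
    return np.fft.irfft(spec, n=dim)


def superpose(vs: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise sum of the inputs (bundling).  Deliberately NOT renormalized:
    the growing norm of an accumulating buffer is itself a model signature."""
    if len(vs) == 0:
        raise ParameterError("superpose requires a non-empty list")
    out = _check_vector(vs[0]).copy()
    for v in vs[1:]:
        v = _check_vector(v)
        _check_same_dim(out, v)
        out += v
    return out


def bind(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Circular convolution c[k] = sum_j a[j] * b[(k - j) mod d].

    Computed via the FFT identity; matches the direct O(d^2) sum to 1e-9.
    Output keeps the operands' dimensionality (a reduced representation).
    """
    a = _check_vector(a, "a")
    b = _check_vector(b, "b")
    _check_same_dim(a, b)
    d = a.shape[0]
    return np.fft.irfft(np.fft.rfft(a) * np.fft.rfft(b), n=d)


def inverse(a: np.ndarray) -> np.ndarray:
    """Approximate inverse (involution): fix entry 0, reverse entries 1..d-1.

    Exact inverse for unitary vectors; applying it twice is the identity.
    """
    a = _check_vector(a)
    return np.concatenate((a[:1], a[:0:-1]))


def unbind(trace: np.ndarray, key: np.ndarray) -> np.ndarray:
    """Release the constituent bound to ``key``: bind(trace, inverse(key))."""
    return bind(trace, inverse(key))


def similarity(a: np.ndarray, b: np.ndarray, metric: str = "cosine") -> float:
    """Vector comparison: ``dot`` (raw inner product) or ``cosine`` in [-1, 1]."""
    a = _check_vector(a, "a")
    b = _check_vector(b, "b")
    _check_same_dim(a, b)
    dot = float(a @ b)
    if metric == "dot":
        return dot
    if metric == "cosine":
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0.0 or nb == 0.0:
            raise ParameterError("cosine similarity undefined for zero-norm input")
        return float(np.clip(dot / (na * nb), -1.0, 1.0))
    raise ParameterError(f"metric must be 'dot' or 'cosine', got {metric!r}")


class CleanupResult(NamedTuple):
    """Outcome of a cleanup-memory lookup (best match and its margin)."""

    name: str
    score: float
    runner_up_score: float


@dataclass(frozen=True)
class Vocabulary:
    """Named atomic symbol vectors plus nearest-neighbour cleanup support.

    Regenerating with the same ``(seed, dim, mode, names in order)`` is
    bit-reproducible.  Vectors are stored row-wise in ``vectors`` in the
    order of ``names``; all rows have unit norm.
    """

    names: tuple[str, ...]
    vectors: np.ndarray  # shape (n, dim), float64, unit rows
    dim: int
    seed: int
    mode: str = "gaussian"
    sparsity: float = 0.05
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.names)})

    @classmethod
    def create(
        cls,
        names: Iterable[str],
        dim: int,
        seed: int,
        mode: str = "gaussian",
        sparsity: float = 0.05,
    ) -> "Vocabulary":
        names = tuple(names)
        if len(names) == 0:
            raise VocabularyError("vocabulary needs at least one name")
        if len(set(names)) != len(names) or any(not n for n in names):
            raise VocabularyError("vocabulary names must be unique and non-empty")
        vectors = np.empty((len(names), dim))
        for i in range(len(names)):
            child = child_rng(seed, "vocabulary", i)
            vectors[i] = random_vector(dim, int(child.integers(2**31)), mode, sparsity)
        return cls(names=names, vectors=vectors, dim=dim, seed=seed, mode=mode, sparsity=sparsity)

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.vectors[self._index[name]]
        except KeyError:
            raise VocabularyError(f"unknown token {name!r}") from None

    def items(self):
        for i, n in enumerate(self.names):
            yield n, self.vectors[i]

    def meta(self) -> dict:
        """JSON-serializable generation metadata (no vector payload)."""
        return {
            "names": list(self.names),
            "dim": self.dim,
            "seed": self.seed,
            "mode": self.mode,
            "sparsity": self.sparsity,
        }

    def meta_json(self) -> str:
        return json.dumps(self.meta())


def cleanup(v: np.ndarray, vocab: Vocabulary, threshold: float = 0.1) -> CleanupResult | None:
    """Nearest-neighbour autoassociative lookup by cosine similarity.

    Returns the best-matching name with its score and the runner-up score,
    or ``None`` (no-match) if the best score falls below ``threshold`` or
    the query has zero norm.  Exact ties resolve to the lexicographically
    smaller name; the tie shows up as runner_up_score == score.
    """
    if len(vocab) == 0:
        raise VocabularyError("cleanup against an empty vocabulary")
    v = _check_vector(v)
    if v.shape[0] != vocab.dim:
        raise DimensionError(f"query dim {v.shape[0]} != vocabulary dim {vocab.dim}")
    nv = np.linalg.norm(v)
    if nv == 0.0:
        return None
    scores = (vocab.vectors @ v) / nv  # rows are unit norm
    order = sorted(range(len(vocab)), key=lambda i: (-scores[i], vocab.names[i]))
    best = order[0]
    best_score = float(np.clip(scores[best], -1.0, 1.0))
    if best_score < threshold:
        return None
    runner = float(np.clip(scores[order[1]], -1.0, 1.0)) if len(vocab) > 1 else -1.0
    return CleanupResult(vocab.names[best], best_score, runner)
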
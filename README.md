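# vsbind

Vector-symbolic sequence processing: a tested Python library and CLI for
encoding serially ordered input into structured, queryable distributed
representations, built on Plate's holographic reduced representations (HRRs).

## Who this is for

Computational neuroscientists and cognitive modellers who want a desk-scale,
fully deterministic implementation of vector-symbolic sequence encoding —
serial-order working memory, non-adjacent dependency chunking, nested and
crossed hierarchical structure, and oscillator-gated operation scheduling —
with Monte-Carlo capacity benchmarks and the population-activity signatures
(rising superposed activation, orthogonalizing binding) that make the model
empirically testable.

## The model in brief

Symbols are random unit vectors in **R**^d (d ≈ 256–1024). Two operators
build structure:

- **Superposition** `A + B`: element-wise addition; the result stays
  *correlated* with each constituent. Deliberately not renormalized — a
  buffer's growing norm is one of the model's neural predictions.
- **Binding** `A ⊛ B`: circular convolution,
  `c[k] = Σ_j a[j]·b[(k−j) mod d]`; the result is approximately *orthogonal*
  to both inputs but keeps their dimensionality (a *reduced representation*).
  Contents are recovered by **unbinding** with the approximate inverse
  `¬B` (the involution fixing entry 0 and reversing the rest):
  `(A ⊛ B) ⊛ ¬B ≈ A + noise`, resolved against a nearest-neighbour
  **cleanup** memory.

Serial order is marked with **positional tags**: convolutional powers of a
unitary base vector (`2° = 1° ⊛ 1°`), one independent family per hierarchy
level, so every tag has an *exact* inverse. A sequence is stored as

    Sequence = w_1·(1° ⊛ Item1) + w_2·(2° ⊛ Item2) + … ,
    w_i = γ^(L−i) + ρ^(i−1)

with recency decay γ and primacy weight ρ producing the classic U-shaped
serial-position curve. Salience filtering deletes irrelevant intervening
items before chunk encoding, so `A-Xⁿ-B` encodes *bit-identically* to `A-B`.
Chunks bound to chunk-level tags and superposed form superchunks encoding
nested (`A1 A2 B2 B1`) or crossed (`A1 A2 B1 B2`) dependencies at fixed
dimensionality; composite keys such as `¬(2°_I ⊛ 1°_C)` retrieve single
slots, partial keys walk a whole chunk or one item across chunks. Ideal
discrete-time oscillators schedule *when* bindings fire (threshold
triggers, antiphase segregation, phase-decoded ordinal position) without
ever changing *what* is encoded.

## Worked example

Library — unbind one pair out of a superposed two-pair trace:

```python
import vsbind as vb

vocab = vb.Vocabulary.create(["A", "B", "C", "D"], dim=1024, seed=42)
R = vb.superpose([vb.bind(vocab["A"], vocab["B"]), vb.bind(vocab["C"], vocab["D"])])
result = vb.cleanup(vb.unbind(R, vocab["D"]), vocab)
print(result)
# CleanupResult(name='C', score=0.6150835717714244, runner_up_score=0.054034398243989756)
```

Unbinding `R` with `¬D` releases `C + noise`: the cleanup score 0.62 is the
cosine to the true answer, and the gap to the runner-up (0.05) is the
retrieval margin left after superposition crosstalk.

CLI — encode the nested structure `A1 A2 B2 B1` (chunks at serial positions
1&4 and 2&3), query one slot, then decode everything:

```bash
$ echo '{"kind": "nested", "chunks": [[1, 4], [2, 3]]}' > nested.json
$ vsbind encode-struct --tokens A1,A2,B2,B1 --spec nested.json --dim 1024 --seed 7 --out s.h5
encoded 2 chunks (nested) at dim=1024 -> s.h5 (seed=7)
$ vsbind query --trace s.h5 --key chunk:1,item:2
chunk:1,item:2: B1 (score=0.486)
$ vsbind unpack --trace s.h5
chunk 1, item 1: A1
chunk 1, item 2: B1
chunk 2, item 1: A2
chunk 2, item 2: B2
4 slots decoded, 0 no-match
```

The composite key `¬(2°_I ⊛ 1°_C)` retrieves the second item of the first
chunk — `B1`, the long-distance partner of `A1` — and iterating all keys
reconstructs every (chunk, item, token) triple of the hierarchy from one
1024-dimensional vector.

Serial-order memory with decay and primacy:

```bash
$ vsbind encode-seq --tokens the,cat,sat --dim 1024 --seed 7 --gamma 0.82 --rho 0.35 --out t.h5
encoded 3 tokens at dim=1024 -> t.h5 (seed=7)
$ vsbind recall --trace t.h5 --position 2
position 2: cat (score=0.471, runner-up=0.022)
```

Other subcommands: `gate-demo` (oscillator commit schedules), `gen`
(artificial-grammar sequences), `benchmark` (recall accuracy over
dimension × load), `report --activation` (buffer accumulation series).

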
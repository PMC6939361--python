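# Methods

This note records the model as implemented: its operators, the places where
the design was genuinely open and what was chosen, the numeric conventions,
what the synthetic generators do and do not emulate, and known limitations.

## The algebra

All representations are float64 vectors of a common dimensionality d.
Binding is circular convolution, computed through the FFT identity
(`irfft(rfft(a)·rfft(b))`); the test suite holds it to within 1e-9 max-abs
of the direct O(d²) sum at d ≤ 256, and the convolution theorem guarantees
the identity at any d in double precision. The approximate inverse is the
index involution `¬a[0] = a[0], ¬a[j] = a[d−j]` — equivalently complex
conjugation of the spectrum — which is the unique index permutation that
makes `u ⊛ ¬u = e₀` exact for unitary vectors and is self-inverse.
Superposition is plain addition and is never renormalized: the squared norm
of an accumulating buffer is itself one of the model's observable
signatures (see Reports below). An explicit `normalize` exists for callers
who want unit inputs.

Atomic symbol vectors default to i.i.d. gaussian N(0, 1/d), unit-normalized
— the distribution for which HRR capacity theory is stated. A sparse mode
(default density 0.05, configurable; the neurally flavoured choice) and a
unitary mode (unit-magnitude spectrum with random conjugate-symmetric
phases) are provided. Unitary vectors are the tag material: binding by them
is norm-preserving and exactly invertible, so positional retrieval loses
nothing beyond superposition crosstalk.

Cleanup is single-shot nearest-neighbour by cosine (scale-invariant, which
matters because stored bindings carry decay weights). Below-threshold best
matches return a distinct no-match outcome rather than raising — an empty
or fully decayed trace is a legitimate query target. Exact ties break to
the lexicographically smaller name so that runs are reproducible; the tie
is visible in the runner-up score. An iterative, attractor-style cleanup
would be a natural extension but is not implemented.

## Seeds

Every stochastic object derives its seed as
`SeedSequence([global_seed, crc32(purpose), index])`, truncated to 31 bits.
CRC-32 rather than Python's `hash` keeps derivation stable across processes
and platforms, making whole pipelines bit-reproducible from one integer.

## Positional tags

Tag k of a level is the k-th convolutional power of that level's unitary
base (2° = 1° ⊛ 1°), so unitarity — and hence exact invertibility — is
inherited by every tag. Orders are 1-based ("primary", "secondary");
storage is 0-based. Each hierarchy level (item, chunk, …) draws an
independent base from its own child seed: levels are near-orthogonal tag
families, which is what lets a composite key address one (chunk, item)
slot. Powers of a random unitary vector are quasi-orthogonal with high
probability but not by construction, so `make_tagset` screens all pairwise
|cosines| against 0.2 and regenerates the base from the next child seed on
failure (up to 10 attempts, then a capacity error recommending a larger d).
The screen makes "each tag orthogonal enough to the last for unambiguous
recovery" a constructive guarantee rather than a hope. Tag identity depends
only on order within a chunk, never on absolute sequence position; the
oscillator (below) selects *which* order index fires, not what the tag is.

## Serial-order buffer

A sequence is stored as Σᵢ wᵢ·(i° ⊛ Itemᵢ) with two-component weights

    wᵢ = γ^(L−i) + ρ^(i−1),   γ ∈ (0,1],  ρ ∈ [0,1).

The recency term is what a leaky recurrent buffer does to older entries;
the primacy term is a rehearsal-like encoding boost for early items. This
is the simplest weighting that produces both ends of the U-shaped
serial-position curve. Convention: ρ = 0 means the primacy component is
absent entirely (not ρ⁰ = 1 for the first item), so γ = 1, ρ = 0 is the
plain unweighted superposition. Defaults γ = 0.82, ρ = 0.35 were calibrated
once to yield a clearly U-shaped curve at list length 7 with a 32-token
vocabulary at d = 256, and are exposed in the API and CLI. The trace keeps
its recency- and primacy-weighted parts separately so that appending a
token is an exact O(d) update (decay the recency part by γ, add the new
binding) equivalent to re-encoding from scratch. The buffer does not
renormalize between items, consistent with the accumulating-activation
signature. A stored token log is debugging metadata only; no decoding path
reads it.

## Dependency and structure coding

Salience filtering keeps the marked tokens (by name and/or serial
position), preserves order, and re-indexes survivors from 1. Chunk encoding
then applies *unweighted* item-tag bindings — the dependency buffer is
modelled as holding its few salient constituents without decay. Both
choices together make the central identity exact and bitwise: A-Xⁿ-B
filters to [A, B] and encodes to literally the same vector as A-B, for any
n that fits in working memory. Decay weighting here would break that
identity, which is why the dependency buffer differs from the serial
buffer.

A structure trace is Σ_c chunk_tag_c ⊛ (Σ_i item_tag_i ⊛ item_{c,i}).
Nested and crossed layouts use identical machinery; only the declarative
chunk spec (which serial positions form which chunk) differs. Two levels
ship by default; deeper recursion is available by treating a structure
trace as a token in a higher-level vocabulary. Partial keys are answered
by unbinding once and then iterating the unspecified level's tags, one
cleanup per slot — the constructive reading of "a chunk key recovers all
of that chunk's position–item bindings". Full decoding iterates the
chunk-major cross-product of keys.

Grammar memory is a weighted superposition of structure traces; familiarity
of a probe is its cosine to that accumulation, and thresholding a
grammaticality decision is left to the caller.

**A deliberate negative result.** Because items bind only to positional
tags — never to each other — a superposed grammar trace is linear in
per-position item counts. Probes that pair A with the *wrong family's* B
in the right order are therefore indistinguishable from grammatical probes
in expectation: measured win rates sit near chance, and provably so.
Probes that violate *order* (B before A) are detected essentially always.
The synthetic generator therefore defaults to reversed-pair violations
(`violation="reversed"`), with family mismatch available as an option
precisely because its at-chance behaviour is an informative property of
additive chunk codes: detecting identity-contingent pairings would require
a conjunctive item–item code, which this model intentionally omits.

## Oscillatory control

Oscillators are ideal sampled sinusoids in unitless discrete time — the
functional contract (threshold triggering, antiphase segregation, phase
coding) needs nothing more, and a spiking substrate is out of scope.
Mapping to theta/gamma bands is documentation only. Triggers fire at
upward threshold crossings (`s(t−1) < θ ≤ s(t)`, with the t = −1 sample
evaluated analytically so a crossing at t = 0 counts). Two gates offset by
π can never fire on the same step: their samples are exact negations, so
the crossing conditions are mutually exclusive — verified exhaustively for
all integer periods up to 200 regardless of parity.

`gated_encode` commits each stimulus at the first trigger at or after its
onset. Its ordinal order is decoded from the phase of a slow oscillator at
freq/K (K = number of stimuli) that is phase-reset at the first commit —
position from phase, anchored at the chunk boundary. Two stimuli claiming
one trigger raise a collision error (no queueing), and decoded orders that
do not form a permutation of 1..K (stimulus rate mismatched to gate rate)
also raise, which keeps the contract exact: the scheduler changes when
bindings fire, never what the trace is. Nested fast/slow (theta–gamma)
gating for stimulus rates above the gate rate is not implemented.

## Synthetic grammars and what they do not emulate

The generators produce the canonical paradigms: adjacent pairs, A-Xⁿ-B
with uniformly drawn filler identities, and nested/crossed k-pair
structures with their chunk layouts attached. Grammatical status alternates
deterministically so any prefix has a known composition. These are clean,
noiseless token streams over small closed vocabularies: no acoustic or
visual variability, no segmentation ambiguity, no upstream parsing (chunk
layouts are given, not inferred), and no learning of the structure —
passing tests show the *representational* capacity of the encoding, not
that the structures could be acquired from input statistics.

## Reports and benchmarks

`benchmark_recall` measures exact-serial-recall rates over a
(dimension × load) grid with fresh vocabularies per trial; accuracy falls
with load and rises with dimension, the lossy-compression trade-off of
reduced representations. `activation_report` tracks the squared norm and
supra-threshold entry count of an accumulating buffer; for k unit-norm
quasi-orthogonal bindings the squared norm grows ≈ linearly in k, and a
reset zeroes it. The active-count threshold 2/√d is a scale-aware
reporting convention, not a model claim. `orthogonality_report` summarizes
|cos| between bound vectors and their constituents (≈ d^(−1/2), mean below
0.1 at d = 256).

## Numerical conventions and problem sizes

Exactness claims are asserted at 1e-9 max-abs (1e-6 for three-way
associativity, where FFT round-off compounds) in double precision at
d ≤ 1024. The packaged test suite and the acceptance script run the
pipeline at the study sizes used throughout: d = 256 for crosstalk-limited
settings (16–32-token vocabularies), d = 1024 where near-perfect retrieval
is the claim, with 100–1000 Monte-Carlo trials per quantity; all are
cheap enough to re-run in seconds on one core.

One measured quantity deserves a flag: the cosine between nested and
crossed traces over the same four tokens. The two layouts share two of
their four bound terms, so the population mean is exactly 1/2 with
±d^(−1/2) spread; "distinguishable" here means far from 1, not near 0,
and any strict bound at 0.5 has no margin.

## Known limitations

- Cleanup is single-shot; no attractor iteration.
- Two hierarchy levels by default; deeper nesting via manual re-tokenizing.
- No learning anywhere: tags, vocabularies and chunk layouts are given.
- Item–item conjunctions are not encoded, so identity-contingent pairing
  violations are invisible to the grammar trace (see above).
- Single-band gating; no nested theta–gamma scheduling.
- Ideal oscillators and exact vector arithmetic; no neural noise model.
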
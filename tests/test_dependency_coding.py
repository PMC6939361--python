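"""Salience filtering, chunk encoding, hierarchical structures and familiarity."""
import numpy as np
import pytest

import vsbind as vb
from vsbind.exceptions import (
    CapacityError,
    EmptyDependencyError,
    KeyStateError,
    ParameterError,
    StructureSpecError,
)


@pytest.fixture(scope="module")
def setup_1024():
    d = 1024
    tokens = ["A1", "A2", "B2", "B1", "X"]
    vocab = vb.Vocabulary.create(tokens, d, seed=41)
    item_tags = vb.make_tagset("item", d, 2, seed=42)
    chunk_tags = vb.make_tagset("chunk", d, 2, seed=43)
    return vocab, item_tags, chunk_tags


class TestSalienceFiltering:
    def test_drops_intervening_items(self):
        mask = vb.SalienceMask(tokens={"A", "B"})
        assert vb.filter_salient(["A", "X", "X", "B"], mask) == ["A", "B"]

    def test_position_mask(self):
        mask = vb.SalienceMask(positions={1, 4})
        assert vb.filter_salient(["A", "X", "X", "B"], mask) == ["A", "B"]

    def test_all_salient_unchanged(self):
        mask = vb.SalienceMask(tokens={"A", "B", "X"})
        assert vb.filter_salient(["A", "X", "B"], mask) == ["A", "X", "B"]

    def test_everything_filtered_raises(self):
        with pytest.raises(EmptyDependencyError):
            vb.filter_salient(["X", "X"], vb.SalienceMask(tokens={"A"}))

    def test_mask_needs_a_criterion(self):
        with pytest.raises(ParameterError):
            vb.SalienceMask()

    @pytest.mark.parametrize("n", range(6))
    def test_nonadjacent_collapses_to_adjacent(self, n, setup_1024):
        # A-X^n-B encodes bit-identically to AB under fixed seeds and tags
        vocab, item_tags, _ = setup_1024
        mask = vb.SalienceMask(tokens={"A1", "B1"})
        seq = ["A1"] + ["X"] * n + ["B1"]
        chunk = vb.encode_chunk(vb.filter_salient(seq, mask), vocab, item_tags)
        ref = vb.encode_chunk(["A1", "B1"], vocab, item_tags)
        assert np.array_equal(chunk, ref)


class TestEncodeChunk:
    def test_superposed_position_item_bindings(self, setup_1024):
        vocab, item_tags, _ = setup_1024
        chunk = vb.encode_chunk(["A1", "B1"], vocab, item_tags)
        manual = vb.bind(item_tags.tag(1), vocab["A1"]) + vb.bind(item_tags.tag(2), vocab["B1"])
        assert np.abs(chunk - manual).max() < 1e-12

    def test_secondary_element_retrieval(self, setup_1024):
        vocab, item_tags, _ = setup_1024
        chunk = vb.encode_chunk(["A1", "B1"], vocab, item_tags)
        r = vb.cleanup(vb.unbind(chunk, item_tags.tag(2)), vocab)
        assert r.name == "B1"

    def test_single_item_chunk(self, setup_1024):
        vocab, item_tags, _ = setup_1024
        chunk = vb.encode_chunk(["A1"], vocab, item_tags)
        assert np.abs(chunk - vb.bind(item_tags.tag(1), vocab["A1"])).max() < 1e-12

    def test_unused_position_is_no_match(self):
        vocab = vb.Vocabulary.create([f"V{i}" for i in range(8)], 1024, seed=5)
        tags = vb.make_tagset("item", 1024, 3, seed=6)
        misses = 0
        for s in range(20):
            rng = vb.child_rng(s, "chunk")
            toks = [f"V{i}" for i in rng.choice(8, 2, replace=False)]
            chunk = vb.encode_chunk(toks, vocab, tags)
            misses += vb.cleanup(vb.unbind(chunk, tags.tag(3)), vocab) is None
        assert misses >= 19

    def test_capacity_error(self, setup_1024):
        vocab, item_tags, _ = setup_1024
        with pytest.raises(CapacityError):
            vb.encode_chunk(["A1", "A2", "B2"], vocab, item_tags)


class TestStructureSpec:
    def test_json_round_trip(self):
        spec = vb.StructureSpec(chunks=((1, 4), (2, 3)), kind="nested")
        assert vb.StructureSpec.from_json(spec.to_json()) == spec

    @pytest.mark.parametrize(
        "chunks,kind",
        [
            (((1, 4), (2, 4)), "custom"),     # position reused
            (((4, 1),), "custom"),            # not increasing
            (((1, 3), (2, 4)), "nested"),     # interleaved spans are not nested
            (((1, 2), (3, 4)), "crossed"),    # no interleave
            ((), "custom"),                   # no chunks
        ],
    )
    def test_invalid_layouts(self, chunks, kind):
        with pytest.raises(StructureSpecError):
            vb.StructureSpec(chunks=chunks, kind=kind)

    def test_valid_nested_and_crossed(self):
        vb.StructureSpec(chunks=((1, 4), (2, 3)), kind="nested")
        vb.StructureSpec(chunks=((1, 3), (2, 4)), kind="crossed")


class TestEncodeStructure:
    def test_superchunk_composition(self, setup_1024):
        vocab, item_tags, chunk_tags = setup_1024
        tokens = ["A1", "A2", "B2", "B1"]
        spec = vb.StructureSpec(chunks=((1, 4), (2, 3)), kind="nested")
        trace = vb.encode_structure(tokens, spec, vocab, item_tags, chunk_tags)
        c1 = vb.encode_chunk(["A1", "B1"], vocab, item_tags)
        c2 = vb.encode_chunk(["A2", "B2"], vocab, item_tags)
        manual = vb.bind(chunk_tags.tag(1), c1) + vb.bind(chunk_tags.tag(2), c2)
        assert np.abs(trace.vector - manual).max() < 1e-12

    def test_single_slot_structure(self, setup_1024):
        vocab, item_tags, chunk_tags = setup_1024
        spec = vb.StructureSpec(chunks=((1,),), kind="custom")
        trace = vb.encode_structure(["A1"], spec, vocab, item_tags, chunk_tags)
        manual = vb.bind(chunk_tags.tag(1), vb.bind(item_tags.tag(1), vocab["A1"]))
        assert np.abs(trace.vector - manual).max() < 1e-12

    def test_timescale_invariance(self, setup_1024):
        # the same pair gathered from far-apart serial positions encodes identically
        vocab, item_tags, chunk_tags = setup_1024
        near = vb.encode_structure(
            ["A1", "B1"], vb.StructureSpec(chunks=((1, 2),)), vocab, item_tags, chunk_tags
        )
        far = vb.encode_structure(
            ["A1", "X", "X", "X", "B1"],
            vb.StructureSpec(chunks=((1, 5),)),
            vocab,
            item_tags,
            chunk_tags,
        )
        assert np.array_equal(near.vector, far.vector)

    def test_spec_out_of_range(self, setup_1024):
        vocab, item_tags, chunk_tags = setup_1024
        with pytest.raises(StructureSpecError):
            vb.encode_structure(
                ["A1"], vb.StructureSpec(chunks=((1, 2),)), vocab, item_tags, chunk_tags
            )


@pytest.fixture(scope="module")
def nested(setup_1024):
    vocab, item_tags, chunk_tags = setup_1024
    spec = vb.StructureSpec(chunks=((1, 4), (2, 3)), kind="nested")
    return vb.encode_structure(["A1", "A2", "B2", "B1"], spec, vocab, item_tags, chunk_tags)


class TestQueryStructure:
    def test_fully_specified_key(self, nested, setup_1024):
        vocab, item_tags, chunk_tags = setup_1024
        key = vb.invert_key(vb.compose_key([item_tags, chunk_tags], [("item", 2), ("chunk", 1)]))
        [(address, r)] = vb.query_structure(nested, key, vocab)
        assert r.name == "B1"

    def test_chunk_key_walks_items(self, nested, setup_1024):
        vocab, item_tags, chunk_tags = setup_1024
        key = vb.invert_key(vb.compose_key([chunk_tags], [("chunk", 1)]))
        names = [r.name for _, r in vb.query_structure(nested, key, vocab) if r]
        assert names == ["A1", "B1"]

    def test_item_key_walks_chunks(self, nested, setup_1024):
        vocab, item_tags, chunk_tags = setup_1024
        key = vb.invert_key(vb.compose_key([item_tags], [("item", 2)]))
        names = [r.name for _, r in vb.query_structure(nested, key, vocab) if r]
        assert names == ["B1", "B2"]

    def test_uninverted_key_rejected(self, nested, setup_1024):
        vocab, item_tags, chunk_tags = setup_1024
        key = vb.compose_key([item_tags], [("item", 1)])
        with pytest.raises(KeyStateError):
            vb.query_structure(nested, key, vocab)

    def test_zero_trace_yields_no_match(self, nested, setup_1024):
        vocab, item_tags, chunk_tags = setup_1024
        import dataclasses

        empty = dataclasses.replace(nested, vector=np.zeros(nested.dim))
        key = vb.invert_key(vb.compose_key([chunk_tags], [("chunk", 1)]))
        assert all(r is None for _, r in vb.query_structure(empty, key, vocab))


class TestUnpackAndFamiliarity:
    def test_round_trip_nested_and_crossed(self, setup_1024):
        vocab, item_tags, chunk_tags = setup_1024
        tokens = ["A1", "A2", "B2", "B1"]
        nested = vb.encode_structure(
            tokens, vb.StructureSpec(chunks=((1, 4), (2, 3)), kind="nested"),
            vocab, item_tags, chunk_tags,
        )
        crossed = vb.encode_structure(
            tokens, vb.StructureSpec(chunks=((1, 3), (2, 4)), kind="crossed"),
            vocab, item_tags, chunk_tags,
        )
        triples_n, miss_n = vb.unpack_structure(nested, vocab)
        assert miss_n == 0
        assert triples_n == [(1, 1, "A1"), (1, 2, "B1"), (2, 1, "A2"), (2, 2, "B2")]
        triples_c, miss_c = vb.unpack_structure(crossed, vocab)
        assert miss_c == 0
        assert triples_c == [(1, 1, "A1"), (1, 2, "B2"), (2, 1, "A2"), (2, 2, "B1")]

    def test_structures_are_distinguishable(self, setup_1024):
        vocab, item_tags, chunk_tags = setup_1024
        tokens = ["A1", "A2", "B2", "B1"]
        nested = vb.encode_structure(
            tokens, vb.StructureSpec(chunks=((1, 4), (2, 3)), kind="nested"),
            vocab, item_tags, chunk_tags,
        )
        crossed = vb.encode_structure(
            tokens, vb.StructureSpec(chunks=((1, 3), (2, 4)), kind="crossed"),
            vocab, item_tags, chunk_tags,
        )
        # two of four bound terms coincide, so cosine sits near 1/2, far from 1
        assert vb.similarity(nested.vector, crossed.vector) < 0.7

    def test_accumulate_single_trace_identity(self, setup_1024):
        vocab, item_tags, chunk_tags = setup_1024
        chunk = vb.encode_structure(
            ["A1", "B1"], vb.StructureSpec(chunks=((1, 2),)), vocab, item_tags, chunk_tags
        )
        acc = vb.accumulate_grammar_trace([chunk], [1.0])
        assert np.array_equal(acc, chunk.vector)

    def test_accumulate_errors(self, setup_1024):
        vocab, item_tags, chunk_tags = setup_1024
        chunk = vb.encode_structure(
            ["A1", "B1"], vb.StructureSpec(chunks=((1, 2),)), vocab, item_tags, chunk_tags
        )
        with pytest.raises(ParameterError):
            vb.accumulate_grammar_trace([chunk], [1.0, 2.0])
        with pytest.raises(ParameterError):
            vb.accumulate_grammar_trace([chunk], [-1.0])

    def test_grammatical_probes_score_higher(self):
        wins = sum(
            fg > fu
            for fg, fu in (vb.familiarity_trial(512, s, n_exemplars=30) for s in range(20))
        )
        assert wins >= 18

    def test_mismatch_to_new_exemplars_decays(self):
        # familiarity of the next exemplar rises (mismatch falls) as the trace grows
        d = 512
        early, late = [], []
        for s in range(20):
            spec = vb.GrammarSpec(kind="axb", vocab_size=16, n_intervening=2,
                                  seed=vb.child_seed(s, "decay"))
            names = vb.grammar_vocabulary_names(spec)
            vocab = vb.Vocabulary.create(names, d, vb.child_seed(s, "decay-vocab"))
            it = vb.make_tagset("item", d, 2, vb.child_seed(s, "decay-item"))
            ct = vb.make_tagset("chunk", d, 1, vb.child_seed(s, "decay-chunk"))
            mask = vb.SalienceMask(tokens={n for n in names if not n.startswith("X")})
            layout = vb.StructureSpec(chunks=((1, 2),))
            seqs = [t for t, _, g in vb.gen_grammar_sequences(spec, 80) if g]
            encoded = [
                vb.encode_structure(vb.filter_salient(t, mask), layout, vocab, it, ct)
                for t in seqs
            ]
            for n, bucket in ((2, early), (30, late)):
                mem = vb.accumulate_grammar_trace(encoded[:n])
                bucket.append(1.0 - vb.familiarity(encoded[n], mem))
        assert np.mean(late) < np.mean(early)
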
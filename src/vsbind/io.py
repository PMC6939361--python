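"""HDF5 container serialization with JSON sidecars.

One ``.h5`` file bundles everything needed to decode a trace offline:
the vocabulary (dataset ``vocabulary/vectors``, float64, row order =
name order), tag families (groups ``tagsets/<level>``) and the trace
itself (group ``traces/<name>``).  A JSON sidecar (same path + ``.json``)
duplicates the generation metadata for humans and tools.  Float64
storage makes round trips bit-exact.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .dependency_coding import StructureSpec, StructureTrace
from .exceptions import ParameterError
from .hrr_core import Vocabulary
from .positional_tags import TagSet
from .sequence_memory import SequenceTrace

__all__ = [
    "save_sequence_bundle",
    "load_sequence_bundle",
    "save_structure_bundle",
    "load_structure_bundle",
]


def _write_vocab(f: h5py.File, vocab: Vocabulary) -> None:
    g = f.create_group("vocabulary")
    g.create_dataset("vectors", data=vocab.vectors, dtype="float64")
    g.attrs["meta"] = vocab.meta_json()


def _read_vocab(f: h5py.File) -> Vocabulary:
    g = f["vocabulary"]
    meta = json.loads(g.attrs["meta"])
    return Vocabulary(
        names=tuple(meta["names"]),
        vectors=np.asarray(g["vectors"], dtype=np.float64),
        dim=int(meta["dim"]),
        seed=int(meta["seed"]),
        mode=meta["mode"],
        sparsity=float(meta["sparsity"]),
    )


def _write_tagset(f: h5py.File, ts: TagSet) -> None:
    g = f.require_group("tagsets").create_group(ts.level)
    g.create_dataset("base", data=ts.base, dtype="float64")
    g.create_dataset("tags", data=np.stack(ts.tags), dtype="float64")
    g.attrs["meta"] = json.dumps(
        {"level": ts.level, "dim": ts.dim, "max_order": ts.max_order, "seed": ts.seed}
    )


def _read_tagset(f: h5py.File, level: str) -> TagSet:
    g = f["tagsets"][level]
    meta = json.loads(g.attrs["meta"])
    tags = np.asarray(g["tags"], dtype=np.float64)
    return TagSet(
        level=meta["level"],
        base=np.asarray(g["base"], dtype=np.float64),
        tags=tuple(tags[i] for i in range(tags.shape[0])),
        dim=int(meta["dim"]),
        max_order=int(meta["max_order"]),
        seed=int(meta["seed"]),
    )


def _sidecar(path: Path, payload: dict) -> None:
    Path(str(path) + ".json").write_text(json.dumps(payload, indent=2, ensure_ascii=False))


def save_sequence_bundle(
    path: str | Path,
    trace: SequenceTrace,
    vocab: Vocabulary,
    tags: TagSet,
    with_log: bool = False,
) -> None:
    """Write a serial-order trace plus its vocabulary and tag family.

    The token log is debugging metadata and is omitted unless ``with_log``.
    """
    path = Path(path)
    meta = {
        "type": "sequence",
        "length": trace.length,
        "level": trace.level,
        "dim": trace.dim,
        "gamma": trace.gamma,
        "rho": trace.rho,
        "log": list(trace.log) if (with_log and trace.log is not None) else None,
    }
    with h5py.File(path, "w") as f:
        _write_vocab(f, vocab)
        _write_tagset(f, tags)
        g = f.create_group("traces/main")
        g.create_dataset("vector", data=trace.vector, dtype="float64")
        g.create_dataset("recency_part", data=trace.recency_part, dtype="float64")
        g.create_dataset("primacy_part", data=trace.primacy_part, dtype="float64")
        g.attrs["meta"] = json.dumps(meta)
    _sidecar(path, {"vocabulary": vocab.meta(), "trace": meta})


def load_sequence_bundle(path: str | Path) -> tuple[SequenceTrace, Vocabulary, TagSet]:
    with h5py.File(path, "r") as f:
        vocab = _read_vocab(f)
        g = f["traces/main"]
        meta = json.loads(g.attrs["meta"])
        if meta["type"] != "sequence":
            raise ParameterError(f"{path} holds a {meta['type']!r} trace, not a sequence")
        tags = _read_tagset(f, meta["level"])
        trace = SequenceTrace(
            vector=np.asarray(g["vector"], dtype=np.float64),
            length=int(meta["length"]),
            level=meta["level"],
            dim=int(meta["dim"]),
            gamma=float(meta["gamma"]),
            rho=float(meta["rho"]),
            recency_part=np.asarray(g["recency_part"], dtype=np.float64),
            primacy_part=np.asarray(g["primacy_part"], dtype=np.float64),
            log=tuple(meta["log"]) if meta.get("log") else None,
        )
    return trace, vocab, tags


def save_structure_bundle(
    path: str | Path,
    trace: StructureTrace,
    vocab: Vocabulary,
    with_log: bool = False,
) -> None:
    """Write a superchunk trace plus vocabulary and both tag families."""
    path = Path(path)
    meta = {
        "type": "structure",
        "spec": json.loads(trace.spec.to_json()),
        "item_level": trace.item_tags.level,
        "chunk_level": trace.chunk_tags.level,
        "dim": trace.dim,
        "levels": trace.levels,
        "log": list(trace.log) if (with_log and trace.log is not None) else None,
    }
    with h5py.File(path, "w") as f:
        _write_vocab(f, vocab)
        _write_tagset(f, trace.item_tags)
        _write_tagset(f, trace.chunk_tags)
        g = f.create_group("traces/main")
        g.create_dataset("vector", data=trace.vector, dtype="float64")
        g.attrs["meta"] = json.dumps(meta)
    _sidecar(path, {"vocabulary": vocab.meta(), "trace": meta})


def load_structure_bundle(path: str | Path) -> tuple[StructureTrace, Vocabulary]:
    with h5py.File(path, "r") as f:
        vocab = _read_vocab(f)
        g = f["traces/main"]
        meta = json.loads(g.attrs["meta"])
        if meta["type"] != "structure":
            raise ParameterError(f"{path} holds a {meta['type']!r} trace, not a structure")
        trace = StructureTrace(
            vector=np.asarray(g["vector"], dtype=np.float64),
            spec=StructureSpec.from_json(json.dumps(meta["spec"])),
            item_tags=_read_tagset(f, meta["item_level"]),
            chunk_tags=_read_tagset(f, meta["chunk_level"]),
            dim=int(meta["dim"]),
            levels=int(meta["levels"]),
            log=tuple(meta["log"]) if meta.get("log") else None,
        )
    return trace, vocab
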
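"""Embedding-based text similarity at word, sentence and paragraph scale.

Four cosine-similarity measures are attached to every token:

* ``word_sent``  — fixated word vs. its containing sentence
* ``sent_sent``  — containing sentence vs. the preceding sentence
* ``sent_para``  — containing sentence vs. its containing paragraph
* ``para_para``  — containing paragraph vs. the preceding paragraph

Sentence- and paragraph-level values are constant across all tokens of a
sentence. ``sent_sent`` is missing (NaN) for the document-initial sentence and
``para_para`` for the first paragraph; "preceding sentence" follows document
order across paragraph boundaries. Embeddings are consumed from a
word2vec-style text file and never trained here.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .text import TextStructure

LEVELS = ("word", "sent", "para")

SIMILARITY_COLUMNS = ["word_sent", "sent_sent", "sent_para", "para_para"]


class EmbeddingFormatError(ValueError):
    pass


class EmbeddingLookupError(KeyError):
    pass


def cosine(x, y) -> float:
    """Cosine of the angle between two equal-length non-zero vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("cosine undefined for a zero vector")
    # clip guards against |value| creeping past 1 by rounding
    return float(np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0))


class EmbeddingSet:
    """Fixed-dimension vectors keyed by (level, id), level in {word, sent, para}."""

    def __init__(self, vectors: dict[tuple[str, int], np.ndarray], dimension: int | None = None):
        if not vectors:
            raise EmbeddingFormatError("no vectors")
        self.vectors = {}
        for key, vec in vectors.items():
            level, uid = key
            if level not in LEVELS:
                raise EmbeddingFormatError(f"unknown level {level!r}")
            vec = np.asarray(vec, dtype=float)
            if dimension is None:
                dimension = vec.size
            if vec.size != dimension:
                raise EmbeddingFormatError(
                    f"vector {level}:{uid} has dimension {vec.size}, expected {dimension}"
                )
            if not np.any(vec):
                raise EmbeddingFormatError(f"vector {level}:{uid} is all-zero")
            self.vectors[(level, int(uid))] = vec
        self.dimension = int(dimension)

    def get(self, level: str, uid: int) -> np.ndarray:
        try:
            return self.vectors[(level, int(uid))]
        except KeyError:
            raise EmbeddingLookupError(f"missing embedding for {level}:{uid}") from None

    def __len__(self) -> int:
        return len(self.vectors)

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.vectors)} {self.dimension}\n")
            for (level, uid), vec in sorted(self.vectors.items()):
                fh.write(f"{level}:{uid} " + " ".join(repr(float(v)) for v in vec) + "\n")


def load_embeddings(path, expected_dim: int | None = None) -> EmbeddingSet:
    """Read a word2vec-text-dialect embedding file.

    First line ``<n> <dim>``, then one row per unit: ``level:id v1 ... vdim``.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise EmbeddingFormatError("header must be '<n> <dim>'")
        n, dim = int(header[0]), int(header[1])
        if expected_dim is not None and dim != expected_dim:
            raise EmbeddingFormatError(f"file dimension {dim} != expected {expected_dim}")
        vectors: dict[tuple[str, int], np.ndarray] = {}
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            key = parts[0]
            if ":" not in key:
                raise EmbeddingFormatError(f"line {lineno}: key {key!r} is not 'level:id'")
            level, uid = key.split(":", 1)
            if level not in LEVELS:
                raise EmbeddingFormatError(f"line {lineno}: unknown level {level!r}")
            if len(parts) - 1 != dim:
                raise EmbeddingFormatError(
                    f"line {lineno}: {len(parts) - 1} values, expected {dim}"
                )
            tkey = (level, int(uid))
            if tkey in vectors:
                raise EmbeddingFormatError(f"line {lineno}: duplicate key {key!r}")
            vectors[tkey] = np.array([float(v) for v in parts[1:]])
    if len(vectors) != n:
        raise EmbeddingFormatError(f"header promised {n} vectors, found {len(vectors)}")
    return EmbeddingSet(vectors, dimension=dim)


def similarity_features(text: TextStructure, emb: EmbeddingSet) -> pd.DataFrame:
    """Per-token similarity features, indexed by token_id.

    Missing values (document-initial sentence / first paragraph) are NaN and
    are excluded later when modelling datasets are assembled.
    """
    sent_level: dict[int, tuple[float, float, float]] = {}
    for sid in sorted(text.sentence_index):
        pid = text.paragraph_of_sentence(sid)
        svec = emb.get("sent", sid)
        sent_sent = cosine(svec, emb.get("sent", sid - 1)) if sid > 0 else math.nan
        sent_para = cosine(svec, emb.get("para", pid))
        para_para = cosine(emb.get("para", pid), emb.get("para", pid - 1)) if pid > 0 else math.nan
        sent_level[sid] = (sent_sent, sent_para, para_para)

    rows = []
    for tok in text.tokens:
        ss, sp, pp = sent_level[tok.sentence_id]
        ws = cosine(emb.get("word", tok.token_id), emb.get("sent", tok.sentence_id))
        rows.append((tok.token_id, ws, ss, sp, pp))
    return pd.DataFrame(rows, columns=["token_id"] + SIMILARITY_COLUMNS).set_index("token_id")
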
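"""Contextual token encoding.

Each sentence is encoded independently by a bidirectional Elman recurrent
layer over word embeddings, producing one ``hidden_dim`` vector per token
(``hidden_dim/2`` per direction, concatenated). A degenerate "projection"
mode (H = X W^T, no recurrence) exists for hand-checkable tests, and a
"document" mode runs one recurrence across the whole document so sentence
context can cross boundaries.

Word embeddings come from a word2vec-format text file when available;
otherwise they are initialised from U(-0.05, 0.05) with a fixed seed so
desk-scale experiments need no external downloads.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .corpus_io import Corpus

PAD, UNK = "<pad>", "<unk>"

__all__ = ["EmbeddingTable", "SentenceEncoder", "read_word2vec_text"]


def read_word2vec_text(path: str | Path) -> dict[str, np.ndarray]:
    """Read a word2vec text-format file (optional count header line)."""
    vectors: dict[str, np.ndarray] = {}
    with open(path) as fh:
        first = fh.readline().split()
        if len(first) != 2 or not first[1].isdigit():
            vectors[first[0]] = np.array([float(x) for x in first[1:]])
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 2:
                continue
            vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
    return vectors


class EmbeddingTable:
    """Token -> trainable embedding row; rows 0/1 are padding and unknown."""

    def __init__(self, vocabulary: dict[str, int], vectors: Tensor):
        if PAD not in vocabulary or UNK not in vocabulary:
            raise ValueError("vocabulary must contain padding and unknown tokens")
        self.vocabulary = vocabulary
        self.vectors = vectors

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    @classmethod
    def build(cls, tokens: set[str], dim: int, seed: int,
              pretrained: dict[str, np.ndarray] | None = None) -> "EmbeddingTable":
        rng = np.random.default_rng(seed)
        vocab = {PAD: 0, UNK: 1}
        for tok in sorted(tokens):
            vocab.setdefault(tok, len(vocab))
        data = rng.uniform(-0.05, 0.05, size=(len(vocab), dim))
        data[0] = 0.0
        if pretrained:
            for tok, vec in pretrained.items():
                if tok in vocab and vec.shape[0] == dim:
                    data[vocab[tok]] = vec
        return cls(vocab, Tensor(data, requires_grad=True))

    @classmethod
    def from_corpus(cls, corpus: Corpus, dim: int, seed: int,
                    pretrained: dict[str, np.ndarray] | None = None) -> "EmbeddingTable":
        tokens = {tok for doc in corpus.documents
                  for sent in doc.sentences for tok in sent.tokens}
        return cls.build(tokens, dim, seed, pretrained)

    def indices(self, tokens: list[str]) -> np.ndarray:
        unk = self.vocabulary[UNK]
        return np.array([self.vocabulary.get(t, unk) for t in tokens], dtype=int)


class SentenceEncoder:
    """Bidirectional recurrent encoder producing per-token representations."""

    def __init__(self, embed_dim: int, hidden_dim: int, seed: int,
                 mode: str = "birnn"):
        if hidden_dim % 2:
            raise ValueError("hidden_dim must be even (two directions)")
        if mode not in ("birnn", "projection", "document"):
            raise ValueError(f"unknown encoder mode {mode!r}")
        self.hidden_dim = hidden_dim
        self.mode = mode
        rng = np.random.default_rng(seed)
        h2 = hidden_dim // 2
        s = 1.0 / np.sqrt(max(embed_dim, h2))
        if mode == "projection":
            self.Wp = ag.parameter(rng, (hidden_dim, embed_dim), s)
        else:
            self.Wx_f = ag.parameter(rng, (h2, embed_dim), s)
            self.Wh_f = ag.parameter(rng, (h2, h2), s)
            self.b_f = Tensor(np.zeros(h2), requires_grad=True)
            self.Wx_b = ag.parameter(rng, (h2, embed_dim), s)
            self.Wh_b = ag.parameter(rng, (h2, h2), s)
            self.b_b = Tensor(np.zeros(h2), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        if self.mode == "projection":
            return [self.Wp]
        return [self.Wx_f, self.Wh_f, self.b_f, self.Wx_b, self.Wh_b, self.b_b]

    def _run_direction(self, X: Tensor, Wx: Tensor, Wh: Tensor, b: Tensor,
                       reverse: bool) -> list[Tensor]:
        n = X.shape[0]
        order = range(n - 1, -1, -1) if reverse else range(n)
        h = Tensor(np.zeros(Wh.shape[0]))
        states: dict[int, Tensor] = {}
        for t in order:
            h = (X[t] @ Wx.transpose() + h @ Wh.transpose() + b).tanh()
            states[t] = h
        return [states[t] for t in range(n)]

    def encode_tokens(self, tokens: list[str], table: EmbeddingTable) -> Tensor:
        """Encode one sentence; returns an (|s|, hidden_dim) matrix."""
        if not tokens:
            raise ValueError("cannot encode an empty sentence")
        X = table.vectors[table.indices(tokens)]
        if self.mode == "projection":
            return X @ self.Wp.transpose()
        fwd = self._run_direction(X, self.Wx_f, self.Wh_f, self.b_f, reverse=False)
        bwd = self._run_direction(X, self.Wx_b, self.Wh_b, self.b_b, reverse=True)
        rows = [ag.cat([f, b]) for f, b in zip(fwd, bwd)]
        return ag.stack(rows, axis=0)

    def encode_document(self, sentences: list[list[str]],
                        table: EmbeddingTable) -> list[Tensor]:
        """Encode each sentence; in "document" mode the recurrence runs over
        the concatenated token stream and is split back per sentence."""
        if self.mode != "document":
            return [self.encode_tokens(s, table) for s in sentences]
        flat = [t for s in sentences for t in s]
        H = self.encode_tokens(flat, table) if flat else None
        out, pos = [], 0
        for s in sentences:
            out.append(H[np.arange(pos, pos + len(s))])
            pos += len(s)
        return out
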
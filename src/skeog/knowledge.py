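"""Knowledge-node content representations.

Two families of providers feed the external-knowledge nodes of the document
graph:

* ``h_ks`` from a triple store: TransE (translation distance, pre-trained
  and frozen), RESCAL (bilinear tensor factorisation, pre-trained and
  frozen), or a GAT subgraph encoder trained end-to-end with the main model;
* ``h_kd`` from entity description text: a simplified distributed-memory
  Doc2vec (pre-trained and frozen) or an end-to-end embed -> BiRNN ->
  mean-pool encoder (EMB).

All providers of one family emit a single configured dimension, so knowledge
node construction is provider-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "Triple", "KnowledgeGraph", "KGEmbeddings", "transe_score", "train_transe",
    "rescal_score", "factorize_rescal", "GATEncoder", "gat_embed",
    "embed_description_doc2vec", "DescriptionEncoder",
    "read_descriptions_tsv", "write_embedding_cache", "read_embedding_cache",
]


@dataclass(frozen=True)
class Triple:
    head: str
    relation: str
    tail: str

    def __post_init__(self):
        if not (self.head and self.relation and self.tail):
            raise ValueError("triple ids must be non-empty")


class KnowledgeGraph:
    def __init__(self, triples: list[Triple]):
        self.triples = list(triples)
        ents = sorted({x for t in self.triples for x in (t.head, t.tail)})
        rels = sorted({t.relation for t in self.triples})
        self.entity_index = {e: i for i, e in enumerate(ents)}
        self.relation_index = {r: i for i, r in enumerate(rels)}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KnowledgeGraph":
        triples = []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            h, r, t = line.split("\t")
            triples.append(Triple(h, r, t))
        return cls(triples)

    @property
    def entity_ids(self) -> set[str]:
        return set(self.entity_index)

    def __len__(self):
        return len(self.triples)

    def neighbors(self, entity_id: str) -> set[str]:
        out = set()
        for t in self.triples:
            if t.head == entity_id:
                out.add(t.tail)
            elif t.tail == entity_id:
                out.add(t.head)
        return out


@dataclass
class KGEmbeddings:
    """Frozen entity representations from one of the KG providers."""
    method: str                                   # transe | rescal
    entity_vectors: dict[str, np.ndarray]
    relation_vectors: dict[str, np.ndarray] = field(default_factory=dict)
    relation_matrices: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return next(iter(self.entity_vectors.values())).shape[0]


# -- TransE -------------------------------------------------------------------

def transe_score(h_vec: np.ndarray, r_vec: np.ndarray, t_vec: np.ndarray) -> float:
    """Translation-distance score ||h + r - t||_2; lower = more plausible."""
    h_vec, r_vec, t_vec = map(np.asarray, (h_vec, r_vec, t_vec))
    if not h_vec.shape == r_vec.shape == t_vec.shape:
        raise ValueError("dimension mismatch in TransE score")
    return float(np.linalg.norm(h_vec + r_vec - t_vec))


def train_transe(kg: KnowledgeGraph, dim: int = 8, gamma: float = 1.0,
                 epochs: int = 200, lr: float = 0.05, seed: int = 0) -> KGEmbeddings:
    """Max-margin training with filtered negative sampling.

    For each true triple a corrupted one is drawn by replacing the head or
    the tail uniformly at random (resampled if the corruption is itself a
    true triple), and the hinge max(f(h,t) + gamma - f(h',t'), 0) is
    minimised by SGD. Entity vectors are re-normalised to unit L2 after
    each epoch.
    """
    if not kg.triples:
        raise ValueError("cannot train TransE on an empty knowledge graph")
    rng = np.random.default_rng(seed)
    ents = sorted(kg.entity_index)
    n_e = len(ents)
    E = rng.uniform(-0.5, 0.5, size=(n_e, dim))
    E /= np.linalg.norm(E, axis=1, keepdims=True)
    R = rng.uniform(-0.5, 0.5, size=(len(kg.relation_index), dim))
    R /= np.linalg.norm(R, axis=1, keepdims=True)
    truth = {(t.head, t.relation, t.tail) for t in kg.triples}
    ei, ri = kg.entity_index, kg.relation_index

    for _ in range(epochs):
        order = rng.permutation(len(kg.triples))
        for idx in order:
            tr = kg.triples[idx]
            h, r, t = ei[tr.head], ri[tr.relation], ei[tr.tail]
            # filtered corruption of head or tail
            hn, tn = h, t
            for _attempt in range(20):
                cand = int(rng.integers(0, n_e))
                if rng.random() < 0.5:
                    hn, tn = cand, t
                else:
                    hn, tn = h, cand
                if (ents[hn], tr.relation, ents[tn]) not in truth:
                    break
            else:
                continue
            dpos = E[h] + R[r] - E[t]
            dneg = E[hn] + R[r] - E[tn]
            fpos = np.linalg.norm(dpos)
            fneg = np.linalg.norm(dneg)
            if fpos + gamma - fneg <= 0:
                continue
            gpos = dpos / (fpos + 1e-12)
            gneg = dneg / (fneg + 1e-12)
            E[h] -= lr * gpos
            E[t] += lr * gpos
            R[r] -= lr * (gpos - gneg)
            E[hn] += lr * gneg
            E[tn] -= lr * gneg
        E /= np.linalg.norm(E, axis=1, keepdims=True) + 1e-12
    return KGEmbeddings("transe",
                        {e: E[i].copy() for e, i in ei.items()},
                        relation_vectors={r: R[i].copy() for r, i in ri.items()})


def transe_margin_loss(kg: KnowledgeGraph, emb: KGEmbeddings, gamma: float,
                       negatives: list[tuple[str, str, str]]) -> float:
    """Hinge objective evaluated on paired true/corrupted triples."""
    total = 0.0
    for t, neg in zip(kg.triples, negatives):
        fpos = transe_score(emb.entity_vectors[t.head],
                            emb.relation_vectors[t.relation],
                            emb.entity_vectors[t.tail])
        fneg = transe_score(emb.entity_vectors[neg[0]],
                            emb.relation_vectors[neg[1]],
                            emb.entity_vectors[neg[2]])
        total += max(fpos + gamma - fneg, 0.0)
    return total


# -- RESCAL -------------------------------------------------------------------

def rescal_score(h_vec: np.ndarray, relation_matrix: np.ndarray,
                 t_vec: np.ndarray) -> float:
    """Bilinear score h^T M_r t."""
    h_vec, t_vec = np.asarray(h_vec), np.asarray(t_vec)
    M = np.asarray(relation_matrix)
    if M.shape != (h_vec.shape[0], t_vec.shape[0]):
        raise ValueError("dimension mismatch in RESCAL score")
    return float(h_vec @ M @ t_vec)


def build_tensor(kg: KnowledgeGraph) -> np.ndarray:
    """Binary tensor X with X[i, j, k] = 1 iff <e_i, r_k, e_j> holds."""
    n, m = len(kg.entity_index), len(kg.relation_index)
    X = np.zeros((n, n, m))
    for t in kg.triples:
        X[kg.entity_index[t.head], kg.entity_index[t.tail],
          kg.relation_index[t.relation]] = 1.0
    return X


def factorize_rescal(kg: KnowledgeGraph, rank: int, epochs: int = 500,
                     lr: float = 0.05, seed: int = 0,
                     ) -> tuple[KGEmbeddings, list[float]]:
    """Fit X_k ~ A R_k A^T by gradient descent on the squared error
    f(A, R) = 1/2 sum_ijk (X_ijk - a_i^T R_k a_j)^2.

    The step size is halved whenever a step would increase the loss, so the
    recorded loss history is monotonically non-increasing. Returns the
    embeddings (entity vector = row of A) and the loss history.
    """
    n = len(kg.entity_index)
    if rank < 1 or rank > n:
        raise ValueError(f"rank must be in [1, {n}], got {rank}")
    rng = np.random.default_rng(seed)
    X = build_tensor(kg)
    m = X.shape[2]
    A = rng.uniform(-0.1, 0.1, size=(n, rank))
    Rk = rng.uniform(-0.1, 0.1, size=(m, rank, rank))

    def loss(A, Rk):
        return 0.5 * sum(float(((X[:, :, k] - A @ Rk[k] @ A.T) ** 2).sum())
                         for k in range(m))

    history = [loss(A, Rk)]
    step = lr
    for _ in range(epochs):
        gA = np.zeros_like(A)
        gR = np.zeros_like(Rk)
        for k in range(m):
            E = X[:, :, k] - A @ Rk[k] @ A.T
            gA -= E @ A @ Rk[k].T + E.T @ A @ Rk[k]
            gR[k] = -(A.T @ E @ A)
        while step > 1e-12:
            A2, R2 = A - step * gA, Rk - step * gR
            new = loss(A2, R2)
            if new <= history[-1]:
                A, Rk = A2, R2
                history.append(new)
                break
            step *= 0.5
        else:
            history.append(history[-1])
    emb = KGEmbeddings("rescal",
                       {e: A[i].copy() for e, i in kg.entity_index.items()},
                       relation_matrices={r: Rk[i].copy()
                                          for r, i in kg.relation_index.items()})
    return emb, history


# -- GAT subgraph encoder (end-to-end) ---------------------------------------

class GATEncoder:
    """Graph-attention encoder over the radius-hop neighborhood of an entity.

    Entity input features are a learnable embedding table; attention follows
    the standard single-layer form
    ``e_uv = LeakyReLU(a^T [W x_u ; W x_v])``, softmax-normalised over the
    neighborhood including a self-loop, and the output is the attention-
    weighted sum of transformed neighbor features (heads averaged). Trained
    jointly with the main model.
    """

    def __init__(self, kg: KnowledgeGraph, dim: int, feature_dim: int = None,
                 heads: int = 1, radius: int = 1, seed: int = 0):
        feature_dim = feature_dim or dim
        self.kg = kg
        self.dim = dim
        self.heads = heads
        self.radius = radius
        rng = np.random.default_rng(seed)
        n = len(kg.entity_index)
        self.X = ag.parameter(rng, (n, feature_dim), 0.1)
        self.W = [ag.parameter(rng, (dim, feature_dim), 1.0 / np.sqrt(feature_dim))
                  for _ in range(heads)]
        self.a = [ag.parameter(rng, (2 * dim,), 0.3) for _ in range(heads)]
        self._adj: dict[str, set[str]] = {}
        for t in kg.triples:
            self._adj.setdefault(t.head, set()).add(t.tail)
            self._adj.setdefault(t.tail, set()).add(t.head)

    def parameters(self) -> list[Tensor]:
        return [self.X] + self.W + self.a

    def _neighborhood(self, entity_id: str) -> list[str]:
        frontier, seen = {entity_id}, {entity_id}
        for _ in range(self.radius):
            frontier = {n for e in frontier for n in self._adj.get(e, ())} - seen
            seen |= frontier
        return sorted(seen)

    def embed(self, entity_id: str) -> Tensor:
        if entity_id not in self.kg.entity_index:
            raise KeyError(f"unknown entity {entity_id!r}")
        hood = self._neighborhood(entity_id)
        idx = np.array([self.kg.entity_index[e] for e in hood])
        center = hood.index(entity_id)
        feats = self.X[idx]                                  # (n_hood, f)
        outs = []
        for W, a in zip(self.W, self.a):
            Wx = feats @ W.transpose()                       # (n_hood, dim)
            pair = ag.cat([ag.stack([Wx[center]] * len(hood), axis=0), Wx], axis=1)
            logits = (pair @ a).leaky_relu(0.2)
            att = ag.softmax(logits, axis=0)
            outs.append(att @ Wx)
        out = outs[0]
        for o in outs[1:]:
            out = out + o
        return out * (1.0 / self.heads)


def gat_embed(kg: KnowledgeGraph, entity_id: str, radius: int = 1,
              params: GATEncoder | None = None, dim: int = 8,
              seed: int = 0) -> np.ndarray:
    """Convenience wrapper: embed one entity with a (possibly fresh) GAT."""
    enc = params or GATEncoder(kg, dim=dim, radius=radius, seed=seed)
    return enc.embed(entity_id).data


# -- description embeddings ---------------------------------------------------

def read_descriptions_tsv(path: str | Path) -> dict[str, str]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        eid, text = line.split("\t", 1)
        out[eid] = text
    return out


def embed_description_doc2vec(descriptions: dict[str, str], dim: int = 8,
                              epochs: int = 40, seed: int = 0, window: int = 2,
                              lr: float = 0.1) -> dict[str, np.ndarray]:
    """Simplified distributed-memory paragraph vectors.

    Each entity's description owns a paragraph vector; every token is
    predicted by softmax regression from the mean of the paragraph vector
    and the window of surrounding word vectors. Paragraph and word vectors
    are trained jointly by SGD; the paragraph vectors are returned.
    """
    ids = sorted(descriptions)
    docs = {e: descriptions[e].split() for e in ids}
    for e, toks in docs.items():
        if not toks:
            raise ValueError(f"empty description for entity {e!r}")
    vocab = sorted({t for toks in docs.values() for t in toks})
    w_index = {w: i for i, w in enumerate(vocab)}
    rng = np.random.default_rng(seed)
    D = rng.uniform(-0.5, 0.5, size=(len(ids), dim)) / dim
    Wv = rng.uniform(-0.5, 0.5, size=(len(vocab), dim)) / dim
    U = np.zeros((len(vocab), dim))

    for epoch in range(epochs):
        order = rng.permutation(len(ids))
        for di in order:
            toks = docs[ids[di]]
            for pos, tok in enumerate(toks):
                ctx = [w_index[toks[j]]
                       for j in range(max(0, pos - window),
                                      min(len(toks), pos + window + 1)) if j != pos]
                parts = [D[di]] + [Wv[c] for c in ctx]
                mean = np.mean(parts, axis=0)
                logits = U @ mean
                logits -= logits.max()
                p = np.exp(logits)
                p /= p.sum()
                p[w_index[tok]] -= 1.0
                gmean = U.T @ p / len(parts)
                U -= lr * np.outer(p, mean)
                D[di] -= lr * gmean
                for c in ctx:
                    Wv[c] -= lr * gmean
    return {e: D[i].copy() for i, e in enumerate(ids)}


class DescriptionEncoder:
    """End-to-end description encoder (EMB): embed -> BiRNN -> mean pooling.

    Gradients flow into both the description word embeddings and the
    recurrent weights when trained jointly with the main model.
    """

    def __init__(self, descriptions: dict[str, str], dim: int = 8,
                 embed_dim: int = 8, seed: int = 0):
        from .encoder import EmbeddingTable, SentenceEncoder
        self.descriptions = {e: d.split() for e, d in descriptions.items()}
        tokens = {t for toks in self.descriptions.values() for t in toks}
        self.table = EmbeddingTable.build(tokens, embed_dim, seed)
        self.rnn = SentenceEncoder(embed_dim, dim, seed + 1)
        self.dim = dim

    def parameters(self) -> list[Tensor]:
        return [self.table.vectors] + self.rnn.parameters()

    def embed_tokens(self, tokens: list[str]) -> Tensor:
        if not tokens:
            raise ValueError("cannot embed an empty description")
        H = self.rnn.encode_tokens(tokens, self.table)
        return H.mean(axis=0)

    def embed(self, entity_id: str) -> Tensor:
        return self.embed_tokens(self.descriptions[entity_id])


# -- embedding cache ----------------------------------------------------------

def write_embedding_cache(vectors: dict[str, np.ndarray], path: str | Path) -> None:
    items = sorted(vectors.items())
    dim = items[0][1].shape[0] if items else 0
    lines = [f"{len(items)} {dim}"]
    for eid, vec in items:
        lines.append(eid + " " + " ".join(f"{x:.8g}" for x in vec))
    Path(path).write_text("\n".join(lines) + "\n")


def read_embedding_cache(path: str | Path) -> dict[str, np.ndarray]:
    from .encoder import read_word2vec_text
    return read_word2vec_text(path)
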
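"""Typed document graph: nodes, edges, and the initial edge tensor.

Node kinds follow the document hierarchy — mention (M), entity (E),
sentence (S), chapter (C), document (D) — plus two external-knowledge kinds:
KS (from a knowledge-graph embedding) and KD (from an entity-description
embedding). Every node representation is the concatenation of a content
vector (averaged token/sub-node encodings, or the knowledge vector) with a
learnable node-type embedding.

Edge kinds and their raw representations:

=====  ==========================================================
MS     [n_m ; n_s]                mention in sentence
MM     [n_m1 ; n_m2 ; c ; d_m]    co-sentential mentions, attention
                                  context c and bucketed token distance
ME     [n_m ; n_e]                mention of entity
SS     [n_si ; n_sj ; d_s ; |n_si - n_sj|]   every sentence pair
ES     [n_e ; n_s]                entity mentioned in sentence
SC     [n_s ; n_c]                sentence in chapter
CC     [n_c1 ; n_c2]              every chapter pair
CD     [n_d ; n_c]                chapter in document
EKS    [n_e ; n_ks]               entity to knowledge-graph node
EKD    [n_e ; n_kd]               entity to description node
=====  ==========================================================

All raw representations are mapped by per-type learnable matrices W_z into
a common dimension d_z, and scattered into a symmetric node-pair tensor
V^(1); pairs with no edge hold the zero vector.

Graphs are per-document and undirected; they never connect across documents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .corpus_io import Document

NODE_KINDS = ("M", "E", "S", "C", "D", "KS", "KD")
EDGE_TYPES = ("MS", "MM", "ME", "SS", "ES", "SC", "CC", "CD", "EKS", "EKD")

__all__ = [
    "NODE_KINDS", "EDGE_TYPES", "Node", "Edge", "DocumentGraph", "GraphParams",
    "EdgeTransforms", "distance_bucket", "build_graph", "mm_attention",
    "attach_knowledge_nodes", "transform_edges", "graph_to_json",
]


def distance_bucket(d: int, n_buckets: int = 6) -> int:
    """Power-of-two distance bucketing: 0, 1, 2-3, 4-7, 8-15, 16+."""
    if d <= 0:
        return 0
    return min(int(np.log2(d)) + 1, n_buckets - 1)


@dataclass
class Node:
    kind: str
    ref: object                 # mention index / entity id / sentence index / ...
    content: Tensor
    rep: Tensor


@dataclass
class Edge:
    type: str
    i: int
    j: int
    raw: Tensor


class GraphParams:
    """Learnable pieces of graph construction: node-type embeddings, the two
    bucketed-distance tables, and the projection used by mention-pair
    attention scoring."""

    def __init__(self, hidden_dim: int, type_dim: int, dist_dim: int,
                 seed: int, n_buckets: int = 6):
        rng = np.random.default_rng(seed)
        self.type_dim = type_dim
        self.dist_dim = dist_dim
        self.n_buckets = n_buckets
        self.type_embeds = ag.parameter(rng, (len(NODE_KINDS), type_dim), 0.1)
        self.mention_dist = ag.parameter(rng, (n_buckets, dist_dim), 0.1)
        self.sentence_dist = ag.parameter(rng, (n_buckets, dist_dim), 0.1)
        self.attn_proj = ag.parameter(rng, (hidden_dim, hidden_dim),
                                      1.0 / np.sqrt(hidden_dim))
        self._kind_row = {k: i for i, k in enumerate(NODE_KINDS)}

    def parameters(self) -> list[Tensor]:
        return [self.type_embeds, self.mention_dist, self.sentence_dist,
                self.attn_proj]

    def type_embed(self, kind: str) -> Tensor:
        return self.type_embeds[self._kind_row[kind]]


@dataclass
class DocumentGraph:
    doc: Document
    nodes: list[Node] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)
    mention_node: dict[int, int] = field(default_factory=dict)
    entity_node: dict[str, int] = field(default_factory=dict)
    sentence_node: dict[int, int] = field(default_factory=dict)
    chapter_node: dict[int, int] = field(default_factory=dict)
    doc_node: int = -1
    ks_node: dict[str, int] = field(default_factory=dict)
    kd_node: dict[str, int] = field(default_factory=dict)

    def add_node(self, node: Node) -> int:
        self.nodes.append(node)
        return len(self.nodes) - 1

    def n_nodes(self) -> int:
        return len(self.nodes)

    def edge_counts(self) -> dict[str, int]:
        counts = {t: 0 for t in EDGE_TYPES}
        for e in self.edges:
            counts[e.type] += 1
        return counts


def _avg(rows: list[Tensor]) -> Tensor:
    out = rows[0]
    for r in rows[1:]:
        out = out + r
    return out * (1.0 / len(rows))


def _mention_token_indices(doc: Document, mi: int) -> list[int]:
    m = doc.mentions[mi]
    sent = doc.sentences[m.sentence_index]
    idx = [ti for ti, (a, b) in enumerate(sent.token_spans)
           if a < m.span.end and m.span.start < b]
    if not idx:
        raise ValueError(f"mention {m.surface!r} covers no tokens")
    return idx


def build_nodes(doc: Document, encodings: list[Tensor],
                params: GraphParams) -> DocumentGraph:
    """Construct M/E/S/C/D nodes; contents are averages of what they contain
    (tokens for M and S, mentions for E, sentences for C, chapters for D)."""
    g = DocumentGraph(doc)
    for mi in range(len(doc.mentions)):
        m = doc.mentions[mi]
        H = encodings[m.sentence_index]
        content = _avg([H[t] for t in _mention_token_indices(doc, mi)])
        g.mention_node[mi] = g.add_node(
            Node("M", mi, content, ag.cat([content, params.type_embed("M")])))
    for ent in doc.entities:
        contents = [g.nodes[g.mention_node[mi]].content
                    for mi, m in enumerate(doc.mentions) if m.entity_id == ent.entity_id]
        content = _avg(contents)
        g.entity_node[ent.entity_id] = g.add_node(
            Node("E", ent.entity_id, content,
                 ag.cat([content, params.type_embed("E")])))
    for si, H in enumerate(encodings):
        content = H.mean(axis=0)
        g.sentence_node[si] = g.add_node(
            Node("S", si, content, ag.cat([content, params.type_embed("S")])))
    for ci, (a, b) in enumerate(doc.chapters):
        content = _avg([g.nodes[g.sentence_node[si]].content for si in range(a, b)])
        g.chapter_node[ci] = g.add_node(
            Node("C", ci, content, ag.cat([content, params.type_embed("C")])))
    content = _avg([g.nodes[g.chapter_node[ci]].content
                    for ci in range(len(doc.chapters))])
    g.doc_node = g.add_node(
        Node("D", doc.doc_id, content, ag.cat([content, params.type_embed("D")])))
    return g


def mm_attention(m1_content: Tensor, m2_content: Tensor, H: Tensor,
                 m1_tokens: list[int], m2_tokens: list[int],
                 proj: Tensor) -> Tensor:
    """Attention context vector for a co-sentential mention pair.

    Each mention scores every token of the sentence (through a projection of
    its content vector), its own tokens are excluded from the softmax
    support, and the two normalised weight vectors are averaged before the
    weighted sum of token encodings is taken.
    """
    n = H.shape[0]
    weights = []
    for content, own in ((m1_content, m1_tokens), (m2_content, m2_tokens)):
        logits = H @ (proj @ content)
        mask = np.zeros(n)
        mask[own] = -1e30
        masked = logits + Tensor(mask)
        support = n - len(set(own))
        if support <= 0:
            weights.append(Tensor(np.zeros(n)))
        else:
            weights.append(ag.softmax(masked, axis=0))
    a = (weights[0] + weights[1]) * 0.5
    return a @ H


def build_edges(g: DocumentGraph, encodings: list[Tensor],
                params: GraphParams) -> DocumentGraph:
    doc = g.doc
    rep = lambda idx: g.nodes[idx].rep
    # MS, ME
    for mi, m in enumerate(doc.mentions):
        mn = g.mention_node[mi]
        g.edges.append(Edge("MS", mn, g.sentence_node[m.sentence_index],
                            ag.cat([rep(mn), rep(g.sentence_node[m.sentence_index])])))
        en = g.entity_node[m.entity_id]
        g.edges.append(Edge("ME", mn, en, ag.cat([rep(mn), rep(en)])))
    # MM with attention context and mention-distance embedding
    by_sentence: dict[int, list[int]] = {}
    for mi, m in enumerate(doc.mentions):
        by_sentence.setdefault(m.sentence_index, []).append(mi)
    for si, mids in by_sentence.items():
        H = encodings[si]
        tok_cache = {mi: _mention_token_indices(doc, mi) for mi in mids}
        for x in range(len(mids)):
            for y in range(x + 1, len(mids)):
                mi, mj = mids[x], mids[y]
                ni, nj = g.mention_node[mi], g.mention_node[mj]
                c = mm_attention(g.nodes[ni].content, g.nodes[nj].content, H,
                                 tok_cache[mi], tok_cache[mj], params.attn_proj)
                dist = abs(tok_cache[mi][0] - tok_cache[mj][0])
                demb = params.mention_dist[distance_bucket(dist, params.n_buckets)]
                g.edges.append(Edge("MM", ni, nj,
                                    ag.cat([rep(ni), rep(nj), c, demb])))
    # SS: complete graph over sentences
    n_s = len(doc.sentences)
    for i in range(n_s):
        for j in range(i + 1, n_s):
            ni, nj = g.sentence_node[i], g.sentence_node[j]
            demb = params.sentence_dist[distance_bucket(j - i, params.n_buckets)]
            g.edges.append(Edge("SS", ni, nj,
                                ag.cat([rep(ni), rep(nj), demb,
                                        (rep(ni) - rep(nj)).abs()])))
    # ES: entity mentioned in sentence
    seen_es = set()
    for m in doc.mentions:
        key = (m.entity_id, m.sentence_index)
        if key in seen_es:
            continue
        seen_es.add(key)
        en, sn = g.entity_node[m.entity_id], g.sentence_node[m.sentence_index]
        g.edges.append(Edge("ES", en, sn, ag.cat([rep(en), rep(sn)])))
    # SC: sentence in chapter
    for ci, (a, b) in enumerate(doc.chapters):
        for si in range(a, b):
            g.edges.append(Edge("SC", g.sentence_node[si], g.chapter_node[ci],
                                ag.cat([rep(g.sentence_node[si]),
                                        rep(g.chapter_node[ci])])))
    # CC: every chapter pair
    n_c = len(doc.chapters)
    for i in range(n_c):
        for j in range(i + 1, n_c):
            ni, nj = g.chapter_node[i], g.chapter_node[j]
            g.edges.append(Edge("CC", ni, nj, ag.cat([rep(ni), rep(nj)])))
    # CD: chapter to document
    for ci in range(n_c):
        g.edges.append(Edge("CD", g.doc_node, g.chapter_node[ci],
                            ag.cat([rep(g.doc_node), rep(g.chapter_node[ci])])))
    return g


def build_graph(doc: Document, encodings: list[Tensor],
                params: GraphParams) -> DocumentGraph:
    g = build_nodes(doc, encodings, params)
    return build_edges(g, encodings, params)


def attach_knowledge_nodes(g: DocumentGraph,
                           ks_vectors: dict[str, Tensor] | None,
                           kd_vectors: dict[str, Tensor] | None,
                           params: GraphParams) -> DocumentGraph:
    """Add one KS node per entity found in the knowledge-graph embeddings and
    one KD node per entity found in the description embeddings, each wired to
    its entity node; entities absent from a source get no node from it."""
    for eid, en in g.entity_node.items():
        if ks_vectors is not None and eid in ks_vectors:
            content = ks_vectors[eid]
            idx = g.add_node(Node("KS", eid, content,
                                  ag.cat([content, params.type_embed("KS")])))
            g.ks_node[eid] = idx
            g.edges.append(Edge("EKS", en, idx,
                                ag.cat([g.nodes[en].rep, g.nodes[idx].rep])))
        if kd_vectors is not None and eid in kd_vectors:
            content = kd_vectors[eid]
            idx = g.add_node(Node("KD", eid, content,
                                  ag.cat([content, params.type_embed("KD")])))
            g.kd_node[eid] = idx
            g.edges.append(Edge("EKD", en, idx,
                                ag.cat([g.nodes[en].rep, g.nodes[idx].rep])))
    return g


class EdgeTransforms:
    """One learnable matrix W_z per edge type, mapping the type's raw
    concatenation to the common edge dimension d_z."""

    def __init__(self, raw_dims: dict[str, int], d_z: int, seed: int):
        rng = np.random.default_rng(seed)
        self.d_z = d_z
        self.W = {z: ag.parameter(rng, (d_z, dim), 1.0 / np.sqrt(dim))
                  for z, dim in raw_dims.items()}

    @classmethod
    def for_dims(cls, hidden_dim: int, type_dim: int, dist_dim: int,
                 d_z: int, seed: int, ks_dim: int | None = None,
                 kd_dim: int | None = None) -> "EdgeTransforms":
        q = hidden_dim + type_dim
        raw = {"MS": 2 * q, "ME": 2 * q, "ES": 2 * q, "SC": 2 * q,
               "CC": 2 * q, "CD": 2 * q,
               "MM": 2 * q + hidden_dim + dist_dim,
               "SS": 3 * q + dist_dim}
        if ks_dim is not None:
            raw["EKS"] = q + ks_dim + type_dim
        if kd_dim is not None:
            raw["EKD"] = q + kd_dim + type_dim
        return cls(raw, d_z, seed)

    def parameters(self) -> list[Tensor]:
        return [self.W[z] for z in sorted(self.W)]


def transform_edges(g: DocumentGraph, transforms: EdgeTransforms) -> Tensor:
    """Map every edge through its type's W_z and scatter into the symmetric
    initial edge tensor V^(1) of shape (n_nodes, n_nodes, d_z)."""
    n = g.n_nodes()
    present = {e.type for e in g.edges}
    missing = present - set(transforms.W)
    if missing:
        raise KeyError(f"no transform for edge types {sorted(missing)}")
    if not g.edges:
        return Tensor(np.zeros((n, n, transforms.d_z)))
    chunks, rows, cols = [], [], []
    for z in sorted(present):
        group = [e for e in g.edges if e.type == z]
        raw = ag.stack([e.raw for e in group], axis=0)
        chunks.append(raw @ transforms.W[z].transpose())
        rows.extend(e.i for e in group)
        cols.extend(e.j for e in group)
    values = ag.cat(chunks, axis=0)
    return ag.scatter_pairs(values, np.array(rows), np.array(cols), n)


def graph_to_json(g: DocumentGraph, path: str | Path | None = None) -> dict:
    """Dump graph structure (not parameters) for inspection and testing."""
    payload = {
        "doc_id": g.doc.doc_id,
        "nodes": [{"kind": n.kind, "ref": n.ref} for n in g.nodes],
        "edges": [{"type": e.type, "endpoints": [e.i, e.j]} for e in g.edges],
    }
    if path is not None:
        Path(path).write_text(json.dumps(payload, indent=1))
    return payload
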
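"""Document graph construction: node formulas, edge combinatorics, attention."""

from math import comb

import numpy as np
import pytest

from skeog import autograd as ag
from skeog.autograd import Tensor
from skeog.corpus_io import read_pubtator
from skeog.doc_graph import (EdgeTransforms, GraphParams, attach_knowledge_nodes,
                             build_graph, build_nodes, distance_bucket,
                             graph_to_json, mm_attention, transform_edges)
from skeog.encoder import EmbeddingTable, SentenceEncoder

HID, TYP, DST = 8, 3, 3


@pytest.fixture
def params():
    return GraphParams(HID, TYP, DST, seed=0)


def encode(corpus, doc):
    table = EmbeddingTable.from_corpus(corpus, 6, seed=0)
    enc = SentenceEncoder(6, HID, seed=1)
    return [enc.encode_tokens(s.tokens, table) for s in doc.sentences]


def corpus_from(tmp_path, text):
    path = tmp_path / "g.pubtator"
    path.write_text(text)
    return read_pubtator(path)


class TestBuildNodes:
    def test_minimal_document_five_nodes(self, tmp_path, params):
        corpus = corpus_from(tmp_path, "1|t|Aspirin\n1|a|\n"
                                       "1\t0\t7\tAspirin\tChemical\tC1\n")
        doc = corpus.documents[0]
        assert len(doc.sentences) == 1 and len(doc.sentences[0].tokens) == 1
        enc = encode(corpus, doc)
        g = build_nodes(doc, enc, params)
        assert [n.kind for n in g.nodes] == ["M", "E", "S", "C", "D"]
        token_vec = enc[0].data[0]
        np.testing.assert_allclose(g.nodes[0].content.data, token_vec)
        np.testing.assert_allclose(g.nodes[2].content.data, token_vec)

    def test_entity_content_is_mention_average(self, tmp_path, params):
        corpus = corpus_from(tmp_path, "1|t|Aspirin.\n1|a|Aspirin.\n"
                                       "1\t0\t7\tAspirin\tChemical\tC1\n"
                                       "1\t9\t16\tAspirin\tChemical\tC1\n")
        doc = corpus.documents[0]
        g = build_nodes(doc, encode(corpus, doc), params)
        m_contents = [n.content.data for n in g.nodes if n.kind == "M"]
        e_content = next(n.content.data for n in g.nodes if n.kind == "E")
        np.testing.assert_allclose(m_contents[0], m_contents[1], atol=1e-12)
        np.testing.assert_allclose(e_content, m_contents[0], atol=1e-12)

    def test_document_content_is_mean_of_chapters(self, tmp_path, params):
        corpus = corpus_from(tmp_path, "1|t|Alpha beta.\n1|a|Gamma delta. Extra one.\n")
        doc = corpus.documents[0]
        g = build_nodes(doc, encode(corpus, doc), params)
        c_contents = [n.content.data for n in g.nodes if n.kind == "C"]
        d_content = next(n.content.data for n in g.nodes if n.kind == "D")
        np.testing.assert_allclose(d_content,
                                   np.mean(c_contents, axis=0), atol=1e-12)

    def test_node_count_formula(self, benchmark, params):
        corpus = benchmark["corpus"]
        table = EmbeddingTable.from_corpus(corpus, 6, seed=0)
        enc = SentenceEncoder(6, HID, seed=1)
        for doc in corpus.documents[:5]:
            encs = [enc.encode_tokens(s.tokens, table) for s in doc.sentences]
            g = build_nodes(doc, encs, params)
            want = (len(doc.mentions) + len(doc.entities) + len(doc.sentences)
                    + len(doc.chapters) + 1)
            assert g.n_nodes() == want


class TestMMAttention:
    def test_uniform_when_all_logits_equal(self, params):
        H = Tensor(np.tile(np.arange(HID, dtype=float), (5, 1)))  # equal rows
        c1 = Tensor(np.ones(HID))
        a_weights_support = 5 - 1
        c = mm_attention(c1, c1, H, [0], [0], params.attn_proj)
        np.testing.assert_allclose(c.data, H.data[1], atol=1e-10)

    def test_weights_sum_to_one_over_support(self, params, rng):
        for _ in range(50):
            n = int(rng.integers(3, 9))
            H = Tensor(rng.normal(size=(n, HID)))
            m1, m2 = [0], [1]
            logits1 = H.data @ (params.attn_proj.data @ rng.normal(size=HID))
            c = mm_attention(Tensor(rng.normal(size=HID)),
                             Tensor(rng.normal(size=HID)), H, m1, m2,
                             params.attn_proj)
            assert c.shape == (HID,)

    def test_hand_computed_four_token_sentence(self, params, rng):
        H = rng.normal(size=(4, HID))
        c1, c2 = rng.normal(size=HID), rng.normal(size=HID)
        got = mm_attention(Tensor(c1), Tensor(c2), Tensor(H), [0], [2],
                           params.attn_proj).data
        P = params.attn_proj.data
        a = np.zeros(4)
        for content, own in ((c1, 0), (c2, 2)):
            logits = H @ (P @ content)
            keep = [i for i in range(4) if i != own]
            w = np.exp(logits[keep] - logits[keep].max())
            w /= w.sum()
            full = np.zeros(4)
            full[keep] = w
            a += 0.5 * full
        np.testing.assert_allclose(got, a @ H, atol=1e-10)


def expected_edge_counts(doc):
    """Brute-force recount of every edge type from the document object."""
    per_sent = {}
    for m in doc.mentions:
        per_sent.setdefault(m.sentence_index, []).append(m)
    mm = sum(comb(len(v), 2) for v in per_sent.values())
    es = len({(m.entity_id, m.sentence_index) for m in doc.mentions})
    n_s, n_c = len(doc.sentences), len(doc.chapters)
    return {"MS": len(doc.mentions), "ME": len(doc.mentions), "MM": mm,
            "SS": comb(n_s, 2), "ES": es, "SC": n_s, "CC": comb(n_c, 2),
            "CD": n_c, "EKS": 0, "EKD": 0}


class TestBuildEdges:
    def test_three_sentence_one_chapter_counts(self, tmp_path, params):
        corpus = corpus_from(tmp_path, "1|t|Alpha one.\n1|a|Beta two. Gamma three.\n")
        doc = corpus.documents[0]
        doc.chapters = [(0, 3)]  # collapse to a single chapter
        g = build_graph(doc, encode(corpus, doc), params)
        counts = g.edge_counts()
        assert counts["SS"] == 3 and counts["SC"] == 3
        assert counts["CD"] == 1 and counts["CC"] == 0

    def test_single_mention_document(self, tmp_path, params):
        corpus = corpus_from(tmp_path, "1|t|Aspirin helps.\n1|a|Yes indeed.\n"
                                       "1\t0\t7\tAspirin\tChemical\tC1\n")
        doc = corpus.documents[0]
        counts = build_graph(doc, encode(corpus, doc), params).edge_counts()
        assert (counts["MS"], counts["ME"], counts["ES"], counts["MM"]) == (1, 1, 1, 0)

    def test_counts_match_brute_force_recount(self, benchmark, params):
        corpus = benchmark["corpus"]
        table = EmbeddingTable.from_corpus(corpus, 6, seed=0)
        enc = SentenceEncoder(6, HID, seed=1)
        for doc in corpus.documents[:5]:
            encs = [enc.encode_tokens(s.tokens, table) for s in doc.sentences]
            g = build_graph(doc, encs, params)
            assert g.edge_counts() == expected_edge_counts(doc)

    def test_collapsing_chapters_degenerates_gracefully(self, tmp_path, params):
        corpus = corpus_from(tmp_path, "1|t|Alpha one.\n1|a|Beta two. Gamma three.\n")
        doc = corpus.documents[0]
        two = build_graph(doc, encode(corpus, doc), params).edge_counts()
        assert two["CC"] == 1 and two["CD"] == 2
        doc.chapters = [(0, len(doc.sentences))]
        one = build_graph(doc, encode(corpus, doc), params).edge_counts()
        # single-chapter layout: the original edge-oriented structure plus a
        # degenerate chapter and document node
        assert one["CC"] == 0 and one["CD"] == 1
        assert one["SS"] == two["SS"] and one["MS"] == two["MS"]


class TestKnowledgeAttachment:
    def fig4_graph(self, tmp_path, params):
        text = ("1|t|E1a with E2a.\n1|a|Then E3a appears.\n"
                "1\t0\t3\tE1a\tChemical\te1\n"
                "1\t9\t12\tE2a\tChemical\te2\n"
                "1\t19\t22\tE3a\tChemical\te3\n")
        corpus = corpus_from(tmp_path, text)
        doc = corpus.documents[0]
        return build_graph(doc, encode(corpus, doc), params)

    def test_fig4_layout_counts(self, tmp_path, params):
        # e1, e2, e3 have descriptions; only e1 and e3 are in the KG
        g = self.fig4_graph(tmp_path, params)
        kd = {e: Tensor(np.ones(4)) for e in ("e1", "e2", "e3")}
        ks = {e: Tensor(np.ones(5)) for e in ("e1", "e3")}
        attach_knowledge_nodes(g, ks, kd, params)
        kinds = [n.kind for n in g.nodes]
        assert kinds.count("KD") == 3 and kinds.count("KS") == 2
        counts = g.edge_counts()
        assert counts["EKD"] == 3 and counts["EKS"] == 2

    def test_entity_in_both_sources_gains_two_nodes(self, tmp_path, params):
        g = self.fig4_graph(tmp_path, params)
        n_before = g.n_nodes()
        attach_knowledge_nodes(g, {"e1": Tensor(np.ones(5))},
                               {"e1": Tensor(np.ones(4))}, params)
        assert g.n_nodes() == n_before + 2

    def test_entity_in_neither_source_unchanged(self, tmp_path, params):
        g = self.fig4_graph(tmp_path, params)
        n_before, e_before = g.n_nodes(), len(g.edges)
        attach_knowledge_nodes(g, {"zzz": Tensor(np.ones(5))}, None, params)
        assert g.n_nodes() == n_before and len(g.edges) == e_before


class TestTransformEdges:
    def graph(self, tmp_path, params):
        corpus = corpus_from(tmp_path, "1|t|Aspirin helps.\n1|a|Good.\n"
                                       "1\t0\t7\tAspirin\tChemical\tC1\n")
        doc = corpus.documents[0]
        return build_graph(doc, encode(corpus, doc), params)

    def transforms(self, d_z=4):
        return EdgeTransforms.for_dims(HID, TYP, DST, d_z, seed=0,
                                       ks_dim=5, kd_dim=4)

    def test_zero_transforms_give_zero_tensor(self, tmp_path, params):
        g = self.graph(tmp_path, params)
        tr = self.transforms()
        for W in tr.W.values():
            W.data[:] = 0.0
        V = transform_edges(g, tr)
        np.testing.assert_array_equal(V.data, 0.0)

    def test_uniform_dimension_and_symmetry(self, tmp_path, params):
        g = self.graph(tmp_path, params)
        V = transform_edges(g, self.transforms(d_z=6))
        assert V.shape == (g.n_nodes(), g.n_nodes(), 6)
        np.testing.assert_allclose(V.data, V.data.transpose(1, 0, 2))

    def test_single_edge_single_nonzero_pair(self, params):
        from skeog.doc_graph import DocumentGraph, Edge, Node
        from skeog.corpus_io import Document
        doc = Document(doc_id="x", text="t", title_end=1)
        g = DocumentGraph(doc)
        raw = Tensor(np.arange(4.0))
        g.nodes = [Node("S", 0, raw, raw), Node("S", 1, raw, raw),
                   Node("S", 2, raw, raw)]
        g.edges = [Edge("SC", 0, 1, raw)]
        tr = EdgeTransforms({"SC": 4}, d_z=4, seed=0)
        V = transform_edges(g, tr).data
        nonzero = {(i, j) for i in range(3) for j in range(3)
                   if np.abs(V[i, j]).sum() > 0}
        assert nonzero == {(0, 1), (1, 0)}
        np.testing.assert_allclose(V[0, 1], tr.W["SC"].data @ raw.data)

    def test_identity_like_transform_preserves_raw_prefix(self, params):
        from skeog.doc_graph import DocumentGraph, Edge, Node
        from skeog.corpus_io import Document
        doc = Document(doc_id="x", text="t", title_end=1)
        g = DocumentGraph(doc)
        raw = Tensor(np.array([1.0, 2.0, 3.0, 4.0]))
        g.nodes = [Node("S", 0, raw, raw), Node("S", 1, raw, raw)]
        g.edges = [Edge("SC", 0, 1, raw)]
        tr = EdgeTransforms({"SC": 4}, d_z=2, seed=0)
        tr.W["SC"].data = np.eye(4)[:2]
        V = transform_edges(g, tr).data
        np.testing.assert_allclose(V[0, 1], raw.data[:2])

    def test_missing_transform_rejected(self, tmp_path, params):
        g = self.graph(tmp_path, params)
        tr = EdgeTransforms({"SC": 2 * (HID + TYP)}, d_z=4, seed=0)
        with pytest.raises(KeyError):
            transform_edges(g, tr)


def test_distance_buckets_clamp():
    assert distance_bucket(0) == 0
    assert distance_bucket(1) == 1
    assert distance_bucket(3) == 2
    assert distance_bucket(1000) == 5


def test_graph_json_dump(tmp_path, params):
    corpus = corpus_from(tmp_path, "1|t|Aspirin helps.\n1|a|Good.\n"
                                   "1\t0\t7\tAspirin\tChemical\tC1\n")
    doc = corpus.documents[0]
    g = build_graph(doc, encode(corpus, doc), params)
    payload = graph_to_json(g, tmp_path / "g.json")
    assert (tmp_path / "g.json").exists()
    assert len(payload["nodes"]) == g.n_nodes()
    assert all(set(e) == {"type", "endpoints"} for e in payload["edges"])
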
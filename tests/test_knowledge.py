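"""Knowledge-node providers: TransE, RESCAL, GAT, Doc2vec, EMB."""

import numpy as np
import pytest

from skeog.autograd import Tensor
from skeog.knowledge import (DescriptionEncoder, GATEncoder, KnowledgeGraph,
                             Triple, embed_description_doc2vec,
                             factorize_rescal, read_embedding_cache,
                             rescal_score, train_transe, transe_margin_loss,
                             transe_score, write_embedding_cache)


def toy_kg(rng, n_entities=20, n_relations=2, n_triples=40):
    ents = [f"E{i}" for i in range(n_entities)]
    rels = [f"R{i}" for i in range(n_relations)]
    seen, triples = set(), []
    while len(triples) < n_triples:
        h, t = rng.choice(n_entities, size=2, replace=False)
        r = int(rng.integers(0, n_relations))
        key = (h, r, t)
        if key not in seen:
            seen.add(key)
            triples.append(Triple(ents[h], rels[r], ents[t]))
    return KnowledgeGraph(triples)


class TestTransE:
    def test_exact_translation_scores_zero(self):
        h, r = np.array([1.0, 2.0]), np.array([0.5, -1.0])
        assert transe_score(h, r, h + r) == 0.0

    def test_unit_distance(self):
        assert transe_score(np.array([1.0, 0.0]), np.zeros(2),
                            np.zeros(2)) == 1.0

    def test_dim_mismatch(self):
        with pytest.raises(ValueError):
            transe_score(np.zeros(2), np.zeros(3), np.zeros(2))

    def test_chained_relations_compose_additively(self):
        # two exact triples h1 -r1-> t1 -r2-> t2 give h1 + r1 + r2 = t2
        h1 = np.array([0.0, 1.0])
        r1, r2 = np.array([1.0, 0.0]), np.array([0.0, 2.0])
        t1, t2 = h1 + r1, h1 + r1 + r2
        assert transe_score(h1, r1 + r2, t2) == 0.0
        assert transe_score(t1, r2, t2) == 0.0

    def test_margin_separates_true_from_corrupted(self, rng):
        kg = toy_kg(rng)
        emb = train_transe(kg, dim=8, epochs=150, seed=3)
        truth = {(t.head, t.relation, t.tail) for t in kg.triples}
        ents = sorted(kg.entity_index)
        true_scores, corrupt_scores = [], []
        for t in kg.triples:
            true_scores.append(transe_score(emb.entity_vectors[t.head],
                                            emb.relation_vectors[t.relation],
                                            emb.entity_vectors[t.tail]))
            while True:
                cand = ents[int(rng.integers(0, len(ents)))]
                if (cand, t.relation, t.tail) not in truth:
                    break
            corrupt_scores.append(transe_score(emb.entity_vectors[cand],
                                               emb.relation_vectors[t.relation],
                                               emb.entity_vectors[t.tail]))
        assert np.mean(true_scores) < np.mean(corrupt_scores)

    def test_hinge_is_gamma_when_negative_equals_positive(self, rng):
        kg = toy_kg(rng, n_triples=5)
        emb = train_transe(kg, dim=4, epochs=1, seed=0)
        negatives = [(t.head, t.relation, t.tail) for t in kg.triples]
        loss = transe_margin_loss(kg, emb, gamma=1.0, negatives=negatives)
        assert abs(loss - len(kg.triples) * 1.0) < 1e-12

    def test_zero_loss_when_pre_satisfied_and_zero_margin(self, rng):
        # chain KG whose embeddings satisfy h + r = t for every triple
        kg = KnowledgeGraph([Triple(f"E{i}", "R0", f"E{i+1}") for i in range(5)])
        emb = train_transe(kg, dim=4, epochs=1, seed=0)
        r = rng.normal(size=4)
        emb.relation_vectors["R0"] = r
        for i in range(6):
            emb.entity_vectors[f"E{i}"] = i * r
        negatives = [("E3", "R0", "E1"), ("E5", "R0", "E0"), ("E2", "R0", "E0"),
                     ("E4", "R0", "E2"), ("E0", "R0", "E3")]
        assert transe_margin_loss(kg, emb, gamma=0.0, negatives=negatives) == 0.0

    def test_empty_kg_rejected(self):
        with pytest.raises(ValueError):
            train_transe(KnowledgeGraph([]))

    def test_deterministic_given_seed(self, rng):
        kg = toy_kg(rng, n_triples=10)
        a = train_transe(kg, dim=4, epochs=5, seed=9).entity_vectors
        b = train_transe(kg, dim=4, epochs=5, seed=9).entity_vectors
        for e in a:
            np.testing.assert_array_equal(a[e], b[e])


class TestRescal:
    def test_identity_relation_is_dot_product(self, rng):
        h, t = rng.normal(size=3), rng.normal(size=3)
        assert abs(rescal_score(h, np.eye(3), t) - h @ t) < 1e-12

    def test_zero_vector_scores_zero(self, rng):
        assert rescal_score(np.zeros(3), rng.normal(size=(3, 3)),
                            rng.normal(size=3)) == 0.0

    def test_matches_double_loop(self, rng):
        h, t = rng.normal(size=3), rng.normal(size=3)
        M = rng.normal(size=(3, 3))
        want = sum(h[i] * M[i, j] * t[j] for i in range(3) for j in range(3))
        assert abs(rescal_score(h, M, t) - want) < 1e-10

    def test_single_triple_full_rank_fits_exactly(self):
        kg = KnowledgeGraph([Triple("a", "r", "b")])
        _, history = factorize_rescal(kg, rank=2, epochs=800, seed=0, lr=0.1)
        assert history[-1] < 1e-4

    def test_loss_monotone_and_reconstruction(self, rng):
        kg = toy_kg(rng, n_entities=8, n_relations=2, n_triples=14)
        emb, history = factorize_rescal(kg, rank=8, epochs=600, seed=1, lr=0.05)
        assert all(b <= a + 1e-12 for a, b in zip(history, history[1:]))
        from skeog.knowledge import build_tensor
        X = build_tensor(kg)
        A = np.stack([emb.entity_vectors[e] for e in sorted(kg.entity_index)])
        correct = total = 0
        for r, k in kg.relation_index.items():
            recon = (A @ emb.relation_matrices[r] @ A.T) > 0.5
            correct += (recon == (X[:, :, k] > 0.5)).sum()
            total += X[:, :, k].size
        assert correct / total >= 0.9

    def test_invalid_rank_rejected(self, rng):
        kg = toy_kg(rng, n_entities=4, n_triples=5)
        with pytest.raises(ValueError):
            factorize_rescal(kg, rank=10)


class TestGAT:
    def test_isolated_entity_uses_self_loop_only(self):
        kg = KnowledgeGraph([Triple("iso", "r", "iso"), Triple("a", "r", "b")])
        enc = GATEncoder(kg, dim=4, seed=0)
        out = enc.embed("iso").data
        idx = kg.entity_index["iso"]
        want = enc.W[0].data @ enc.X.data[idx]
        np.testing.assert_allclose(out, want, atol=1e-12)

    def test_uniform_logits_give_neighborhood_mean(self):
        kg = KnowledgeGraph([Triple("c", "r", "n1"), Triple("c", "r", "n2")])
        enc = GATEncoder(kg, dim=3, seed=0)
        enc.a[0].data[:] = 0.0   # all attention logits equal -> uniform
        out = enc.embed("c").data
        hood = sorted(["c", "n1", "n2"])
        Wx = np.stack([enc.W[0].data @ enc.X.data[kg.entity_index[e]]
                       for e in hood])
        np.testing.assert_allclose(out, Wx.mean(axis=0), atol=1e-12)

    def test_hand_computed_star(self):
        kg = KnowledgeGraph([Triple("c", "r", "n1"), Triple("c", "r", "n2")])
        enc = GATEncoder(kg, dim=2, seed=4)
        out = enc.embed("c").data
        hood = sorted(["c", "n1", "n2"])
        center = hood.index("c")
        Wx = np.stack([enc.W[0].data @ enc.X.data[kg.entity_index[e]]
                       for e in hood])
        logits = np.array([np.concatenate([Wx[center], Wx[v]]) @ enc.a[0].data
                           for v in range(3)])
        logits = np.where(logits > 0, logits, 0.2 * logits)
        att = np.exp(logits - logits.max())
        att /= att.sum()
        np.testing.assert_allclose(out, att @ Wx, atol=1e-10)

    def test_unknown_entity_rejected(self):
        kg = KnowledgeGraph([Triple("a", "r", "b")])
        with pytest.raises(KeyError):
            GATEncoder(kg, dim=2, seed=0).embed("zzz")

    def test_gradient_flows_to_features(self):
        kg = KnowledgeGraph([Triple("a", "r", "b")])
        enc = GATEncoder(kg, dim=2, seed=0)
        enc.embed("a").sum().backward()
        assert enc.X.grad is not None and np.abs(enc.X.grad).sum() > 0


class TestDoc2vec:
    DESCS = {f"{cls}{i}": " ".join(f"{cls}tok{j}" for j in (0, 1, 2, i % 4))
             for cls in ("alpha", "beta", "gamma") for i in range(6)}

    def test_dimension_and_determinism(self):
        a = embed_description_doc2vec(self.DESCS, dim=6, epochs=5, seed=2)
        b = embed_description_doc2vec(self.DESCS, dim=6, epochs=5, seed=2)
        assert all(v.shape == (6,) for v in a.values())
        for e in a:
            np.testing.assert_array_equal(a[e], b[e])

    def test_empty_description_rejected(self):
        with pytest.raises(ValueError):
            embed_description_doc2vec({"x": "  "}, dim=4)

    def test_class_structure_recovered(self):
        vecs = embed_description_doc2vec(self.DESCS, dim=8, epochs=60, seed=0)
        ids = sorted(vecs)
        M = np.stack([vecs[e] for e in ids])
        cls = [e.rstrip("0123456789") for e in ids]
        hits = 0
        for i in range(len(ids)):
            d = np.linalg.norm(M - M[i], axis=1)
            d[i] = np.inf
            hits += cls[int(np.argmin(d))] == cls[i]
        purity = hits / len(ids)
        assert purity > 1.0 / 3.0 + 0.15   # clearly above chance


class TestEMB:
    DESCS = {"e1": "potent compound", "e2": "inert compound", "e3": "salt"}

    def test_single_token_pooling_identity(self):
        enc = DescriptionEncoder(self.DESCS, dim=6, embed_dim=4, seed=0)
        H = enc.rnn.encode_tokens(["salt"], enc.table)
        np.testing.assert_allclose(enc.embed("e3").data, H.data[0], atol=1e-12)

    def test_order_sensitivity(self):
        enc = DescriptionEncoder(self.DESCS, dim=6, embed_dim=4, seed=0)
        fwd = enc.embed_tokens(["potent", "compound"]).data
        rev = enc.embed_tokens(["compound", "potent"]).data
        assert not np.allclose(fwd, rev)

    def test_empty_rejected(self):
        enc = DescriptionEncoder(self.DESCS, dim=6, embed_dim=4, seed=0)
        with pytest.raises(ValueError):
            enc.embed_tokens([])

    def test_finite_difference_gradient(self):
        enc = DescriptionEncoder(self.DESCS, dim=4, embed_dim=4, seed=1)
        enc.embed_tokens(["potent", "compound"]).sum().backward()
        grad = enc.table.vectors.grad
        row = enc.table.vocabulary["potent"]
        eps = 1e-6
        base = enc.table.vectors.data.copy()
        def f(v):
            enc.table.vectors.data = v
            out = float(enc.embed_tokens(["potent", "compound"]).sum().data)
            enc.table.vectors.data = base
            return out
        vp, vm = base.copy(), base.copy()
        vp[row, 1] += eps
        vm[row, 1] -= eps
        assert abs(grad[row, 1] - (f(vp) - f(vm)) / (2 * eps)) < 1e-5


def test_embedding_cache_round_trip(tmp_path, rng):
    vecs = {"a": rng.normal(size=4), "b": rng.normal(size=4)}
    path = tmp_path / "cache.txt"
    write_embedding_cache(vecs, path)
    again = read_embedding_cache(path)
    for k in vecs:
        np.testing.assert_allclose(again[k], vecs[k], atol=1e-6)
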
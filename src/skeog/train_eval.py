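"""Model assembly, training orchestration, prediction and evaluation.

The full per-document pipeline is: encode sentences -> build the typed
document graph -> attach external-knowledge nodes -> transform edges into
V^(1) -> walk aggregation to V^(L) -> softmax classification of candidate
entity pairs -> interpolated cross-entropy / soft-F loss.

The evaluation protocol mirrors common practice on the chemical-disease
corpora: train on the training set while monitoring F1 on the development
set, then retrain with the selected setting on train+dev and report test
metrics, split into overall / intra-sentence / inter-sentence rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Adagrad, Tensor
from .corpus_io import (NULL_LABEL, CandidatePair, Corpus, Document, Hierarchy,
                        enumerate_candidate_pairs, hypernym_filter, is_intra)
from .doc_graph import (EdgeTransforms, GraphParams, attach_knowledge_nodes,
                        build_graph, transform_edges)
from .encoder import EmbeddingTable, SentenceEncoder
from .inference import (LossConfig, PairClassifier, WalkParams,
                        aggregate_walks, classify_pairs, total_loss)
from .knowledge import (DescriptionEncoder, GATEncoder, KnowledgeGraph,
                        embed_description_doc2vec, factorize_rescal,
                        train_transe)

__all__ = ["TrainConfig", "Scores", "Metrics", "f_measure", "split_intra_inter",
           "evaluate", "SkeogModel", "train_model", "predict",
           "write_predictions_tsv", "read_predictions_tsv", "run_protocol"]


@dataclass
class TrainConfig:
    seed: int = 0
    epochs: int = 30
    batch_size: int = 1
    lr: float = 0.1
    clip: float = 5.0
    weight_decay: float = 0.0
    embed_dim: int = 16
    hidden_dim: int = 24
    type_dim: int = 6
    dist_dim: int = 6
    d_z: int = 16
    kg_dim: int = 8
    desc_dim: int = 8
    walk_alpha: float = 0.8
    final_length: int = 4
    walk_w_init: float = 0.25    # U(-s, s) init of the walk matrix
    ks_standardize: bool = True  # per-dim standardization of frozen h_ks
    word_dropout: float = 0.0
    mention_dropout: float = 0.0
    lambda_ce: float = 0.7
    soft_f_beta: float = 1e-8
    kg_provider: str = "none"        # none | transe | rescal | gat
    desc_provider: str = "none"      # none | doc2vec | emb
    head_type: str = "Chemical"
    tail_type: str = "Disease"
    encoder_mode: str = "birnn"
    gat_radius: int = 1
    gat_heads: int = 1
    kg_pretrain_epochs: int = 100
    doc2vec_epochs: int = 40
    eval_every: int = 2

    def __post_init__(self):
        if self.kg_provider not in ("none", "transe", "rescal", "gat"):
            raise ValueError(f"unknown kg_provider {self.kg_provider!r}")
        if self.desc_provider not in ("none", "doc2vec", "emb"):
            raise ValueError(f"unknown desc_provider {self.desc_provider!r}")
        for name in ("embed_dim", "hidden_dim", "type_dim", "dist_dim",
                     "d_z", "kg_dim", "desc_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        import yaml
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)


# -- metrics ------------------------------------------------------------------

def f_measure(p: float, r: float) -> float:
    """Harmonic mean of precision and recall (percent scale)."""
    return 2.0 * p * r / (p + r) if (p + r) > 0 else 0.0


@dataclass
class Scores:
    precision: float
    recall: float
    f1: float

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "Scores":
        p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
        r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        return cls(round(p, 10), round(r, 10), f_measure(p, r))


@dataclass
class Metrics:
    overall: Scores
    intra: Scores
    inter: Scores

    def to_dict(self) -> dict:
        return {split: {"P": s.precision, "R": s.recall, "F1": s.f1}
                for split, s in (("overall", self.overall),
                                 ("intra", self.intra), ("inter", self.inter))}


def split_intra_inter(pair: CandidatePair, doc: Document) -> str:
    """"intra" iff some sentence mentions both entities of the pair."""
    return "intra" if is_intra(doc, pair.head, pair.tail) else "inter"


def evaluate(predictions: list[CandidatePair], gold: list[CandidatePair],
             pair_locality: dict[tuple[str, str, str], str]) -> Metrics:
    """Precision/recall/F1 with the non-null label as the positive class,
    overall and restricted to intra-/inter-sentence pairs.

    ``pair_locality`` maps (doc_id, head, tail) to "intra"/"inter" and must
    cover every pair seen in predictions or gold.
    """
    def key(p: CandidatePair):
        return (p.doc_id, p.head, p.tail)

    for p in predictions:
        if key(p) not in pair_locality:
            raise KeyError(f"prediction for unknown pair {key(p)}")
    pred_pos = {key(p): p.label for p in predictions if p.label != NULL_LABEL}
    gold_pos = {key(p): p.label for p in gold if p.label != NULL_LABEL}

    def counts(restrict: str | None) -> Scores:
        keep = (lambda k: restrict is None or pair_locality[k] == restrict)
        pp = {k: v for k, v in pred_pos.items() if keep(k)}
        gp = {k: v for k, v in gold_pos.items() if keep(k)}
        tp = sum(1 for k, v in pp.items() if gp.get(k) == v)
        return Scores.from_counts(tp, len(pp) - tp, len(gp) - tp)

    return Metrics(counts(None), counts("intra"), counts("inter"))


def corpus_locality(corpus: Corpus, head_type: str, tail_type: str,
                    ) -> dict[tuple[str, str, str], str]:
    out = {}
    for doc in corpus.documents:
        for pair in enumerate_candidate_pairs(doc, head_type, tail_type):
            out[(doc.doc_id, pair.head, pair.tail)] = split_intra_inter(pair, doc)
    return out


# -- model --------------------------------------------------------------------

class SkeogModel:
    """All learnable components plus frozen knowledge-provider vectors."""

    def __init__(self, corpus: Corpus, config: TrainConfig,
                 kg: KnowledgeGraph | None = None,
                 descriptions: dict[str, str] | None = None):
        self.config = config
        self.label_set = list(corpus.label_set)
        self.null_index = self.label_set.index(NULL_LABEL)
        seed = config.seed
        self.table = EmbeddingTable.from_corpus(corpus, config.embed_dim, seed)
        self.encoder = SentenceEncoder(config.embed_dim, config.hidden_dim,
                                       seed + 1, mode=config.encoder_mode)
        self.gparams = GraphParams(config.hidden_dim, config.type_dim,
                                   config.dist_dim, seed + 2)
        ks_dim = config.kg_dim if config.kg_provider != "none" else None
        kd_dim = config.desc_dim if config.desc_provider != "none" else None
        self.transforms = EdgeTransforms.for_dims(
            config.hidden_dim, config.type_dim, config.dist_dim, config.d_z,
            seed + 3, ks_dim=ks_dim, kd_dim=kd_dim)
        rng = np.random.default_rng(seed + 4)
        self.walk = WalkParams(
            W=ag.parameter(rng, (config.d_z, config.d_z), config.walk_w_init),
            alpha=config.walk_alpha, final_length=config.final_length)
        self.classifier = PairClassifier(config.d_z, len(self.label_set), seed + 5)
        self.loss_config = LossConfig(config.lambda_ce, config.soft_f_beta)

        self.gat: GATEncoder | None = None
        self.desc_encoder: DescriptionEncoder | None = None
        self.ks_frozen: dict[str, Tensor] | None = None
        self.kd_frozen: dict[str, Tensor] | None = None
        if config.kg_provider != "none":
            if kg is None or not kg.triples:
                raise ValueError("kg_provider set but no knowledge graph given")
            if config.kg_provider == "transe":
                emb = train_transe(kg, dim=config.kg_dim, seed=seed + 6,
                                   epochs=config.kg_pretrain_epochs)
                self.ks_frozen = _freeze(emb.entity_vectors, config)
            elif config.kg_provider == "rescal":
                emb, _ = factorize_rescal(kg, rank=min(config.kg_dim,
                                                       len(kg.entity_index)),
                                          seed=seed + 6,
                                          epochs=config.kg_pretrain_epochs)
                self.ks_frozen = _freeze({e: _pad(v, config.kg_dim)
                                          for e, v in emb.entity_vectors.items()},
                                         config)
            else:
                self.gat = GATEncoder(kg, dim=config.kg_dim,
                                      heads=config.gat_heads,
                                      radius=config.gat_radius, seed=seed + 6)
        if config.desc_provider != "none":
            if not descriptions:
                raise ValueError("desc_provider set but no descriptions given")
            if config.desc_provider == "doc2vec":
                vecs = embed_description_doc2vec(descriptions, dim=config.desc_dim,
                                                 epochs=config.doc2vec_epochs,
                                                 seed=seed + 7)
                self.kd_frozen = {e: Tensor(v) for e, v in vecs.items()}
            else:
                self.desc_encoder = DescriptionEncoder(
                    descriptions, dim=config.desc_dim,
                    embed_dim=config.desc_dim, seed=seed + 7)

    def parameters(self) -> list[Tensor]:
        params = ([self.table.vectors] + self.encoder.parameters()
                  + self.gparams.parameters() + self.transforms.parameters()
                  + [self.walk.W] + self.classifier.parameters())
        if self.gat is not None:
            params += self.gat.parameters()
        if self.desc_encoder is not None:
            params += self.desc_encoder.parameters()
        return params

    def _knowledge_vectors(self, doc: Document):
        ks = kd = None
        if self.ks_frozen is not None:
            ks = self.ks_frozen
        elif self.gat is not None:
            ks = {e.entity_id: self.gat.embed(e.entity_id) for e in doc.entities
                  if e.entity_id in self.gat.kg.entity_index}
        if self.kd_frozen is not None:
            kd = self.kd_frozen
        elif self.desc_encoder is not None:
            kd = {e.entity_id: self.desc_encoder.embed(e.entity_id)
                  for e in doc.entities
                  if e.entity_id in self.desc_encoder.descriptions}
        return ks, kd

    def forward(self, doc: Document, dropout_rng: np.random.Generator | None = None):
        """Run the pipeline on one document.

        Returns ``(probs, pairs)`` — the (n_pairs, n_labels) probability
        tensor and the candidate pairs (gold-labelled) — or None when the
        document yields no candidate pairs. ``dropout_rng`` enables
        training-time word dropout (tokens replaced by the unknown token),
        which teaches the model to handle unseen vocabulary.
        """
        pairs = enumerate_candidate_pairs(doc, self.config.head_type,
                                          self.config.tail_type)
        if not pairs:
            return None
        sentences = [list(s.tokens) for s in doc.sentences]
        if dropout_rng is not None:
            from .encoder import UNK
            p_w = self.config.word_dropout
            if p_w > 0:
                sentences = [[UNK if dropout_rng.random() < p_w else t for t in s]
                             for s in sentences]
            # mention dropout (entity blinding): hide an entity's surface
            # tokens so the model must handle unseen entities whose only
            # evidence is context, knowledge nodes, or nothing
            p_m = self.config.mention_dropout
            if p_m > 0:
                blind = {e.entity_id for e in doc.entities
                         if dropout_rng.random() < p_m}
                for m in doc.mentions:
                    if m.entity_id not in blind:
                        continue
                    sent = doc.sentences[m.sentence_index]
                    for ti, (a, b) in enumerate(sent.token_spans):
                        if a < m.span.end and m.span.start < b:
                            sentences[m.sentence_index][ti] = UNK
        encodings = self.encoder.encode_document(sentences, self.table)
        g = build_graph(doc, encodings, self.gparams)
        ks, kd = self._knowledge_vectors(doc)
        attach_knowledge_nodes(g, ks, kd, self.gparams)
        V1 = transform_edges(g, self.transforms)
        VL = aggregate_walks(V1, self.walk)
        pair_nodes = [(g.entity_node[p.head], g.entity_node[p.tail]) for p in pairs]
        probs = classify_pairs(VL, pair_nodes, self.classifier)
        return probs, pairs

    def loss(self, doc: Document,
             dropout_rng: np.random.Generator | None = None) -> Tensor | None:
        out = self.forward(doc, dropout_rng)
        if out is None:
            return None
        probs, pairs = out
        gold_idx = np.array([self.label_set.index(p.label) for p in pairs])
        return total_loss(probs, gold_idx, self.null_index, self.loss_config)

    def snapshot(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def restore(self, snap: list[np.ndarray]) -> None:
        for p, d in zip(self.parameters(), snap):
            p.data = d.copy()


def _pad(v: np.ndarray, dim: int) -> np.ndarray:
    return v if v.shape[0] == dim else np.pad(v, (0, dim - v.shape[0]))


def _freeze(vectors: dict[str, np.ndarray], config: TrainConfig,
            ) -> dict[str, Tensor]:
    """Frozen provider output -> constant tensors, optionally standardized
    per dimension across entities so knowledge contrasts are O(1) features."""
    if not config.ks_standardize or len(vectors) < 2:
        return {e: Tensor(v) for e, v in vectors.items()}
    M = np.stack(list(vectors.values()))
    mu = M.mean(axis=0)
    sd = M.std(axis=0) + 1e-8
    return {e: Tensor((v - mu) / sd) for e, v in vectors.items()}


# -- training / prediction ----------------------------------------------------

def train_model(corpus_train: Corpus, corpus_dev: Corpus | None,
                kg: KnowledgeGraph | None, descriptions: dict[str, str] | None,
                config: TrainConfig,
                model: SkeogModel | None = None):
    """Train the full pipeline; returns ``(model, history)``.

    History rows are ``{"epoch", "train_loss", "dev_f1"}``; when a dev
    corpus is given, the parameters scoring the best dev F1 are restored
    before returning.
    """
    if not corpus_train.documents:
        raise ValueError("empty training set")
    if corpus_dev is not None:
        train_ids = {d.doc_id for d in corpus_train.documents}
        if train_ids & {d.doc_id for d in corpus_dev.documents}:
            raise ValueError("train and dev corpora share documents")
    if model is None:
        model = SkeogModel(corpus_train, config, kg, descriptions)
    opt = Adagrad(model.parameters(), lr=config.lr, clip=config.clip,
                  weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    history: list[dict] = []
    best = (-1.0, None)
    docs = list(corpus_train.documents)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(docs))
        epoch_loss, n_batches = 0.0, 0
        batch: list = []
        for pos, di in enumerate(order):
            loss = model.loss(docs[di], dropout_rng=rng)
            if loss is not None:
                batch.append(loss)
            if len(batch) >= config.batch_size or (pos == len(order) - 1 and batch):
                total = batch[0]
                for b in batch[1:]:
                    total = total + b
                total = total * (1.0 / len(batch))
                opt.zero_grad()
                total.backward()
                opt.step()
                epoch_loss += total.item()
                n_batches += 1
                batch = []
        row = {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1),
               "dev_f1": None}
        if corpus_dev is not None and (epoch % config.eval_every == 0
                                       or epoch == config.epochs):
            metrics = evaluate_model(model, corpus_dev)
            row["dev_f1"] = metrics.overall.f1
            if metrics.overall.f1 > best[0]:
                best = (metrics.overall.f1, model.snapshot())
        history.append(row)
    if best[1] is not None:
        model.restore(best[1])
    return model, history


def predict(model: SkeogModel, corpus: Corpus,
            hierarchy: Hierarchy | None = None) -> list[CandidatePair]:
    """Argmax predictions for every candidate pair; hypernym filtering is
    applied to the positives when a hierarchy is supplied."""
    out: list[CandidatePair] = []
    for doc in corpus.documents:
        res = model.forward(doc)
        if res is None:
            continue
        probs, pairs = res
        labels = np.argmax(probs.data, axis=1)
        for p, li in zip(pairs, labels):
            out.append(CandidatePair(p.doc_id, p.head, p.tail,
                                     model.label_set[int(li)]))
    if hierarchy is not None:
        out = hypernym_filter(out, hierarchy)
    return out


def evaluate_model(model: SkeogModel, corpus: Corpus,
                   hierarchy: Hierarchy | None = None) -> Metrics:
    preds = predict(model, corpus, hierarchy)
    gold = [p for doc in corpus.documents
            for p in enumerate_candidate_pairs(doc, model.config.head_type,
                                               model.config.tail_type)]
    locality = corpus_locality(corpus, model.config.head_type,
                               model.config.tail_type)
    return evaluate(preds, gold, locality)


def write_predictions_tsv(predictions: list[CandidatePair],
                          path: str | Path) -> None:
    lines = [f"{p.doc_id}\t{p.head}\t{p.label}\t{p.tail}"
             for p in predictions if p.label != NULL_LABEL]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_predictions_tsv(path: str | Path) -> list[CandidatePair]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        doc_id, head, label, tail = line.split("\t")
        out.append(CandidatePair(doc_id, head, tail, label))
    return out


def run_protocol(corpus_train: Corpus, corpus_dev: Corpus, corpus_test: Corpus,
                 kg: KnowledgeGraph | None, descriptions: dict[str, str] | None,
                 config: TrainConfig, hierarchy: Hierarchy | None = None,
                 log_path: str | Path | None = None) -> Metrics:
    """Train -> select on dev -> retrain on train+dev -> report test metrics."""
    _, history = train_model(corpus_train, corpus_dev, kg, descriptions, config)
    evaluated = [h for h in history if h["dev_f1"] is not None]
    best_epoch = max(evaluated, key=lambda h: h["dev_f1"])["epoch"] if evaluated \
        else config.epochs
    retrain_cfg = TrainConfig(**{**config.__dict__, "epochs": best_epoch})
    combined = Corpus(corpus_train.documents + corpus_dev.documents,
                      corpus_train.label_set)
    model, _ = train_model(combined, None, kg, descriptions, retrain_cfg)
    metrics = evaluate_model(model, corpus_test, hierarchy)
    if log_path is not None:
        payload = {"seed": config.seed, "selected_epochs": best_epoch,
                   "history": history, "test_metrics": metrics.to_dict()}
        Path(log_path).write_text(json.dumps(payload, indent=1))
    return metrics
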
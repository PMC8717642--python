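"""Synthetic corpora, knowledge graphs, hierarchies and entity descriptions.

The generator plants document-level chemical-disease relations whose textual
evidence mimics the two localities of the real task:

* intra-sentence positives: head and tail mentions co-occur in one sentence
  around a dedicated trigger token (``RELTRIG``);
* inter-sentence positives: the head sentence carries ``FWDTRIG`` and a later
  sentence carries ``BWDTRIG`` before the tail mention, and the two entities
  never share a sentence.

A configurable fraction of positives is *knowledge-dependent*: a KG-active
("potent") chemical relates to its co-document diseases with probability
``kg_signal_strength``, with no textual trigger at all. The potency marker
exists only in the generated knowledge graph (a triple to a per-type hub
node; linked pairs also get a direct head-tail triple). A model without
access to the knowledge graph cannot distinguish such pairs from
negatives, which is exactly the ablation contrast the benchmark is built
to expose.

The knowledge graph supports two regimes mirroring the contrast between a
taxonomy-like source (3 relation types, about one neighbor per entity) and a
reaction-database-like source (9 relation types, about three neighbors per
entity).

Everything is deterministic given the config seed; emitted files are
byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .corpus_io import (Corpus, Document, Entity, Mention, Span,
                        segment_document, write_pubtator)

RELATION_LABEL = "CID"
TRIGGER_INTRA = "RELTRIG"
TRIGGER_FWD = "FWDTRIG"
TRIGGER_BWD = "BWDTRIG"
HUB_CHEMICAL = "HUB_CHEM"
HUB_DISEASE = "HUB_DIS"

__all__ = [
    "GeneratorConfig", "generate_corpus", "generate_kg", "generate_benchmark",
    "write_benchmark", "RELATION_LABEL",
]


@dataclass
class GeneratorConfig:
    n_docs: int = 50
    sentences_per_doc: tuple[int, int] = (3, 5)   # body sentences (title extra)
    vocab_size: int = 60
    n_entities: int = 40                          # split evenly chemical/disease
    chems_per_doc: int = 2
    dis_per_doc: int = 2
    p_positive: float = 0.35
    p_inter: float = 0.3
    kg_signal_strength: float = 0.5
    noise_rate: float = 0.0
    kg_regime: str = "mesh"                       # "mesh" | "biochem"
    kg_active_fraction: float = 0.2
    p_entity_in_kg: float = 0.9
    entity_id_offset: int = 0
    generic_surfaces: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("p_positive", "p_inter", "kg_signal_strength",
                     "noise_rate", "kg_active_fraction", "p_entity_in_kg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.kg_regime not in ("mesh", "biochem"):
            raise ValueError(f"unknown kg_regime {self.kg_regime!r}")
        if self.p_inter > 0 and self.sentences_per_doc[0] < 2:
            raise ValueError("inter-sentence positives need >= 2 body sentences")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _inventory(cfg: GeneratorConfig, rng: np.random.Generator):
    n_chem = cfg.n_entities // 2
    n_dis = cfg.n_entities - n_chem
    off = cfg.entity_id_offset
    chems = [f"C{i:03d}" for i in range(off, off + n_chem)]
    diseases = [f"D{i:03d}" for i in range(off, off + n_dis)]
    in_kg = {e: bool(rng.random() < cfg.p_entity_in_kg) for e in chems + diseases}
    # exactly the configured fraction of in-KG entities per type is KG-active
    active = {e: False for e in chems + diseases}
    for group in (chems, diseases):
        eligible = [e for e in group if in_kg[e]]
        k = int(round(cfg.kg_active_fraction * len(eligible)))
        for e in rng.choice(eligible, size=k, replace=False) if k else []:
            active[e] = True
    return chems, diseases, in_kg, active


def _surface(entity_id: str, generic: bool = False) -> str:
    """Mention surface form. With ``generic`` surfaces every chemical reads
    ``CHEMX`` and every disease ``DISX`` (corpus-level entity blinding), so
    lexical identity cannot stand in for external knowledge."""
    kind = "CHEM" if entity_id.startswith("C") else "DIS"
    if generic:
        return kind + "X"
    return kind + entity_id[1:].lstrip("0").zfill(1)


def generate_corpus(cfg: GeneratorConfig):
    """Generate a corpus with planted relations.

    Returns ``(corpus, manifest)`` where the manifest records every planted
    pair with its label, locality and knowledge-dependence, the planted
    sentence index of every mention, and the per-entity KG membership /
    activity flags consumed by :func:`generate_kg`.
    """
    rng = np.random.default_rng(cfg.seed)
    chems, diseases, in_kg, active = _inventory(cfg, rng)
    vocab = [f"W{i:03d}" for i in range(cfg.vocab_size)]

    def filler(k: int) -> list[tuple[str, str | None]]:
        return [(vocab[i], None) for i in rng.integers(0, cfg.vocab_size, size=k)]

    def ent_tok(entity_id: str) -> tuple[str, str]:
        return (_surface(entity_id, cfg.generic_surfaces), entity_id)

    documents: list[Document] = []
    manifest_docs = []
    for d in range(cfg.n_docs):
        doc_id = f"SYN{d:04d}"
        n_body = int(rng.integers(cfg.sentences_per_doc[0], cfg.sentences_per_doc[1] + 1))
        doc_chems = [str(x) for x in rng.choice(chems, size=cfg.chems_per_doc,
                                                 replace=False)]
        doc_dis = [str(x) for x in rng.choice(diseases, size=cfg.dis_per_doc,
                                              replace=False)]

        # sentence 0 is the title (chapter 0); it mentions one chemical only,
        # so it can never collapse a planned inter-sentence pair to intra.
        sents: list[list[tuple[str, str | None]]] = [
            filler(2) + [ent_tok(doc_chems[0]), (".", None)]]
        sent_entities: list[set[str]] = [{doc_chems[0]}]
        for _ in range(n_body):
            sents.append(filler(int(rng.integers(2, 5))))
            sent_entities.append(set())
        body = range(1, n_body + 1)

        forbidden: set[frozenset[str]] = set()   # pairs that must stay inter

        def place(entity_id: str, si: int, extra: list[str] | None = None):
            sents[si].append(ent_tok(entity_id))
            sents[si].extend((t, None) for t in (extra or []))
            sent_entities[si].add(entity_id)

        # decide labels and realize evidence
        pairs_manifest = []
        for h in doc_chems:
            for t in doc_dis:
                kg_dependent = False
                positive = False
                # single-ended rule: a KG-active ("potent") chemical relates
                # to its co-document diseases; the marker exists only in the
                # knowledge graph, never in the text
                if active[h] and rng.random() < cfg.kg_signal_strength:
                    positive, kg_dependent = True, True
                elif rng.random() < cfg.p_positive:
                    positive = True
                inter = bool(positive and not kg_dependent
                             and rng.random() < cfg.p_inter)
                noisy = bool(positive and not kg_dependent
                             and rng.random() < cfg.noise_rate)
                # knowledge-dependent positives get NO textual realization:
                # their mentions are placed by the same mechanism as negative
                # pairs' mentions below, so text alone cannot separate them
                if positive and not noisy and not kg_dependent:
                    if inter:
                        si, sj = rng.choice(list(body), size=2, replace=False)
                        place(h, int(si), [TRIGGER_FWD])
                        sents[int(sj)].append((TRIGGER_BWD, None))
                        place(t, int(sj))
                        forbidden.add(frozenset((h, t)))
                    else:
                        si = int(rng.choice(list(body)))
                        sents[si].append(ent_tok(h))
                        sents[si].append((TRIGGER_INTRA, None))
                        sents[si].append(ent_tok(t))
                        sent_entities[si] |= {h, t}
                pairs_manifest.append({
                    "head": h, "tail": t,
                    "label": RELATION_LABEL if positive else None,
                    "kg_dependent": kg_dependent,
                    "noisy": noisy,
                    "planned_locality": "inter" if (positive and inter) else "intra",
                })

        # every document entity needs at least one mention; extras at random,
        # never violating an inter constraint
        for e in doc_chems + doc_dis:
            placed = any(e in s for s in sent_entities)
            want_extra = rng.random() < 0.3
            if placed and not want_extra:
                continue
            candidates = [si for si in body
                          if not any(frozenset((e, o)) in forbidden
                                     for o in sent_entities[si])]
            if candidates:
                place(e, int(rng.choice(candidates)))

        for s in sents[1:]:
            s.append((".", None))

        doc = _render(doc_id, sents, set(chems))
        gold = {(p["head"], RELATION_LABEL, p["tail"])
                for p in pairs_manifest if p["label"] is not None}
        doc.gold_relations = gold
        segment_document(doc)

        # actual locality from final placements
        for p in pairs_manifest:
            co = any({p["head"], p["tail"]} <= s for s in sent_entities)
            p["locality"] = "intra" if co else "inter"

        manifest_docs.append({
            "doc_id": doc_id,
            "mentions": [{"entity_id": m.entity_id, "sentence_index": m.sentence_index}
                         for m in doc.mentions],
            "pairs": pairs_manifest,
        })
        documents.append(doc)

    manifest = {
        "config": asdict(cfg),
        "relation_label": RELATION_LABEL,
        "entities": [{"entity_id": e,
                      "entity_type": "Chemical" if e in chems else "Disease",
                      "in_kg": in_kg[e], "kg_active": active[e]}
                     for e in chems + diseases],
    }
    manifest["documents"] = manifest_docs
    return Corpus(documents, ["NULL", RELATION_LABEL]), manifest


def _render(doc_id: str, sents: list[list[tuple[str, str | None]]],
            chems: set[str]) -> Document:
    """Join annotated token lists into text with character-accurate mentions."""
    mentions: list[Mention] = []
    pieces = []
    offset = 0
    for si, toks in enumerate(sents):
        for tok, eid in toks:
            if pieces:
                offset += 1  # joining space
            start = offset
            offset += len(tok)
            pieces.append(tok)
            if eid is not None:
                etype = "Chemical" if eid in chems else "Disease"
                mentions.append(Mention(Span(start, start + len(tok)), tok, eid, etype))
    text = " ".join(pieces)
    title_end = len(" ".join(t for t, _ in sents[0]))
    mentions.sort(key=lambda m: (m.span.start, m.span.end, m.entity_id))
    ents: dict[str, Entity] = {}
    for m in mentions:
        ents.setdefault(m.entity_id, Entity(m.entity_id, m.entity_type, [])).mentions.append(m)
    return Document(doc_id=doc_id, text=text, title_end=title_end,
                    mentions=mentions, entities=list(ents.values()))


# -- knowledge graph / hierarchy / descriptions -------------------------------

_MESH_RELATIONS = ["interacts", "affects", "assoc"]
_BIOCHEM_EXTRA = [f"reacts_{i}" for i in range(6)]


def generate_kg(cfg: GeneratorConfig, manifest: dict | None = None):
    """Generate triples, a child->parent hierarchy and entity descriptions.

    Returns ``(triples, hierarchy_pairs, descriptions)``. Triples encode the
    planted signal: KG-active entities link to a per-type hub node, and
    knowledge-dependent positive pairs get a direct ``assoc`` triple. The
    regime controls relation-type count and mean degree (mesh-like: 3 types,
    about 1 neighbor per entity; biochem-like: 9 types, about 3).
    """
    if manifest is None:
        _, manifest = generate_corpus(cfg)
    rng = np.random.default_rng(cfg.seed + 104729)

    ent_info = manifest["entities"]
    in_kg = [e["entity_id"] for e in ent_info if e["in_kg"]]
    active = [e["entity_id"] for e in ent_info if e["kg_active"]]
    etype = {e["entity_id"]: e["entity_type"] for e in ent_info}

    triples: list[tuple[str, str, str]] = []
    for e in active:
        hub = HUB_CHEMICAL if etype[e] == "Chemical" else HUB_DISEASE
        rel = "interacts" if etype[e] == "Chemical" else "affects"
        triples.append((e, rel, hub))

    linked = set()
    in_kg_set = set(in_kg)
    for doc in manifest["documents"]:
        for p in doc["pairs"]:
            if p["kg_dependent"] and p["tail"] in in_kg_set:
                linked.add((p["head"], p["tail"]))
    for h, t in sorted(linked):
        triples.append((h, "assoc", t))

    covered = {x for tr in triples for x in (tr[0], tr[2])}
    uncovered = [e for e in in_kg if e not in covered]
    rng.shuffle(uncovered)
    relations = _MESH_RELATIONS + (_BIOCHEM_EXTRA if cfg.kg_regime == "biochem" else [])
    filler_rels = [r for r in relations if r != "assoc"]
    for i in range(0, len(uncovered) - 1, 2):
        rel = filler_rels[int(rng.integers(0, len(filler_rels)))]
        triples.append((uncovered[i], rel, uncovered[i + 1]))
    if len(uncovered) % 2 == 1 and in_kg:
        other = in_kg[int(rng.integers(0, len(in_kg)))]
        triples.append((uncovered[-1], filler_rels[0], other))

    if cfg.kg_regime == "biochem":
        n_kg = len(in_kg) + 2
        target = int(round(1.5 * n_kg))
        existing = set(triples)
        while len(triples) < target:
            h, t = rng.choice(in_kg, size=2, replace=False)
            rel = relations[int(rng.integers(0, len(relations)))]
            tr = (str(h), rel, str(t))
            if tr not in existing:
                existing.add(tr)
                triples.append(tr)

    # hypernym chains over chemicals: every 4th is a family root
    chems = [e["entity_id"] for e in ent_info if e["entity_type"] == "Chemical"]
    hierarchy = []
    for i in range(0, len(chems) - 2, 4):
        hierarchy.append((chems[i + 1], chems[i]))
        hierarchy.append((chems[i + 2], chems[i + 1]))

    vocab = [f"W{i:03d}" for i in range(cfg.vocab_size)]
    descriptions = {}
    for e in ent_info:
        eid = e["entity_id"]
        cls = "CHEMCLASS" if e["entity_type"] == "Chemical" else "DISCLASS"
        act = ("POTENT" if e["kg_active"] else "INERT")
        fill = [vocab[i] for i in rng.integers(0, cfg.vocab_size, size=3)]
        descriptions[eid] = " ".join([cls, act] + fill)
    return triples, hierarchy, descriptions


def generate_benchmark(cfg: GeneratorConfig):
    """Corpus + manifest + KG + hierarchy + descriptions in one call."""
    corpus, manifest = generate_corpus(cfg)
    triples, hierarchy, descriptions = generate_kg(cfg, manifest)
    return corpus, manifest, triples, hierarchy, descriptions


def generate_ablation_benchmark(cfg: GeneratorConfig, n_dev_docs: int | None = None):
    """Train/dev benchmark probing dependence on external knowledge.

    Mention surfaces are type-generic (corpus-level entity blinding), so
    entity identity is visible to the model only through the knowledge
    graph: knowledge-dependent positives carry no textual evidence and no
    lexical identity, and are recoverable only via the KG activity markers
    attached to their entity nodes. Training and development documents are
    an iid split over one entity inventory.

    The instance is validated against declared power targets before being
    returned (enough textual supervision to learn the trigger patterns, a
    bounded knowledge-dependent share so those pairs do not act as dominant
    label noise for text features, and enough of both pair kinds in the dev
    split to measure a contrast). Generation is re-salted deterministically
    until the targets hold, so any seed yields a usable instance and the
    same seed always yields the same one. Returns ``(train_corpus,
    dev_corpus, triples, hierarchy, descriptions, manifests)``.
    """
    n_dev = n_dev_docs if n_dev_docs is not None else max(1, cfg.n_docs // 3)
    for salt in range(64):
        full_cfg = GeneratorConfig(**{**asdict(cfg),
                                      "n_docs": cfg.n_docs + n_dev,
                                      "generic_surfaces": True,
                                      "seed": (cfg.seed + salt * 65537)
                                      % (2 ** 31)})
        corpus, manifest = generate_corpus(full_cfg)
        counts = {"train": {"text": 0, "kgdep": 0},
                  "dev": {"text": 0, "kgdep": 0}}
        for i, mdoc in enumerate(manifest["documents"]):
            split = "train" if i < cfg.n_docs else "dev"
            for p in mdoc["pairs"]:
                if p["label"] is None or p["noisy"]:
                    continue
                counts[split]["kgdep" if p["kg_dependent"] else "text"] += 1
        tr, dv = counts["train"], counts["dev"]
        scale = cfg.n_docs / 50.0
        dev_scale = n_dev / 20.0
        share = tr["kgdep"] / max(tr["kgdep"] + tr["text"], 1)
        ok = (tr["text"] >= 50 * scale
              and 20 * scale <= tr["kgdep"] and share <= 0.40
              and dv["kgdep"] >= 12 * dev_scale
              and dv["text"] >= 16 * dev_scale)
        if ok or cfg.kg_signal_strength == 0.0:
            break
    triples, hierarchy, descriptions = generate_kg(full_cfg, manifest)
    train_corpus = Corpus(corpus.documents[:cfg.n_docs], corpus.label_set)
    dev_corpus = Corpus(corpus.documents[cfg.n_docs:], corpus.label_set)
    manifests = {"train": {**manifest,
                           "documents": manifest["documents"][:cfg.n_docs]},
                 "dev": {**manifest,
                         "documents": manifest["documents"][cfg.n_docs:]}}
    return (train_corpus, dev_corpus, triples, hierarchy, descriptions,
            manifests)


def write_benchmark(cfg: GeneratorConfig, out_dir: str | Path) -> dict[str, Path]:
    """Emit the full benchmark as files: PubTator corpus, manifest JSON,
    triples TSV, hierarchy TSV, descriptions TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    corpus, manifest, triples, hierarchy, descriptions = generate_benchmark(cfg)
    paths = {
        "corpus": out / "corpus.pubtator",
        "manifest": out / "manifest.json",
        "triples": out / "triples.tsv",
        "hierarchy": out / "hierarchy.tsv",
        "descriptions": out / "descriptions.tsv",
    }
    write_pubtator(corpus, paths["corpus"])
    paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True))
    paths["triples"].write_text(
        "".join(f"{h}\t{r}\t{t}\n" for h, r, t in triples))
    paths["hierarchy"].write_text(
        "".join(f"{c}\t{p}\n" for c, p in hierarchy))
    paths["descriptions"].write_text(
        "".join(f"{e}\t{d}\n" for e, d in sorted(descriptions.items())))
    return paths
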
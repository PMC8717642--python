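"""Anatomy of the knowledge-ablation benchmark.

The probe asks: does attaching knowledge-graph nodes improve document-level
relation extraction? For the question to be answerable, the benchmark must
guarantee that (a) some positives are recoverable only through the
knowledge graph and (b) nothing in the text leaks entity identity. This
script generates the benchmark and verifies both properties directly.

The measured contrast itself (mean dev F1 over three training seeds, with
vs without a knowledge provider, 50 training documents, 60 epochs) is a
multi-minute computation; `scripts/acceptance.py` runs it.
"""

from collections import Counter

from skeog.knowledge import KnowledgeGraph, Triple
from skeog.synthetic_data import GeneratorConfig, generate_ablation_benchmark

cfg = GeneratorConfig(n_docs=50, kg_signal_strength=0.9, seed=11)
train, dev, triples, hierarchy, descriptions, manifests = \
    generate_ablation_benchmark(cfg, n_dev_docs=20)
kg = KnowledgeGraph([Triple(*t) for t in triples])

# 1. entity blinding: every mention surface is type-generic
surfaces = {m.surface for d in train.documents + dev.documents
            for m in d.mentions}
print(f"mention surfaces in the whole benchmark: {sorted(surfaces)}")

# 2. pair composition: textual vs knowledge-dependent positives
for split in ("train", "dev"):
    c = Counter()
    for d in manifests[split]["documents"]:
        for p in d["pairs"]:
            if p["label"]:
                c["knowledge-dependent" if p["kg_dependent"] else "textual"] += 1
            else:
                c["negative"] += 1
    print(f"{split}: {dict(c)}")

# 3. the knowledge-dependent evidence lives only in the KG: potent
#    chemicals carry a marker triple to the hub node
potent = {e["entity_id"] for e in manifests["train"]["entities"]
          if e["kg_active"] and e["entity_type"] == "Chemical"}
hub_linked = {t.head for t in kg.triples if t.tail == "HUB_CHEM"}
print(f"potent chemicals: {len(potent)}, all hub-marked: {potent <= hub_linked}")

# 4. and never in the text: no knowledge-dependent pair has a trigger token
triggers = {"RELTRIG", "FWDTRIG", "BWDTRIG"}
leaks = 0
for mdoc, doc in zip(manifests["train"]["documents"], train.documents):
    kg_pairs = [p for p in mdoc["pairs"] if p["kg_dependent"]]
    for p in kg_pairs:
        for sent in doc.sentences:
            ents = {m.entity_id for m in doc.mentions
                    if doc.sentences[m.sentence_index] is sent}
            if {p["head"], p["tail"]} & ents and set(sent.tokens) & triggers:
                # a trigger may appear for a different, textual pair in the
                # same sentence; only co-location of both entities with a
                # trigger would be a leak
                if {p["head"], p["tail"]} <= ents:
                    leaks += 1
print(f"knowledge-dependent pairs co-sentential with a trigger: {leaks}")
# A text-only model sees the blinded corpus above; a knowledge-equipped
# model additionally sees the hub markers — exactly the difference the
# acceptance probe measures as a dev-F1 gap.
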
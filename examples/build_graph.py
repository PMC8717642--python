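"""Build the typed document graph for one abstract and inspect it.

Nodes follow the document hierarchy (mention/entity/sentence/chapter/
document) plus knowledge nodes for entities found in external sources;
edges connect levels and are mapped into a shared-dimension edge tensor.
"""

from collections import Counter

from skeog.autograd import Tensor
from skeog.doc_graph import (EdgeTransforms, GraphParams, attach_knowledge_nodes,
                             build_graph, graph_to_json, transform_edges)
from skeog.encoder import EmbeddingTable, SentenceEncoder
from skeog.synthetic_data import GeneratorConfig, generate_benchmark
import numpy as np

cfg = GeneratorConfig(n_docs=3, seed=7)
corpus, manifest, triples, _, descriptions = generate_benchmark(cfg)
doc = corpus.documents[0]

hidden, e_type, e_dist, d_z = 16, 4, 4, 8
table = EmbeddingTable.from_corpus(corpus, 8, seed=0)
encoder = SentenceEncoder(8, hidden, seed=1)
params = GraphParams(hidden, e_type, e_dist, seed=2)

encodings = [encoder.encode_tokens(s.tokens, table) for s in doc.sentences]
graph = build_graph(doc, encodings, params)
print(f"{doc.doc_id}: {graph.n_nodes()} nodes "
      f"({Counter(n.kind for n in graph.nodes)})")
print("edge counts:", {k: v for k, v in graph.edge_counts().items() if v})

# attach knowledge nodes for entities present in the triple store
kg_entities = {x for h, _, t in triples for x in (h, t)}
ks = {e.entity_id: Tensor(np.ones(6)) for e in doc.entities
      if e.entity_id in kg_entities}
attach_knowledge_nodes(graph, ks, None, params)
print("after knowledge attachment:", graph.n_nodes(), "nodes,",
      graph.edge_counts()["EKS"], "entity-knowledge edges")

transforms = EdgeTransforms.for_dims(hidden, e_type, e_dist, d_z, seed=3,
                                     ks_dim=6)
V1 = transform_edges(graph, transforms)
print(f"initial edge tensor V1: shape {V1.shape}, "
      f"{(abs(V1.data).sum(axis=2) > 0).sum() // 2} populated node pairs")
print(graph_to_json(graph)["nodes"][:5], "...")
# Every populated pair entry is one typed edge mapped through its W_z; the
# zero entries are pairs with no length-1 path, which walk aggregation fills.
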
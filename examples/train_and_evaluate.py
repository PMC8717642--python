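"""Train the full pipeline on a small synthetic corpus and score it.

The per-document pipeline: encode sentences -> build the typed graph ->
transform edges -> walk aggregation -> classify candidate chemical-disease
pairs -> interpolated cross-entropy / soft-F1 loss.
"""

import json

from skeog.corpus_io import Corpus
from skeog.synthetic_data import GeneratorConfig, generate_corpus
from skeog.train_eval import TrainConfig, evaluate_model, train_model

cfg = GeneratorConfig(n_docs=12, kg_signal_strength=0.0, seed=5)
corpus, _ = generate_corpus(cfg)
train = Corpus(corpus.documents[:9], corpus.label_set)
heldout = Corpus(corpus.documents[9:], corpus.label_set)

tc = TrainConfig(seed=0, epochs=15)
model, history = train_model(train, None, None, None, tc)
print("training loss by epoch:",
      [round(h["train_loss"], 3) for h in history[::3]])

for name, split in (("train", train), ("heldout", heldout)):
    metrics = evaluate_model(model, split)
    print(name, json.dumps(metrics.to_dict()))
# Train F1 should approach 100 (the planted trigger patterns are noise-free);
# held-out F1 is lower but well above zero, showing the trigger patterns
# rather than document identity are what the model picked up.
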
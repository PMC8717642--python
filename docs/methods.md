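# Methods

## The model

`skeog` implements an edge-oriented graph neural network (SKEoG) for
document-level relation extraction between entities in biomedical abstracts,
typically chemical–disease pairs. Instead of learning node states, the model
maintains a representation per *node pair* (an edge tensor) and composes
short paths into longer ones, so a relation — an edge between two entity
nodes — is the object being modelled directly.

### Document graph

A document is segmented into a hierarchy: tokens → sentences → chapters →
document. For PubMed-style abstracts the default chaptering is chapter 0 =
title, chapter 1 = abstract body; a hook accepts custom chapterings for
longer documents. Five structural node kinds are built, each represented as
`[content ; t_kind]` where `t_kind` is a learnable node-type embedding:

- mention node `n_m`: average of the encoder states of the mention's tokens;
- entity node `n_e`: average of its mention contents;
- sentence node `n_s`: average of the sentence's token states;
- chapter node `n_c`: average of its sentence contents;
- document node `n_d`: average of chapter contents.

The chapter-node content is defined over *sentence node contents*; that is
the only sentence-level vector available and the natural reading of the
hierarchy (this was a genuinely open design point).

Structural edges: mention–sentence, mention–mention (co-sentential, with an
attention context vector and a bucketed token-distance embedding),
mention–entity, sentence–sentence (complete graph, with bucketed sentence
distance and the elementwise absolute difference of the two sentence nodes),
entity–sentence, sentence–chapter, chapter–chapter, chapter–document. Eight
structural types are implemented (the hierarchy yields eight even though
informal descriptions often count six). Edges are undirected and stored
once per unordered pair; graphs never cross document boundaries.

The mention-pair attention scores every sentence token against each mention
through a learned projection of the mention's *content* part (the type
embedding is excluded; without the projection the score would not be
well-typed), masks the mention's own tokens out of the softmax support,
averages the two normalised weight vectors, and takes the weighted sum of
token encodings. The context vector therefore lives in encoder space and
has fixed length regardless of sentence length.

Distance buckets are powers of two (0, 1, 2–3, 4–7, 8–15, 16+) for both
mention-level (token offset between mention starts) and sentence-level
(`|i - j|`) distances. The mention-level distance is used on
mention–mention edges: the distance that matters there is between the two
mentions, measured within the sentence.

Each edge type `z` has a raw concatenated representation and a learnable
matrix `W_z` mapping it to a common dimension `d_z`; the transformed vectors
are scattered into a symmetric `(n_nodes, n_nodes, d_z)` tensor `V^(1)`,
zero where no edge exists.

### External knowledge

Entities that exist in an external source gain knowledge nodes wired to
their entity node: a KS node whose content comes from a knowledge-graph
encoder, and/or a KD node whose content embeds the entity's description
text. Providers:

- **TransE** — translation embeddings minimising a max-margin objective with
  filtered negative sampling; the score is the L2 distance `‖h + r − t‖`
  (the margin structure requires lower-is-better, and entity vectors are
  re-normalised to unit length per epoch, standard TransE practice).
  Margin default 1. Pre-trained, then frozen.
- **RESCAL** — gradient descent on the squared reconstruction error of the
  binary relation tensor `X_k ≈ A R_k Aᵀ` with a step-halving safeguard that
  makes the loss history monotonically non-increasing. Gradient descent
  rather than alternating least squares keeps the implementation uniform
  and seedable. Pre-trained, then frozen; entity vector = row of `A`.
- **GAT** — single-layer, single-head graph attention over the 1-hop
  neighborhood (radius and heads configurable), with a learnable feature
  table for KG entities; trained end-to-end with the main model.
- **Doc2vec** — a simplified distributed-memory paragraph-vector model
  (paragraph vector + context word vectors → softmax word prediction),
  written in plain numpy; exact parity with the original tool is a
  non-goal. Pre-trained, then frozen.
- **EMB** — embed → BiRNN → mean-pool over the description tokens, trained
  end-to-end (the minimal end-to-end description encoder consistent with
  the design).

The frozen-vs-end-to-end split follows the natural reading of the
architecture: factorisation-style encoders are pre-trained; neural encoders
participate in the joint gradient.

### Walk aggregation and inference

One walk step combines length-`l` paths through every intermediate node:

    f(v_ik, v_kj) = sigmoid(v_ik ⊙ (W v_kj))
    v_ij^(2l)     = α v_ij^(l) + (1 − α) Σ_{k∉{i,j}} f(v_ik^(l), v_kj^(l))

applied log2(L) times (default L = 4, enough for the
entity–sentence–sentence–entity paths that carry inter-sentence relations).
After each step the tensor is re-symmetrised by averaging `(i,j)` and
`(j,i)`, preserving the undirected contract. `α` is a fixed interpolation
hyper-parameter (default 0.8). There are no explicit entity–entity edges at `l = 1`; entity-pair
representations emerge entirely from aggregation.

Candidate pairs (ordered, by entity type, e.g. chemical→disease) are read
off the entity-node entries of `V^(L)` and classified by a linear softmax
layer. The loss interpolates mean cross-entropy with a differentiable soft
F-measure surrogate

    soft_f_loss = 1 − 2 Σ(p·y) / (Σp + Σy + β),   β = 1e−8,

computed one-vs-rest on the non-null labels and averaged (the surrogate is
the standard soft-F1 construction; the mixing weight `lambda_ce` defaults
to 0.7). The soft-F term counteracts the null-label imbalance typical of
document-level relation corpora.

### Training protocol

Adagrad with global-norm gradient clipping (default lr 0.1, clip 5),
one document per update. The evaluation protocol mirrors the common
practice on the chemical–disease corpora: train on the training split while
monitoring dev F1, select the best epoch, retrain on train+dev with that
epoch budget, report test precision/recall/F1 overall and split into
intra-/inter-sentence pairs. A pair is *intra* iff some single sentence
mentions both entities (the convention of the edge-oriented lineage; the
split is otherwise under-specified). Hypernym filtering, when a hierarchy
is supplied, removes a predicted positive pair when the same document
predicts the same relation for a strict descendant of its head (same tail)
or of its tail (same head); it applies to predictions only by default,
with a hook available at candidate construction.

Optional regularisers: word dropout (any token → unknown) and mention
dropout (all surface tokens of a sampled entity → unknown, i.e. stochastic
entity blinding). Both default to off.

## Differentiation engine

No GPU tensor framework is assumed; all differentiable components run on a
small reverse-mode autodiff module over numpy arrays (`skeog.autograd`)
supporting broadcast arithmetic, matrix products, pointwise nonlinearities,
reductions, indexing, concatenation and a symmetric pair-scatter primitive.
Gradient correctness is verified against finite differences in the test
suite, including end-to-end through walk aggregation and both losses.

## Synthetic benchmark

No public corpus is bundled; the generator emits the exact file formats the
package consumes (PubTator corpus, 3-column triples TSV, 2-column hierarchy
and description TSVs, a JSON ground-truth manifest) with planted, fully
bookkept structure:

- **Textual positives.** Intra-sentence pairs co-occur around a dedicated
  trigger token; inter-sentence pairs use a two-sentence mediated pattern
  (`FWDTRIG` in the head sentence, `BWDTRIG` before the tail mention) and
  their entities never share a sentence. `p_inter` (default 0.3, matching
  the inter fraction of the public chemical–disease corpus this emulates)
  applies to textual positives.
- **Knowledge-dependent positives.** With probability `kg_signal_strength`,
  a KG-active ("potent") chemical is related to each disease in its
  document, with *no* textual realisation: the pair's mentions are placed
  by the same mechanism as negative pairs' mentions, so text alone cannot
  separate these positives from negatives. The KG marks active entities
  with marker triples to a per-type hub node and adds a direct head–tail
  `assoc` triple per linked pair. Two deliberate consequences of this
  construction: the hub makes active entities a tight cluster under TransE
  (an entity-level attribute — the only form of KG signal the walk
  architecture can propagate into an entity-pair representation at L = 4,
  where knowledge content arrives as additive per-entity features), and
  the rule is single-ended (head-side only), which those additive features
  can express exactly; a both-entities rule is representable only through
  threshold calibration against half-active pairs and measurably collapses
  precision at this scale.
- **Regimes.** "mesh" emulates a taxonomy-like source: 3 relation types,
  mean degree near 1. "biochem" emulates a reaction database: 9 relation
  types, mean degree near 3 (filler triples pad to the target density).
- **Hierarchy** contains depth-2 hypernym chains over chemicals so the
  hypernym filter is exercisable; **descriptions** carry class- and
  activity-indicative tokens.

Default shape: 50 documents, 1 title + 3–5 body sentences, 2 chemicals and
2 diseases per document (so 4 candidate pairs), 40-entity inventory,
`p_positive` 0.35 — roughly one tenth of the public corpus scale, keeping
every experiment desk-sized. `kg_active_fraction` defaults to 0.2 so that
knowledge-dependent and purely textual positives occur at comparable rates
(an exact fraction of in-KG entities per type is sampled active, which
removes one layer of binomial variance from small benchmarks).

**The ablation probe.** The knowledge-ablation benchmark additionally
blinds mention surfaces (every chemical renders as `CHEMX`, every disease
as `DISX`). Without blinding, a model memorises entity identity from
surface tokens, which is informationally equivalent to looking the entity
up in the knowledge graph — the with/without-KG contrast then measures
nothing. With blinding, entity identity reaches the model *only* through
knowledge nodes, so the dev-F1 gap between `kg_provider=transe` and
`kg_provider=none` isolates the knowledge contribution. Training and dev
documents are an iid split over one inventory. Before returning an
instance, the generator checks declared power targets — enough textual
positives to learn the trigger patterns, a knowledge-dependent share of
positives at most 40% (beyond that those pairs act as dominant label noise
for text features and push both arms into degenerate all-positive or
all-null behaviour), and enough pairs of both kinds in the dev split to
measure a contrast — and deterministically re-salts generation until the
targets hold, the benchmark analogue of a power analysis. The probe's
training configuration (interpolation α = 0.8, walk-matrix init 0.05,
standardized frozen knowledge vectors) keeps early sigmoids unsaturated
and preserves a strong direct term for the entity-knowledge edge in the
pair representation, both of which speed up learning of evidence that
enters only through knowledge-node paths. The knowledge contribution
measurable this way is a few F1 points — the magnitude typical of
knowledge ablations on this task — and sits near the training-noise floor
of such small corpora, so the probe reports a mean over three training
seeds on one fixed benchmark instance.

### What the generator does not emulate

Pseudo-word text (uppercase-initial filler tokens) keeps tokenisation and
offsets exact but has no linguistic structure: no anaphora, no synonymy, no
ambiguous mention boundaries, no discourse beyond the planted two-sentence
pattern. Passing tests therefore demonstrate that the machinery is
implemented correctly and that the architecture can exploit planted
structural and knowledge signals — not that it reaches any particular
accuracy on real corpora.

## Numerical choices

- Offsets 0-based half-open; title and abstract joined by a single space.
- Sentence splitting is rule-based (terminal punctuation + uppercase/digit
  lookahead); a split falling inside a mention span is suppressed, because
  node construction requires every mention inside one sentence. Composite
  entity ids (`D001|D002`) split into one mention copy per id; id `-1`
  mentions are dropped.
- Softmax is computed with max-shifting; cross-entropy clamps probabilities
  at 1e−12. The attention mask uses an additive −1e30, which underflows to
  exact zero weight outside the support.
- The walk step excludes `k ∈ {i, j}` for every entry, including the
  diagonal `i = j` (where the exclusion set is just `{i}`); diagonal
  entries are never read by the classifier but the brute-force test oracle
  covers them.
- Mention-pair attention with an empty support (a mention covering the
  whole sentence) yields a zero weight vector rather than an error.
- RESCAL rank is clamped to the entity count; TransE corruption resamples
  up to 20 times to avoid true triples, then skips the example.
- Metric edge cases: precision/recall are 0 when their denominator is 0,
  and F1 = 0 when P + R = 0.

## Problem sizes used by the automated checks

The acceptance checks run, per invocation: walk-aggregation brute-force
comparison on 200 random graphs (≤ 6 nodes, d_z ≤ 4); attention
normalisation on 1,000 random instances; TransE on a 20-entity toy KG;
RESCAL on an 8-entity/2-relation tensor; memorisation of 10 noise-free
documents (≤ 200 epochs, cross-entropy-dominant loss mix); and the
knowledge ablation on the blinded benchmark (50 training + 20 dev
documents, `kg_signal_strength` 0.9, 3 training seeds per arm, 60 epochs,
α = 0.8, 4-dimensional knowledge vectors). These sizes were chosen so the
whole battery is a desk-scale computation.

## Known limitations

- The encoder is a BiRNN over pseudo-words; no subword or transformer
  support, and no pre-trained vectors are bundled (a word2vec-format text
  reader is provided).
- `h_ks`/`h_kd` dimensions are global per provider family, not per entity.
- The soft-F surrogate is computed per batch (here: per document), so its
  value is not the corpus-level F1.
- Walk aggregation is O(n³ d_z) per step in dense form; fine for abstracts
  (tens of nodes), not engineered for full-text documents.
- The published benchmark F1 scores on CDR/CHR are out of scope: they
  require the real corpora, MeSH/Biochem4j-derived resources and long
  stochastic training runs.
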
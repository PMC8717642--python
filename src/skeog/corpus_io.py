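"""PubTator-style corpus I/O and document structuring.

Reads span-annotated abstracts (title line ``ID|t|...``, abstract line
``ID|a|...``, TAB-separated mention and relation lines), segments each
document into a sentence/chapter hierarchy, enumerates candidate entity
pairs, and applies the corpus-specific preprocessing filters (hypernym
filtering, knowledge-graph entity filtering, self-relation removal).

Conventions: character offsets are 0-based half-open over the full
document text, which is title + single space + abstract. For abstracts
the chapter layout is chapter 0 = title, chapter 1 = abstract body; a
custom chaptering hook may override this for longer documents.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

NULL_LABEL = "NULL"

__all__ = [
    "NULL_LABEL", "Span", "Mention", "Entity", "Sentence", "Document",
    "Corpus", "Hierarchy", "CandidatePair", "PubTatorParseError",
    "CorpusValidationError", "read_pubtator", "write_pubtator",
    "segment_document", "enumerate_candidate_pairs", "hypernym_filter",
    "chr_preprocess", "is_intra", "corpus_statistics", "write_statistics",
]


class PubTatorParseError(ValueError):
    pass


class CorpusValidationError(ValueError):
    pass


@dataclass(frozen=True)
class Span:
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise CorpusValidationError(f"bad span [{self.start}, {self.end})")


@dataclass
class Mention:
    span: Span
    surface: str
    entity_id: str
    entity_type: str
    sentence_index: int = -1
    chapter_index: int = -1

    def __eq__(self, other):
        return (self.span, self.surface, self.entity_id, self.entity_type) == (
            other.span, other.surface, other.entity_id, other.entity_type)


@dataclass
class Entity:
    entity_id: str
    entity_type: str
    mentions: list[Mention]


@dataclass
class Sentence:
    span: Span                      # char range in document text
    tokens: list[str]
    token_spans: list[tuple[int, int]]


@dataclass
class Document:
    doc_id: str
    text: str
    title_end: int                  # char offset where the title ends
    mentions: list[Mention] = field(default_factory=list)
    entities: list[Entity] = field(default_factory=list)
    gold_relations: set[tuple[str, str, str]] = field(default_factory=set)
    sentences: list[Sentence] = field(default_factory=list)
    chapters: list[tuple[int, int]] = field(default_factory=list)  # sentence ranges

    def entity_by_id(self, entity_id: str) -> Entity:
        for e in self.entities:
            if e.entity_id == entity_id:
                return e
        raise KeyError(entity_id)


@dataclass
class Corpus:
    documents: list[Document]
    label_set: list[str]

    def __post_init__(self):
        if self.label_set.count(NULL_LABEL) != 1:
            raise CorpusValidationError("label_set must contain the null label exactly once")


@dataclass(frozen=True)
class CandidatePair:
    doc_id: str
    head: str
    tail: str
    label: str


class Hierarchy:
    """Child -> parent links over entity identifiers (acyclic)."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        self.parents: dict[str, set[str]] = defaultdict(set)
        for child, parent in pairs:
            self.parents[child].add(parent)
        self._check_acyclic()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Hierarchy":
        pairs = []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            child, parent = line.split("\t")
            pairs.append((child, parent))
        return cls(pairs)

    def _check_acyclic(self) -> None:
        WHITE, GREY, BLACK = 0, 1, 2
        color: dict[str, int] = defaultdict(int)
        for start in list(self.parents):
            if color[start] != WHITE:
                continue
            stack = [(start, iter(self.parents.get(start, ())))]
            color[start] = GREY
            while stack:
                node, it = stack[-1]
                advanced = False
                for nxt in it:
                    if color[nxt] == GREY:
                        raise CorpusValidationError(f"hierarchy cycle through {nxt!r}")
                    if color[nxt] == WHITE:
                        color[nxt] = GREY
                        stack.append((nxt, iter(self.parents.get(nxt, ()))))
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    stack.pop()

    def ancestors(self, entity_id: str) -> set[str]:
        out: set[str] = set()
        frontier = list(self.parents.get(entity_id, ()))
        while frontier:
            p = frontier.pop()
            if p not in out:
                out.add(p)
                frontier.extend(self.parents.get(p, ()))
        return out

    def is_strict_descendant(self, a: str, b: str) -> bool:
        """True iff `a` is a strict descendant of `b`."""
        return a != b and b in self.ancestors(a)


# -- reading / writing --------------------------------------------------------

def _build_entities(mentions: Sequence[Mention]) -> list[Entity]:
    grouped: dict[str, Entity] = {}
    for m in mentions:
        ent = grouped.get(m.entity_id)
        if ent is None:
            grouped[m.entity_id] = Entity(m.entity_id, m.entity_type, [m])
        else:
            ent.mentions.append(m)
    return list(grouped.values())


def read_pubtator(path: str | Path, segment: bool = True) -> Corpus:
    """Parse a PubTator-format file into a :class:`Corpus`.

    Mentions with entity id ``-1`` are dropped; composite ids such as
    ``D001|D002`` are split into one mention copy per id. Offsets are
    validated against the document text.
    """
    text = Path(path).read_text()
    documents: list[Document] = []
    labels: set[str] = set()

    block: list[tuple[int, str]] = []
    lines = text.splitlines()
    for lineno, raw in enumerate(lines + [""], start=1):
        if raw.strip():
            block.append((lineno, raw))
            continue
        if block:
            documents.append(_parse_block(block, labels))
            block = []

    if segment:
        documents = [segment_document(d) for d in documents]
    return Corpus(documents, [NULL_LABEL] + sorted(labels))


def _parse_block(block: list[tuple[int, str]], labels: set[str]) -> Document:
    title = abstract = None
    doc_id = None
    mention_rows: list[tuple[int, list[str]]] = []
    relation_rows: list[list[str]] = []
    for lineno, line in block:
        if "|t|" in line and title is None:
            doc_id, _, title = line.split("|", 2)
            continue
        if "|a|" in line and abstract is None:
            aid, _, abstract = line.split("|", 2)
            if doc_id is not None and aid != doc_id:
                raise PubTatorParseError(f"line {lineno}: abstract id {aid!r} != {doc_id!r}")
            continue
        cols = line.split("\t")
        if len(cols) == 4:
            relation_rows.append(cols)
        elif len(cols) >= 6:
            mention_rows.append((lineno, cols))
        else:
            raise PubTatorParseError(f"line {lineno}: malformed annotation line: {line!r}")
    if title is None or abstract is None or doc_id is None:
        lineno = block[0][0]
        raise PubTatorParseError(f"line {lineno}: document block missing title/abstract line")

    doc_text = title + " " + abstract
    mentions: list[Mention] = []
    for lineno, cols in mention_rows:
        _, start_s, end_s, surface, etype, eid = cols[:6]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise PubTatorParseError(f"line {lineno}: non-integer offsets") from exc
        if end > len(doc_text) or doc_text[start:end] != surface:
            raise CorpusValidationError(
                f"doc {doc_id}: span [{start},{end}) reads "
                f"{doc_text[start:end]!r}, annotation says {surface!r}")
        for single_id in eid.split("|"):
            if single_id == "-1":
                continue
            mentions.append(Mention(Span(start, end), surface, single_id, etype))
    mentions.sort(key=lambda m: (m.span.start, m.span.end, m.entity_id))

    gold: set[tuple[str, str, str]] = set()
    for cols in relation_rows:
        _, rel, head, tail = cols
        gold.add((head, rel, tail))
        labels.add(rel)

    return Document(doc_id=doc_id, text=doc_text, title_end=len(title),
                    mentions=mentions, entities=_build_entities(mentions),
                    gold_relations=gold)


def write_pubtator(corpus: Corpus, path: str | Path) -> None:
    out = []
    for doc in corpus.documents:
        title = doc.text[:doc.title_end]
        abstract = doc.text[doc.title_end + 1:]
        out.append(f"{doc.doc_id}|t|{title}")
        out.append(f"{doc.doc_id}|a|{abstract}")
        for m in doc.mentions:
            out.append("\t".join([doc.doc_id, str(m.span.start), str(m.span.end),
                                  m.surface, m.entity_type, m.entity_id]))
        for head, rel, tail in sorted(doc.gold_relations):
            out.append("\t".join([doc.doc_id, rel, head, tail]))
        out.append("")
    Path(path).write_text("\n".join(out))


# -- segmentation -------------------------------------------------------------

_TOKEN_RE = re.compile(r"[A-Za-z0-9_:']+|[^\sA-Za-z0-9_:']")
_BREAK_RE = re.compile(r"[.!?]\s+(?=[A-Z0-9])")


def _split_region(text: str, offset: int, protected: list[Span]) -> list[Span]:
    """Split ``text`` (starting at document offset ``offset``) into sentence
    spans at terminal punctuation followed by an uppercase/digit lookahead,
    suppressing breaks that fall inside a protected (mention) span."""
    breaks = []
    for match in _BREAK_RE.finditer(text):
        cut = offset + match.end()
        if any(sp.start < cut < sp.end for sp in protected):
            continue
        breaks.append(cut)
    bounds = [offset] + breaks + [offset + len(text)]
    spans = []
    for a, b in zip(bounds, bounds[1:]):
        if b > a:
            spans.append(Span(a, b))
    return spans


def segment_document(doc: Document,
                     chapterer: Callable[[Document, list[Span]], list[tuple[int, int]]] | None = None,
                     ) -> Document:
    """Populate sentences, chapters, and mention sentence/chapter indices.

    Default chaptering: chapter 0 holds the title's sentences, chapter 1
    the abstract's. A ``chapterer(doc, sentence_spans)`` hook may return
    custom (start, stop) sentence ranges for longer documents.
    """
    if not doc.text.strip():
        raise CorpusValidationError(f"doc {doc.doc_id}: empty text")
    protected = [m.span for m in doc.mentions]
    title_spans = _split_region(doc.text[:doc.title_end], 0, protected)
    body_spans = _split_region(doc.text[doc.title_end + 1:], doc.title_end + 1, protected)
    sent_spans = title_spans + body_spans

    sentences = []
    for sp in sent_spans:
        toks, tok_spans = [], []
        for m in _TOKEN_RE.finditer(doc.text[sp.start:sp.end]):
            toks.append(m.group(0))
            tok_spans.append((sp.start + m.start(), sp.start + m.end()))
        sentences.append(Sentence(sp, toks, tok_spans))

    if chapterer is not None:
        chapters = chapterer(doc, sent_spans)
    else:
        chapters = [(0, len(title_spans)), (len(title_spans), len(sent_spans))]
        chapters = [(a, b) for a, b in chapters if b > a]

    sent_chapter = {}
    for ci, (a, b) in enumerate(chapters):
        for si in range(a, b):
            sent_chapter[si] = ci

    for m in doc.mentions:
        for si, sent in enumerate(sentences):
            if sent.span.start <= m.span.start and m.span.end <= sent.span.end:
                m.sentence_index = si
                m.chapter_index = sent_chapter[si]
                break
        else:
            raise CorpusValidationError(
                f"doc {doc.doc_id}: mention {m.surface!r} crosses a sentence boundary")

    doc.sentences = sentences
    doc.chapters = chapters
    return doc


# -- candidate pairs / filters ------------------------------------------------

def enumerate_candidate_pairs(doc: Document, head_type: str, tail_type: str,
                              ) -> list[CandidatePair]:
    """All ordered (head, tail) entity pairs of the requested types.

    A pair is labelled with its gold relation label when one exists,
    otherwise with the null label. Self-pairs are never emitted.
    """
    gold_by_pair = {(h, t): r for h, r, t in doc.gold_relations}
    pairs = []
    for head in doc.entities:
        if head.entity_type != head_type:
            continue
        for tail in doc.entities:
            if tail.entity_type != tail_type or head.entity_id == tail.entity_id:
                continue
            label = gold_by_pair.get((head.entity_id, tail.entity_id), NULL_LABEL)
            pairs.append(CandidatePair(doc.doc_id, head.entity_id, tail.entity_id, label))
    return pairs


def hypernym_filter(predicted_pairs: Iterable[CandidatePair],
                    hierarchy: Hierarchy) -> list[CandidatePair]:
    """Keep only the most specific predicted relations per document.

    A predicted positive pair (c, d) is removed when the same document also
    predicts (c', d) with c' a strict descendant of c, or (c, d') with d'
    a strict descendant of d.
    """
    pairs = list(predicted_pairs)
    by_doc: dict[str, list[CandidatePair]] = defaultdict(list)
    for p in pairs:
        if p.label != NULL_LABEL:
            by_doc[p.doc_id].append(p)

    removed: set[CandidatePair] = set()
    for doc_pairs in by_doc.values():
        for p in doc_pairs:
            for q in doc_pairs:
                if q is p or q.label != p.label:
                    continue
                if q.tail == p.tail and hierarchy.is_strict_descendant(q.head, p.head):
                    removed.add(p)
                    break
                if q.head == p.head and hierarchy.is_strict_descendant(q.tail, p.tail):
                    removed.add(p)
                    break
    return [p for p in pairs if p not in removed]


def chr_preprocess(corpus: Corpus, kg_entity_ids: set[str]) -> Corpus:
    """Drop entities absent from the triple store (with their mentions) and
    self-relations; gold relations touching a dropped entity go with it."""
    docs = []
    for doc in corpus.documents:
        keep_mentions = [m for m in doc.mentions if m.entity_id in kg_entity_ids]
        keep_ids = {m.entity_id for m in keep_mentions}
        gold = {(h, r, t) for h, r, t in doc.gold_relations
                if h != t and h in keep_ids and t in keep_ids}
        docs.append(replace(doc, mentions=keep_mentions,
                            entities=_build_entities(keep_mentions),
                            gold_relations=gold))
    return Corpus(docs, list(corpus.label_set))


# -- locality / statistics ----------------------------------------------------

def is_intra(doc: Document, head_id: str, tail_id: str) -> bool:
    """True iff some sentence contains at least one mention of each entity."""
    head_sents = {m.sentence_index for m in doc.mentions if m.entity_id == head_id}
    tail_sents = {m.sentence_index for m in doc.mentions if m.entity_id == tail_id}
    return bool(head_sents & tail_sents)


def corpus_statistics(corpus: Corpus, head_type: str, tail_type: str) -> dict[str, int]:
    """Corpus shape counts: documents, positive/negative candidate pairs,
    and how many of each are inter-sentence."""
    stats = {"n_doc": len(corpus.documents), "n_positive": 0, "n_positive_inter": 0,
             "n_negative": 0, "n_negative_inter": 0}
    for doc in corpus.documents:
        for pair in enumerate_candidate_pairs(doc, head_type, tail_type):
            inter = not is_intra(doc, pair.head, pair.tail)
            if pair.label != NULL_LABEL:
                stats["n_positive"] += 1
                stats["n_positive_inter"] += int(inter)
            else:
                stats["n_negative"] += 1
                stats["n_negative_inter"] += int(inter)
    return stats


def write_statistics(stats: dict[str, int], path: str | Path) -> None:
    keys = ["n_doc", "n_positive", "n_positive_inter", "n_negative", "n_negative_inter"]
    lines = ["\t".join(keys), "\t".join(str(stats[k]) for k in keys)]
    Path(path).write_text("\n".join(lines) + "\n")
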
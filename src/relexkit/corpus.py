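"""brat-standoff corpus I/O, sentence binding, and relation signatures.

A corpus is a collection of :class:`AnnotatedDocument` objects, each pairing
raw text with offset-anchored entity mentions (brat ``T`` lines) and binary
relation mentions (brat ``R`` lines).  Offsets are 0-based half-open
throughout, matching the brat convention.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "EntityMention",
    "RelationMention",
    "RelationSignature",
    "SentenceSpan",
    "AnnotatedDocument",
    "BratFormatError",
    "DEFAULT_TYPE_MAP",
    "CHARACTERISTIC_SUBTYPES",
    "read_brat_document",
    "write_brat_document",
    "regex_sentence_splitter",
    "segment_and_bind",
    "select_studied_signatures",
    "collapse_characteristic_subtypes",
]

#: Default label normalisation: the patient/study-group types are one label.
DEFAULT_TYPE_MAP: dict[str, str] = {"patient": "cohort", "Patient": "cohort", "Cohort": "cohort"}

#: Fine-grained sub-labels that can be collapsed into a single category.
CHARACTERISTIC_SUBTYPES: tuple[str, ...] = (
    "Concepts&Ideas",
    "Disorders",
    "Physiology",
    "Phenomena",
)

CHARACTERISTIC_LABEL = "Characteristic"


class BratFormatError(ValueError):
    """Raised when a brat .ann file violates the standoff contract."""


@dataclass(frozen=True)
class EntityMention:
    """A typed, offset-anchored entity mention (brat ``T`` annotation)."""

    id: str
    etype: str
    start: int
    end: int
    surface: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"entity {self.id}: invalid span [{self.start}, {self.end})")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class RelationMention:
    """A binary, typed relation between two entity mentions (brat ``R``)."""

    id: str
    predicate: str
    arg1: str
    arg2: str

    def __post_init__(self) -> None:
        if self.arg1 == self.arg2:
            raise ValueError(f"relation {self.id}: arguments must be distinct mentions")


@dataclass(frozen=True, order=True)
class RelationSignature:
    """The ordered triple (arg1 type, predicate, arg2 type) naming a relation.

    Signatures with the same predicate but different argument types are
    distinct relations.
    """

    arg1_type: str
    predicate: str
    arg2_type: str

    def __str__(self) -> str:
        return f"{self.arg1_type}-{self.predicate}-{self.arg2_type}"

    @classmethod
    def parse(cls, text: str) -> "RelationSignature":
        parts = text.split("-")
        if len(parts) != 3:
            raise ValueError(f"cannot parse signature {text!r}; expected Arg1-pred-Arg2")
        return cls(parts[0], parts[1], parts[2])


@dataclass(frozen=True)
class SentenceSpan:
    """One sentence of a document with the entities fully contained in it."""

    index: int
    start: int
    end: int
    entity_ids: tuple[str, ...] = ()


@dataclass
class AnnotatedDocument:
    """Document text plus entity and relation annotations (brat semantics)."""

    doc_id: str
    text: str
    entities: dict[str, EntityMention] = field(default_factory=dict)
    relations: dict[str, RelationMention] = field(default_factory=dict)
    sentences: list[SentenceSpan] = field(default_factory=list)
    #: relation ids whose arguments lie in different sentences (set by
    #: :func:`segment_and_bind`).
    cross_sentence: set[str] = field(default_factory=set)

    def entity_sentence(self, entity_id: str) -> int | None:
        """Return the index of the sentence an entity is bound to."""
        for sent in self.sentences:
            if entity_id in sent.entity_ids:
                return sent.index
        return None

    def signature_of(self, rel: RelationMention) -> RelationSignature:
        e1 = self.entities[rel.arg1]
        e2 = self.entities[rel.arg2]
        return RelationSignature(e1.etype, rel.predicate, e2.etype)

    def relation_signatures(self) -> Counter:
        return Counter(self.signature_of(r) for r in self.relations.values())


_T_LINE = re.compile(r"^(T\S+)\t(\S+) ([\d;\s]+)\t(.*)$", re.DOTALL)
_R_LINE = re.compile(r"^(R\S+)\t(\S+) Arg1:(\S+) Arg2:(\S+)\s*$")


def read_brat_document(
    txt_content: str,
    ann_content: str,
    doc_id: str = "doc",
    type_map: Mapping[str, str] | None = None,
) -> AnnotatedDocument:
    """Parse a paired ``.txt``/``.ann`` brat document.

    ``T`` lines become :class:`EntityMention`; discontinuous spans
    (``start end;start end``) are collapsed to their envelope.  ``R`` lines
    become :class:`RelationMention`.  Other annotation kinds are ignored.
    Entity labels are renamed through ``type_map`` when present.

    Raises
    ------
    BratFormatError
        If an entity span falls outside the text or a relation references
        a missing entity id.
    """
    if type_map is None:
        type_map = DEFAULT_TYPE_MAP
    doc = AnnotatedDocument(doc_id=doc_id, text=txt_content)
    pending_relations: list[tuple[str, str, str, str]] = []
    for raw_line in ann_content.splitlines():
        line = raw_line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("T"):
            m = _T_LINE.match(line)
            if m is None:
                raise BratFormatError(f"{doc_id}: malformed T line: {line!r}")
            tid, label, span_text, _surface = m.groups()
            offsets: list[int] = []
            for fragment in span_text.split(";"):
                parts = fragment.split()
                if len(parts) != 2:
                    raise BratFormatError(f"{doc_id}: bad span in {tid}: {span_text!r}")
                offsets.extend(int(p) for p in parts)
            start, end = min(offsets), max(offsets)
            if end > len(txt_content) or start < 0 or start >= end:
                raise BratFormatError(
                    f"{doc_id}: entity {tid} span [{start}, {end}) outside text of "
                    f"length {len(txt_content)}"
                )
            etype = type_map.get(label, label)
            doc.entities[tid] = EntityMention(
                id=tid, etype=etype, start=start, end=end, surface=txt_content[start:end]
            )
        elif line.startswith("R"):
            m = _R_LINE.match(line)
            if m is None:
                raise BratFormatError(f"{doc_id}: malformed R line: {line!r}")
            pending_relations.append(m.groups())
        # A/#/E/N lines etc. are ignorable per the standoff contract.
    for rid, predicate, arg1, arg2 in pending_relations:
        for arg in (arg1, arg2):
            if arg not in doc.entities:
                raise BratFormatError(f"{doc_id}: relation {rid} references missing entity {arg}")
        doc.relations[rid] = RelationMention(id=rid, predicate=predicate, arg1=arg1, arg2=arg2)
    return doc


def write_brat_document(doc: AnnotatedDocument) -> tuple[str, str]:
    """Serialise a document back to ``(txt_content, ann_content)``.

    Round trip: ``read_brat_document(*write_brat_document(doc))`` reproduces
    the entities and relations exactly.
    """
    lines: list[str] = []
    for ent in doc.entities.values():
        surface = doc.text[ent.start : ent.end].replace("\n", " ")
        lines.append(f"{ent.id}\t{ent.etype} {ent.start} {ent.end}\t{surface}")
    for rel in doc.relations.values():
        lines.append(f"{rel.id}\t{rel.predicate} Arg1:{rel.arg1} Arg2:{rel.arg2}")
    ann = "\n".join(lines)
    if lines:
        ann += "\n"
    return doc.text, ann


_SENT_BOUNDARY = re.compile(r"(?<=[.!?])\s+")


def regex_sentence_splitter(text: str) -> list[tuple[int, int]]:
    """Default segmenter: split after sentence-final punctuation.

    Returns character spans that tile the text (trailing whitespace is
    attached to the preceding sentence).
    """
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _SENT_BOUNDARY.finditer(text):
        spans.append((start, m.end()))
        start = m.end()
    if start < len(text):
        spans.append((start, len(text)))
    if not spans and text:
        spans = [(0, len(text))]
    return spans


Segmenter = Callable[[str], list[tuple[int, int]]]


def segment_and_bind(
    doc: AnnotatedDocument, segmenter: Segmenter = regex_sentence_splitter
) -> AnnotatedDocument:
    """Populate sentence spans and bind each entity to its sentence.

    Entities that straddle a proposed boundary force a merge of the two
    sentences, so no gold entity is ever split.  Relations whose arguments
    end up in different sentences are flagged in ``doc.cross_sentence``.
    Returns ``doc`` (modified in place) for convenience.
    """
    if not doc.text:
        raise ValueError(f"{doc.doc_id}: cannot segment empty text")
    spans = [list(s) for s in segmenter(doc.text)]
    # Merge sentences until every entity is fully inside one span.
    merged = True
    while merged:
        merged = False
        for ent in doc.entities.values():
            for i, (s, e) in enumerate(spans):
                if s <= ent.start < e and ent.end > e:
                    spans[i][1] = spans[i + 1][1]
                    del spans[i + 1]
                    merged = True
                    break
            if merged:
                break
    sentences: list[SentenceSpan] = []
    for idx, (s, e) in enumerate(spans):
        ids = tuple(
            sorted(
                (ent.id for ent in doc.entities.values() if s <= ent.start and ent.end <= e),
                key=lambda t: (doc.entities[t].start, doc.entities[t].end, t),
            )
        )
        sentences.append(SentenceSpan(index=idx, start=s, end=e, entity_ids=ids))
    doc.sentences = sentences
    doc.cross_sentence = set()
    for rel in doc.relations.values():
        s1 = doc.entity_sentence(rel.arg1)
        s2 = doc.entity_sentence(rel.arg2)
        if s1 is None or s2 is None or s1 != s2:
            doc.cross_sentence.add(rel.id)
    return doc


def select_studied_signatures(
    corpus: Iterable[AnnotatedDocument], min_count: int = 100
) -> list[tuple[RelationSignature, int]]:
    """Signatures attested at least ``min_count`` times, most frequent first."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: Counter = Counter()
    for doc in corpus:
        counts.update(doc.relation_signatures())
    selected = [(sig, n) for sig, n in counts.items() if n >= min_count]
    selected.sort(key=lambda item: (-item[1], str(item[0])))
    return selected


def collapse_characteristic_subtypes(
    corpus: Sequence[AnnotatedDocument],
    subtypes: Sequence[str] = CHARACTERISTIC_SUBTYPES,
    collapsed_label: str = CHARACTERISTIC_LABEL,
) -> list[AnnotatedDocument]:
    """Relabel every entity of a configured subtype to the collapsed label.

    Idempotent; relation count is conserved (signatures merge accordingly).
    """
    subtype_set = set(subtypes)
    out: list[AnnotatedDocument] = []
    for doc in corpus:
        entities = {
            tid: (replace(ent, etype=collapsed_label) if ent.etype in subtype_set else ent)
            for tid, ent in doc.entities.items()
        }
        out.append(
            AnnotatedDocument(
                doc_id=doc.doc_id,
                text=doc.text,
                entities=entities,
                relations=dict(doc.relations),
                sentences=list(doc.sentences),
                cross_sentence=set(doc.cross_sentence),
            )
        )
    return out
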
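"""Sentential co-occurrence baseline with semantic type constraints.

Every same-sentence ordered entity pair whose types match a relation
signature is emitted as an instance of that relation — the simplest
possible extractor, and an upper bound on the recall of any sentence-bound
method.  An optional filter drops relations whose two arguments annotate
the identical character span (two readings of the same string); it is OFF
by default to match the uncontrolled baseline.
"""

from __future__ import annotations

from typing import Iterable

from relexkit.corpus import AnnotatedDocument, RelationMention, RelationSignature

__all__ = ["extract_cooccurrence_relations", "same_string_filter"]


def extract_cooccurrence_relations(
    doc: AnnotatedDocument, signature: RelationSignature
) -> set[RelationMention]:
    """All same-sentence ordered pairs satisfying the signature's types.

    Requires the document to be segmented (``doc.sentences`` populated).
    When the two argument types are equal, both orderings are emitted.
    """
    if not doc.sentences:
        raise ValueError(f"{doc.doc_id}: document must be segmented first")
    out: set[RelationMention] = set()
    counter = 0
    for sent in doc.sentences:
        ents = [doc.entities[i] for i in sent.entity_ids]
        for a in ents:
            if a.etype != signature.arg1_type:
                continue
            for b in ents:
                if b.id == a.id or b.etype != signature.arg2_type:
                    continue
                counter += 1
                out.add(
                    RelationMention(
                        id=f"C{counter}",
                        predicate=signature.predicate,
                        arg1=a.id,
                        arg2=b.id,
                    )
                )
    return out


def same_string_filter(
    relations: Iterable[RelationMention],
    doc: AnnotatedDocument,
    enabled: bool = True,
) -> set[RelationMention]:
    """Drop relations whose two arguments cover the identical span.

    Partially overlapping (non-identical) spans are kept.  With
    ``enabled=False`` this is the identity.
    """
    rels = set(relations)
    if not enabled:
        return rels
    return {
        r
        for r in rels
        if doc.entities[r.arg1].span != doc.entities[r.arg2].span
    }
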
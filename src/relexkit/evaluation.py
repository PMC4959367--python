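"""Relation matching, F-beta metrics, and k-fold cross-validation.

Predictions match gold relations on (predicate, arg1 span, arg2 span)
after deduplication of identical tuples on both sides.  Cross-sentence
gold relations are unreachable by sentence-bound extractors and count as
false negatives.  Both macro-over-folds and pooled-micro aggregates are
always reported, since fold-level averaging conventions differ.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from relexkit.corpus import AnnotatedDocument, RelationMention, RelationSignature

__all__ = [
    "ConfusionCounts",
    "MetricRecord",
    "FoldPlan",
    "fbeta",
    "match_predictions",
    "make_folds",
    "cross_validate",
    "ExtractorFactory",
]

MACRO = "macro_over_folds"
MICRO = "pooled_micro"


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0


@dataclass
class MetricRecord:
    signature: RelationSignature
    precision: float
    recall: float
    fbeta: float
    beta: float
    fold: int | str
    counts: ConfusionCounts | None = None
    aggregation: str | None = None


def fbeta(p: float, r: float, beta: float = 0.5) -> float:
    """Weighted harmonic mean (1+β²)PR / (β²P + R); 0 when P = R = 0."""
    if not (0.0 <= p <= 1.0 and 0.0 <= r <= 1.0):
        raise ValueError("precision and recall must be fractions in [0, 1]")
    if beta <= 0:
        raise ValueError("beta must be positive")
    denom = beta * beta * p + r
    if denom == 0:
        return 0.0
    return (1 + beta * beta) * p * r / denom


def _relation_key(doc: AnnotatedDocument, rel: RelationMention) -> tuple:
    e1 = doc.entities[rel.arg1]
    e2 = doc.entities[rel.arg2]
    return (rel.predicate, e1.span, e2.span)


def match_predictions(
    predicted: Iterable[RelationMention],
    gold: Iterable[RelationMention],
    doc: AnnotatedDocument,
) -> ConfusionCounts:
    """Exact-span matching: TP iff predicate and both argument spans agree.

    Identical tuples are deduplicated on both sides before counting.
    """
    pred_keys = {_relation_key(doc, r) for r in predicted}
    gold_keys = {_relation_key(doc, r) for r in gold}
    tp = len(pred_keys & gold_keys)
    return ConfusionCounts(tp=tp, fp=len(pred_keys) - tp, fn=len(gold_keys) - tp)


def gold_relations(
    doc: AnnotatedDocument, signature: RelationSignature
) -> set[RelationMention]:
    return {
        r for r in doc.relations.values() if doc.signature_of(r) == signature
    }


@dataclass
class FoldPlan:
    seed: int
    groups: list[list[str]]  # file (document) ids per fold

    @property
    def n_folds(self) -> int:
        return len(self.groups)


def make_folds(files: Sequence[str], n_folds: int, seed: int) -> FoldPlan:
    """Seeded permutation of files dealt into near-equal contiguous groups."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    order = list(files)
    random.Random(seed).shuffle(order)
    base, extra = divmod(len(order), n_folds)
    groups: list[list[str]] = []
    pos = 0
    for i in range(n_folds):
        size = base + (1 if i < extra else 0)
        groups.append(order[pos : pos + size])
        pos += size
    return FoldPlan(seed=seed, groups=groups)


# extractor factory: train on docs, return a per-document predictor
ExtractorFactory = Callable[
    [Sequence[AnnotatedDocument], RelationSignature],
    Callable[[AnnotatedDocument], set[RelationMention]],
]


def cross_validate(
    corpus: Sequence[AnnotatedDocument],
    factory: ExtractorFactory,
    signature: RelationSignature,
    plan: FoldPlan,
    beta: float = 0.5,
) -> list[MetricRecord]:
    """Per-fold metrics plus macro-over-folds and pooled-micro aggregates.

    A fold with zero gold relations has undefined recall; it is skipped in
    the macro average while its counts still pool into the micro aggregate.
    """
    by_id = {doc.doc_id: doc for doc in corpus}
    records: list[MetricRecord] = []
    pooled = ConfusionCounts()
    per_fold: list[tuple[float, float, float]] = []
    for fold_idx, test_ids in enumerate(plan.groups):
        train_docs = [
            by_id[d] for g_idx, g in enumerate(plan.groups) if g_idx != fold_idx for d in g
        ]
        test_docs = [by_id[d] for d in test_ids]
        predictor = factory(train_docs, signature)
        counts = ConfusionCounts()
        for doc in test_docs:
            counts = counts + match_predictions(
                predictor(doc), gold_relations(doc, signature), doc
            )
        pooled = pooled + counts
        p, r = counts.precision, counts.recall
        f = fbeta(p, r, beta)
        has_gold = counts.tp + counts.fn > 0
        records.append(
            MetricRecord(
                signature=signature, precision=p, recall=r, fbeta=f, beta=beta,
                fold=fold_idx, counts=counts,
            )
        )
        if has_gold:
            per_fold.append((p, r, f))
    if per_fold:
        mp = sum(x[0] for x in per_fold) / len(per_fold)
        mr = sum(x[1] for x in per_fold) / len(per_fold)
        mf = sum(x[2] for x in per_fold) / len(per_fold)
    else:
        mp = mr = mf = 0.0
    records.append(
        MetricRecord(
            signature=signature, precision=mp, recall=mr, fbeta=mf, beta=beta,
            fold="aggregate", aggregation=MACRO,
        )
    )
    p, r = pooled.precision, pooled.recall
    records.append(
        MetricRecord(
            signature=signature, precision=p, recall=r, fbeta=fbeta(p, r, beta),
            beta=beta, fold="aggregate", counts=pooled, aggregation=MICRO,
        )
    )
    return records
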
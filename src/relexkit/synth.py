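"""Synthetic brat-format corpus generator with a planted-truth oracle.

Documents are built from templated SVO/prepositional sentences whose slots
are filled with typed entity surfaces.  Same-sentence candidate pairs of a
configured relation signature become gold relations with a planting
probability; positives carry a lexical trigger verb between the arguments
(except under noise), negatives a neutral connector (except under noise).
A configurable fraction of gold relations is re-homed across a sentence
boundary, distractor entities create controlled baseline false positives,
and surfaces can carry a second entity type (same-string multi-type
annotations).  Everything is deterministic per seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from relexkit.corpus import (
    AnnotatedDocument,
    EntityMention,
    RelationMention,
    RelationSignature,
    segment_and_bind,
)

__all__ = [
    "EntityTypeSpec",
    "SignatureSpec",
    "SynthConfig",
    "PlantedRelation",
    "SynthOracle",
    "default_synth_config",
    "generate_corpus",
    "describe_corpus",
    "oracle_tsv",
]


@dataclass(frozen=True)
class EntityTypeSpec:
    name: str
    lexicon: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.lexicon:
            raise ValueError(f"entity type {self.name!r} has an empty lexicon")


@dataclass(frozen=True)
class SignatureSpec:
    signature: RelationSignature
    triggers: tuple[str, ...]
    plant_prob: float = 1.0

    def __post_init__(self) -> None:
        if not self.triggers:
            raise ValueError(f"signature {self.signature} has no trigger lexicon")
        if not 0.0 <= self.plant_prob <= 1.0:
            raise ValueError("plant_prob must be in [0, 1]")


@dataclass
class SynthConfig:
    seed: int = 0
    n_docs: int = 20
    sentences_per_doc: tuple[int, int] = (3, 6)
    entity_types: tuple[EntityTypeSpec, ...] = ()
    signatures: tuple[SignatureSpec, ...] = ()
    neutral_connectors: tuple[str, ...] = ("accompanied", "preceded")
    noise_rate: float = 0.0  # ε: positive loses its trigger / negative gains one
    distractor_rate: float = 0.0
    cross_sentence_fraction: float = 0.0
    same_string_multitype_rate: float = 0.0
    #: type -> alternate type used for same-string double annotations
    metonym_types: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rate in (
            self.noise_rate,
            self.distractor_rate,
            self.cross_sentence_fraction,
            self.same_string_multitype_rate,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("all rates must lie in [0, 1]")
        type_names = {t.name for t in self.entity_types}
        for spec in self.signatures:
            for t in (spec.signature.arg1_type, spec.signature.arg2_type):
                if t not in type_names:
                    raise ValueError(
                        f"signature {spec.signature} uses type {t!r} absent from the inventory"
                    )

    def type_spec(self, name: str) -> EntityTypeSpec:
        for t in self.entity_types:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclass(frozen=True)
class PlantedRelation:
    doc_id: str
    relation_id: str
    signature: RelationSignature
    arg1_span: tuple[int, int]
    arg2_span: tuple[int, int]
    cross_sentence: bool
    trigger: str | None


@dataclass
class SynthOracle:
    """Exact record of everything planted, keyed by document."""

    relations: list[PlantedRelation] = field(default_factory=list)

    def by_signature(self) -> dict[RelationSignature, int]:
        counts: dict[RelationSignature, int] = {}
        for rel in self.relations:
            counts[rel.signature] = counts.get(rel.signature, 0) + 1
        return counts

    def cross_fraction(self) -> float:
        if not self.relations:
            return 0.0
        return sum(r.cross_sentence for r in self.relations) / len(self.relations)


def default_synth_config(
    seed: int = 0,
    n_docs: int = 20,
    plant_prob: float = 0.6,
    noise_rate: float = 0.0,
    distractor_rate: float = 0.3,
    cross_sentence_fraction: float = 0.0,
    same_string_multitype_rate: float = 0.0,
    sentences_per_doc: tuple[int, int] = (3, 6),
) -> SynthConfig:
    """A ready-to-use inventory mirroring a variant-curation corpus."""
    entity_types = (
        EntityTypeSpec("cohort", ("patients", "individuals", "families", "carriers", "probands")),
        EntityTypeSpec(
            "disease",
            ("colorectal cancer", "lynch syndrome", "endometrial cancer", "polyposis",
             "ovarian cancer"),
        ),
        EntityTypeSpec("gene", ("MLH1", "MSH2", "APC", "TP53", "BRCA1", "PMS2")),
        EntityTypeSpec(
            "mutation",
            ("missense variants", "frameshift deletions", "splice mutations",
             "truncating mutations", "germline substitutions"),
        ),
        EntityTypeSpec("size", ("57", "112", "23", "408", "96")),
    )
    signatures = (
        SignatureSpec(
            RelationSignature("cohort", "has", "disease"),
            triggers=("developed", "suffered", "presented"),
            plant_prob=plant_prob,
        ),
        SignatureSpec(
            RelationSignature("gene", "has", "mutation"),
            triggers=("harboured", "carried", "contained"),
            plant_prob=plant_prob,
        ),
        SignatureSpec(
            RelationSignature("cohort", "has", "mutation"),
            triggers=("showed", "exhibited", "displayed"),
            plant_prob=plant_prob,
        ),
    )
    return SynthConfig(
        seed=seed,
        n_docs=n_docs,
        sentences_per_doc=sentences_per_doc,
        entity_types=entity_types,
        signatures=signatures,
        noise_rate=noise_rate,
        distractor_rate=distractor_rate,
        cross_sentence_fraction=cross_sentence_fraction,
        same_string_multitype_rate=same_string_multitype_rate,
        metonym_types={"disease": "cohort"},
    )


@dataclass
class _DocBuilder:
    doc_id: str
    parts: list[str] = field(default_factory=list)
    cursor: int = 0
    entities: dict[str, EntityMention] = field(default_factory=dict)
    relations: dict[str, RelationMention] = field(default_factory=dict)
    t_counter: int = 0
    r_counter: int = 0

    def append_text(self, text: str) -> None:
        self.parts.append(text)
        self.cursor += len(text)

    def add_entity(self, etype: str, surface: str) -> EntityMention:
        start = self.cursor
        self.append_text(surface)
        self.t_counter += 1
        ent = EntityMention(
            id=f"T{self.t_counter}", etype=etype, start=start, end=self.cursor, surface=surface
        )
        self.entities[ent.id] = ent
        return ent

    def annotate_span(self, etype: str, start: int, end: int, surface: str) -> EntityMention:
        self.t_counter += 1
        ent = EntityMention(
            id=f"T{self.t_counter}", etype=etype, start=start, end=end, surface=surface
        )
        self.entities[ent.id] = ent
        return ent

    def add_relation(self, predicate: str, arg1: str, arg2: str) -> RelationMention:
        self.r_counter += 1
        rel = RelationMention(
            id=f"R{self.r_counter}", predicate=predicate, arg1=arg1, arg2=arg2
        )
        self.relations[rel.id] = rel
        return rel

    def finish(self) -> AnnotatedDocument:
        doc = AnnotatedDocument(
            doc_id=self.doc_id,
            text="".join(self.parts),
            entities=self.entities,
            relations=self.relations,
        )
        return segment_and_bind(doc)


def _maybe_metonym(
    builder: _DocBuilder, ent: EntityMention, cfg: SynthConfig, rng: random.Random
) -> None:
    alt = cfg.metonym_types.get(ent.etype)
    if alt is not None and rng.random() < cfg.same_string_multitype_rate:
        builder.annotate_span(alt, ent.start, ent.end, ent.surface)


def generate_corpus(cfg: SynthConfig) -> tuple[list[AnnotatedDocument], SynthOracle]:
    """Generate a segmented corpus and the oracle of planted truth."""
    if not cfg.entity_types or not cfg.signatures:
        raise ValueError("config must declare entity types and signatures")
    rng = random.Random(cfg.seed)
    docs: list[AnnotatedDocument] = []
    oracle = SynthOracle()
    for d in range(cfg.n_docs):
        builder = _DocBuilder(doc_id=f"synth{d:04d}")
        n_sent = rng.randint(*cfg.sentences_per_doc)
        s = 0
        while s < n_sent:
            spec = rng.choice(cfg.signatures)
            sig = spec.signature
            surf1 = rng.choice(cfg.type_spec(sig.arg1_type).lexicon)
            surf2 = rng.choice(cfg.type_spec(sig.arg2_type).lexicon)
            is_gold = rng.random() < spec.plant_prob
            cross = is_gold and rng.random() < cfg.cross_sentence_fraction
            if is_gold and rng.random() >= cfg.noise_rate:
                connector = rng.choice(spec.triggers)
            elif not is_gold and rng.random() < cfg.noise_rate:
                connector = rng.choice(spec.triggers)  # noisy negative
            else:
                connector = rng.choice(cfg.neutral_connectors)
            if cross:
                # two sentences; the relation spans the boundary
                builder.append_text("The ")
                e1 = builder.add_entity(sig.arg1_type, surf1)
                _maybe_metonym(builder, e1, cfg, rng)
                builder.append_text(f" {connector} several notable outcomes. ")
                builder.append_text("These outcomes involved the ")
                e2 = builder.add_entity(sig.arg2_type, surf2)
                _maybe_metonym(builder, e2, cfg, rng)
                builder.append_text(" in this study. ")
                rel = builder.add_relation(sig.predicate, e1.id, e2.id)
                oracle.relations.append(
                    PlantedRelation(
                        doc_id=builder.doc_id,
                        relation_id=rel.id,
                        signature=sig,
                        arg1_span=e1.span,
                        arg2_span=e2.span,
                        cross_sentence=True,
                        trigger=connector,
                    )
                )
                s += 2
                continue
            frame = rng.randrange(3)
            if frame == 0:
                builder.append_text("The ")
            elif frame == 1:
                builder.append_text("In this study the ")
            else:
                builder.append_text("Notably the ")
            e1 = builder.add_entity(sig.arg1_type, surf1)
            _maybe_metonym(builder, e1, cfg, rng)
            builder.append_text(f" {connector} the ")
            e2 = builder.add_entity(sig.arg2_type, surf2)
            _maybe_metonym(builder, e2, cfg, rng)
            if rng.random() < cfg.distractor_rate:
                # distractor of the arg1 type after the pair: a baseline
                # false positive candidate with no trigger between
                d_surf = rng.choice(cfg.type_spec(sig.arg1_type).lexicon)
                builder.append_text(" near the ")
                d_ent = builder.add_entity(sig.arg1_type, d_surf)
                _maybe_metonym(builder, d_ent, cfg, rng)
            builder.append_text(". ")
            if is_gold:
                rel = builder.add_relation(sig.predicate, e1.id, e2.id)
                oracle.relations.append(
                    PlantedRelation(
                        doc_id=builder.doc_id,
                        relation_id=rel.id,
                        signature=sig,
                        arg1_span=e1.span,
                        arg2_span=e2.span,
                        cross_sentence=False,
                        trigger=connector if connector in spec.triggers else None,
                    )
                )
            s += 1
        docs.append(builder.finish())
    return docs, oracle


def describe_corpus(corpus: Sequence[AnnotatedDocument]) -> dict:
    """Per-signature relation counts, entity counts, cross-sentence stats."""
    sig_counts: dict[str, int] = {}
    entity_counts: dict[str, int] = {}
    n_cross = 0
    n_rel = 0
    for doc in corpus:
        for ent in doc.entities.values():
            entity_counts[ent.etype] = entity_counts.get(ent.etype, 0) + 1
        for rel in doc.relations.values():
            n_rel += 1
            key = str(doc.signature_of(rel))
            sig_counts[key] = sig_counts.get(key, 0) + 1
            if rel.id in doc.cross_sentence:
                n_cross += 1
    return {
        "n_docs": len(corpus),
        "n_relations": n_rel,
        "n_cross_sentence": n_cross,
        "cross_sentence_fraction": (n_cross / n_rel) if n_rel else 0.0,
        "signature_counts": dict(sorted(sig_counts.items())),
        "entity_counts": dict(sorted(entity_counts.items())),
    }


def oracle_tsv(oracle: SynthOracle) -> str:
    """Serialise the oracle to a TSV (one planted relation per row)."""
    lines = ["doc_id\trelation_id\tsignature\targ1_span\targ2_span\tcross_sentence\ttrigger"]
    for r in oracle.relations:
        lines.append(
            "\t".join(
                [
                    r.doc_id,
                    r.relation_id,
                    str(r.signature),
                    f"{r.arg1_span[0]}:{r.arg1_span[1]}",
                    f"{r.arg2_span[0]}:{r.arg2_span[1]}",
                    str(int(r.cross_sentence)),
                    r.trigger or "-",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def synth_trigger_verb_forms(cfg: SynthConfig) -> dict[str, str]:
    """form -> lemma map covering the config's triggers and connectors.

    Surface forms are their own lemmas (the generator emits one inflection
    per trigger, so identity keeps adapter and verb lexicon consistent).
    """
    words = set(cfg.neutral_connectors)
    for spec in cfg.signatures:
        words.update(spec.triggers)
    return {w: w for w in sorted(words)}


def synth_verb_lexicon(cfg: SynthConfig) -> dict[str, str]:
    """Trigger lemma -> relation-verb class table for the feature rules."""
    lexicon: dict[str, str] = {}
    for spec in cfg.signatures:
        cls = str(spec.signature).upper().replace("-", "_")
        for trig in spec.triggers:
            lexicon[trig] = cls
    return lexicon
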
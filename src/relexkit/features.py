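"""The 19 feature rules turning an (entity pair, parsed sentence) context
into a named feature vector.

Seven syntactic rules (verb in dependency path, no-verb, clause presence,
clause distance, same head, full tree path, path length), eight lexical
rules (negation, voice, words between, surface distance, left/right entity
windows, nominalization, weak nominalization) and four supplementary rules
(entities between, which entities, entity counts, entity order), plus the
entity type tags that every vector carries.

Feature extraction is a pure function of (context, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from relexkit.corpus import EntityMention
from relexkit.parse import (
    DOWN,
    UP,
    ConstituencyNode,
    ParsedSentence,
    anchor_entity_node,
    dependency_path,
    find_head_token,
    path_tokens,
)

__all__ = [
    "RuleConfig",
    "EntityPairContext",
    "DEFAULT_VERB_LEXICON",
    "DEFAULT_NOMINALIZATION_LEXICON",
    "DEFAULT_NEGATION_WORDS",
    "NO_CLAUSE_SENTINEL",
    "extract_feature_vector",
    "verb_in_dependency_path",
    "no_verb_in_dependency_path",
    "clause_features",
    "same_head_and_path_features",
    "negation_feature",
    "voice_feature",
    "lexical_window_features",
    "nominalization_features",
    "supplementary_features",
    "vectorize",
]

#: verb lemma -> relation-verb class; small editable seed table.
DEFAULT_VERB_LEXICON: dict[str, str] = {
    "reduce": "DOWN_REGULATE",
    "decrease": "DOWN_REGULATE",
    "inhibit": "DOWN_REGULATE",
    "suppress": "DOWN_REGULATE",
    "increase": "UP_REGULATE",
    "activate": "UP_REGULATE",
    "enhance": "UP_REGULATE",
    "induce": "UP_REGULATE",
    "regulate": "REGULATE",
    "affect": "ASSOCIATE",
    "associate": "ASSOCIATE",
    "cause": "CAUSE",
    "carry": "HAVE",
    "harbour": "HAVE",
    "harbor": "HAVE",
    "have": "HAVE",
    "develop": "HAVE",
    "suffer": "HAVE",
    "show": "SHOW",
    "display": "SHOW",
    "exhibit": "SHOW",
    "involve": "ASSOCIATE",
}

#: Seed list of nominalized biomedical verb forms (user-extensible).
DEFAULT_NOMINALIZATION_LEXICON: frozenset[str] = frozenset(
    {
        "mutation", "deletion", "insertion", "inhibition", "activation",
        "expression", "regulation", "association", "interaction",
        "phosphorylation", "methylation", "reduction", "induction",
        "suppression", "translocation", "amplification", "substitution",
    }
)

DEFAULT_NEGATION_WORDS: frozenset[str] = frozenset(
    {"no", "not", "never", "without", "neither", "nor", "fail", "fails",
     "failed", "lack", "lacks", "lacked", "absent", "unable"}
)

#: Sentinel emitted for clause distances when the sentence has no clause.
NO_CLAUSE_SENTINEL = 999


@dataclass
class RuleConfig:
    """Knobs shared by the feature rules."""

    window_k: int = 3
    verb_lexicon: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_VERB_LEXICON))
    nominalization_lexicon: frozenset[str] = DEFAULT_NOMINALIZATION_LEXICON
    negation_words: frozenset[str] = DEFAULT_NEGATION_WORDS

    def __post_init__(self) -> None:
        if self.window_k < 1:
            raise ValueError("window_k must be >= 1")


@dataclass
class EntityPairContext:
    """Two same-sentence entities with their anchored nodes and head tokens.

    ``e1`` precedes ``e2`` in text order; ``arg_order`` records whether the
    signature's first argument is the textually first entity.
    """

    e1: EntityMention
    e2: EntityMention
    parsed: ParsedSentence
    sentence_entities: Sequence[EntityMention] = ()
    arg_order: str = "forward"  # forward: e1 is the signature's arg1

    def __post_init__(self) -> None:
        if self.e1.start > self.e2.start or (
            self.e1.start == self.e2.start and self.e1.end > self.e2.end
        ):
            raise ValueError("e1 must precede e2 in text order")
        self._e1_tokens = self.parsed.tokens_in_char_span(self.e1.start, self.e1.end)
        self._e2_tokens = self.parsed.tokens_in_char_span(self.e2.start, self.e2.end)
        if not self._e1_tokens or not self._e2_tokens:
            raise ValueError("entities must be covered by the parsed sentence")
        self.e1_head = self.parsed.entity_head_token(self._e1_tokens)
        self.e2_head = self.parsed.entity_head_token(self._e2_tokens)
        self.e1_node = anchor_entity_node(self._e1_tokens, self.parsed)
        self.e2_node = anchor_entity_node(self._e2_tokens, self.parsed)

    @property
    def e1_tokens(self) -> list[int]:
        return self._e1_tokens

    @property
    def e2_tokens(self) -> list[int]:
        return self._e2_tokens


def _path(ctx: EntityPairContext) -> list[tuple[str, str]]:
    return dependency_path(ctx.parsed.dep, ctx.e1_head, ctx.e2_head)


def _interior_path_tokens(ctx: EntityPairContext) -> list[int]:
    toks = path_tokens(ctx.parsed.dep, ctx.e1_head, ctx.e2_head)
    return [t for t in toks if t not in (ctx.e1_head, ctx.e2_head)]


def _path_verbs(ctx: EntityPairContext) -> list[int]:
    return [
        t for t in _interior_path_tokens(ctx)
        if ctx.parsed.tokens[t].simple_pos == "verb"
    ]


def verb_in_dependency_path(ctx: EntityPairContext, cfg: RuleConfig) -> dict:
    """Rule 1: labeled dependency path anchored on the root-most path verb."""
    verbs = _path_verbs(ctx)
    if not verbs:
        return {"verb_in_path": False}
    anchor = min(verbs, key=lambda t: (ctx.parsed.dep.depth(t), t))
    steps = _path(ctx)
    signature = " AND ".join(f"{lbl}{d}" for lbl, d in steps)
    directions = "".join(sorted({d for _, d in steps}))
    lemma = ctx.parsed.tokens[anchor].lemma
    feats = {
        "verb_in_path": True,
        "path_signature": signature,
        "verb_lemma": lemma,
        "directions": directions,
    }
    if lemma in cfg.verb_lexicon:
        feats["relation_verb_class"] = cfg.verb_lexicon[lemma]
    return feats


def no_verb_in_dependency_path(ctx: EntityPairContext, cfg: RuleConfig) -> dict:
    """Rule 2: gate — true iff no verb lies on the inter-entity path."""
    return {"no_verb": not _path_verbs(ctx)}


def _sbar_nodes(tree: ConstituencyNode) -> list[ConstituencyNode]:
    return [n for n in tree.iter_nodes() if n.label == "SBAR"]


def clause_features(ctx: EntityPairContext) -> dict:
    """Rules 3–4: clause (SBAR) presence and distances to entities.

    ``sbar_between`` is true when the entities fall in different clauses:
    either an SBAR lies strictly between them, or exactly one of the two
    sits inside an SBAR.
    """
    sbars = _sbar_nodes(ctx.parsed.tree)
    e1_span = (min(ctx.e1_tokens), max(ctx.e1_tokens) + 1)
    e2_span = (min(ctx.e2_tokens), max(ctx.e2_tokens) + 1)
    if not sbars:
        return {
            "contains_clause": False,
            "sbar_between": False,
            "clause_distance_left": NO_CLAUSE_SENTINEL,
            "clause_distance_right": NO_CLAUSE_SENTINEL,
        }
    between = False
    for node in sbars:
        s, e = node.span
        inside1 = s <= e1_span[0] and e1_span[1] <= e
        inside2 = s <= e2_span[0] and e2_span[1] <= e
        if inside1 != inside2:
            between = True
        if e1_span[1] <= s and e <= e2_span[0]:
            between = True

    def signed_distance(span: tuple[int, int]) -> int:
        best = None
        for node in sbars:
            s, e = node.span
            for boundary in (s, e):
                if boundary >= span[1]:
                    d = boundary - span[1] + 1  # clause to the right
                elif boundary <= span[0]:
                    d = -(span[0] - boundary + 1)  # clause to the left
                else:
                    d = 0
                if best is None or abs(d) < abs(best):
                    best = d
        return best if best is not None else NO_CLAUSE_SENTINEL

    return {
        "contains_clause": True,
        "sbar_between": between,
        "clause_distance_left": signed_distance(e1_span),
        "clause_distance_right": signed_distance(e2_span),
    }


def same_head_and_path_features(ctx: EntityPairContext) -> dict:
    """Rules 5–7: shared parent, constituency path, and its length.

    The "full tree path" rule is ambiguous between constituency and
    dependency labels, so both are emitted under distinct names.
    """
    parents = ctx.parsed.tree.parent_map()

    def lift(node: ConstituencyNode) -> ConstituencyNode:
        # maximal projection: highest ancestor covering the identical span
        while id(node) in parents and parents[id(node)].span == node.span:
            node = parents[id(node)]
        return node

    e1_node = lift(ctx.e1_node)
    e2_node = lift(ctx.e2_node)
    p1 = parents.get(id(e1_node))
    p2 = parents.get(id(e2_node))
    same = p1 is not None and p1 is p2

    # ancestor chains from each anchored node to the root
    def chain(node: ConstituencyNode) -> list[ConstituencyNode]:
        out = [node]
        while id(out[-1]) in parents:
            out.append(parents[id(out[-1])])
        return out

    c1 = chain(e1_node)
    c2 = chain(e2_node)
    ids2 = {id(n): i for i, n in enumerate(c2)}
    lca_i1 = next(i for i, n in enumerate(c1) if id(n) in ids2)
    lca_i2 = ids2[id(c1[lca_i1])]
    up = c1[: lca_i1 + 1]
    down = list(reversed(c2[:lca_i2]))
    labels = [n.label for n in up] + [n.label for n in down]
    dep_steps = _path(ctx)
    return {
        "same_head": same,
        "full_tree_path": "-".join(labels),
        "full_dep_path": " ".join(f"{lbl}{d}" for lbl, d in dep_steps),
        "path_length": len(labels) - 1,
    }


def negation_feature(ctx: EntityPairContext, cfg: RuleConfig) -> dict:
    """Rule 8: negation scoped to the inter-entity relation.

    True iff a ``neg`` arc attaches to a token on the dependency path, or a
    lexicon negation word modifies the anchored path verb.
    """
    on_path = set(path_tokens(ctx.parsed.dep, ctx.e1_head, ctx.e2_head))
    dep = ctx.parsed.dep
    for head, child, label in dep.arcs():
        if label == "neg" and head in on_path:
            return {"negated": True}
    verbs = _path_verbs(ctx)
    for v in verbs:
        for child in dep.children(v):
            if ctx.parsed.tokens[child].lemma in cfg.negation_words:
                return {"negated": True}
        # a semantically negative word governing the path verb also negates
        head = dep.heads[v]
        if head >= 0 and ctx.parsed.tokens[head].lemma in cfg.negation_words:
            return {"negated": True}
    return {"negated": False}


def voice_feature(ctx: EntityPairContext) -> dict:
    """Rule 9: passive voice via an auxpass arc into a path verb."""
    on_path = set(path_tokens(ctx.parsed.dep, ctx.e1_head, ctx.e2_head))
    for head, child, label in ctx.parsed.dep.arcs():
        if label == "auxpass" and head in on_path:
            if ctx.parsed.tokens[head].simple_pos == "verb":
                return {"passive": True}
    return {"passive": False}


def lexical_window_features(ctx: EntityPairContext, cfg: RuleConfig) -> dict:
    """Rules 10–13: words between, surface distance, entity windows."""
    toks = ctx.parsed.tokens
    e1_last = max(ctx.e1_tokens)
    e2_first = min(ctx.e2_tokens)
    e1_first = min(ctx.e1_tokens)
    e2_last = max(ctx.e2_tokens)
    between = [toks[i].surface for i in range(e1_last + 1, e2_first)]
    k = cfg.window_k
    left = [(toks[i].surface, toks[i].pos) for i in range(max(0, e1_first - k), e1_first)]
    right = [
        (toks[i].surface, toks[i].pos)
        for i in range(e2_last + 1, min(len(toks), e2_last + 1 + k))
    ]
    return {
        "words_between": tuple(between),
        "surface_distance": e2_last - e1_first + 1,
        "window_left_e1": tuple(left),
        "window_right_e2": tuple(right),
    }


def nominalization_features(ctx: EntityPairContext, cfg: RuleConfig) -> dict:
    """Rules 14–15: strict and weak nominalization patterns.

    Strict: a lexicon nominalization relates both entities — it lies on the
    verb-free dependency path between the two entity heads.  Weak: exactly
    one entity sits after a preposition with a lexicon nominalization ahead
    of that preposition.
    """
    toks = ctx.parsed.tokens
    lexicon = cfg.nominalization_lexicon
    feats: dict = {
        "nominalization": False,
        "weak_nominalization": False,
        "nominalization_side": "none",
        "nominalization_distance": 0,
    }
    if not lexicon:
        return feats
    interior = _interior_path_tokens(ctx)
    nominal_on_path = [
        t for t in interior
        if toks[t].lemma in lexicon and toks[t].simple_pos == "noun"
    ]
    if nominal_on_path and not _path_verbs(ctx):
        nom = nominal_on_path[0]
        d1 = abs(nom - ctx.e1_head)
        d2 = abs(nom - ctx.e2_head)
        feats["nominalization"] = True
        feats["nominalization_side"] = "left" if nom < (ctx.e1_head + ctx.e2_head) / 2 else "right"
        feats["nominalization_distance"] = min(d1, d2)
        return feats

    def entity_in_weak_pattern(first_tok: int) -> bool:
        if first_tok == 0:
            return False
        prep = first_tok - 1
        if toks[prep].pos not in ("IN", "TO"):
            return False
        return any(toks[i].lemma in lexicon for i in range(prep))

    hits = sum(
        entity_in_weak_pattern(first)
        for first in (min(ctx.e1_tokens), min(ctx.e2_tokens))
    )
    if hits == 1:
        feats["weak_nominalization"] = True
    return feats


def supplementary_features(ctx: EntityPairContext) -> dict:
    """Rules 16–19 plus the entity-type tags carried by every vector."""
    between_types = sorted(
        e.etype
        for e in ctx.sentence_entities
        if e.start >= ctx.e1.end and e.end <= ctx.e2.start
        and e.id not in (ctx.e1.id, ctx.e2.id)
    )
    if ctx.arg_order == "forward":
        t1, t2 = ctx.e1.etype, ctx.e2.etype
    else:
        t1, t2 = ctx.e2.etype, ctx.e1.etype
    return {
        "n_entities_between": len(between_types),
        "entities_between_types": tuple(between_types),
        "entity_counts": len(ctx.sentence_entities),
        "entity_order": f"{t1}<{t2}" if ctx.arg_order == "forward" else f"{t1}>{t2}",
        "e1_type": t1,
        "e2_type": t2,
    }


def extract_feature_vector(ctx: EntityPairContext, cfg: RuleConfig) -> dict:
    """All 19 rules concatenated under stable names; deterministic."""
    fv: dict = {}
    fv.update(verb_in_dependency_path(ctx, cfg))
    fv.update(no_verb_in_dependency_path(ctx, cfg))
    fv.update(clause_features(ctx))
    fv.update(same_head_and_path_features(ctx))
    fv.update(negation_feature(ctx, cfg))
    fv.update(voice_feature(ctx))
    fv.update(lexical_window_features(ctx, cfg))
    fv.update(nominalization_features(ctx, cfg))
    fv.update(supplementary_features(ctx))
    return fv


def lexical_only_vector(
    e1: EntityMention,
    e2: EntityMention,
    sentence_text: str,
    sentence_start: int,
    sentence_entities: Sequence[EntityMention],
    cfg: RuleConfig,
    arg_order: str = "forward",
) -> dict:
    """Fallback vector for unparsed sentences: surface-token rules only."""
    words = sentence_text.split()
    # crude whitespace alignment
    offsets = []
    pos = 0
    for w in words:
        i = sentence_text.index(w, pos)
        offsets.append((sentence_start + i, sentence_start + i + len(w)))
        pos = i + len(w)
    e1_toks = [i for i, (s, e) in enumerate(offsets) if s < e1.end and e > e1.start]
    e2_toks = [i for i, (s, e) in enumerate(offsets) if s < e2.end and e > e2.start]
    between = (
        tuple(words[max(e1_toks) + 1 : min(e2_toks)]) if e1_toks and e2_toks else ()
    )
    between_types = sorted(
        e.etype
        for e in sentence_entities
        if e.start >= e1.end and e.end <= e2.start and e.id not in (e1.id, e2.id)
    )
    t1, t2 = (e1.etype, e2.etype) if arg_order == "forward" else (e2.etype, e1.etype)
    return {
        "words_between": between,
        "n_entities_between": len(between_types),
        "entities_between_types": tuple(between_types),
        "entity_counts": len(sentence_entities),
        "entity_order": f"{t1}<{t2}" if arg_order == "forward" else f"{t1}>{t2}",
        "e1_type": t1,
        "e2_type": t2,
    }


def vectorize(fv: Mapping) -> dict[str, float]:
    """Flatten a named feature vector into classifier features.

    Booleans and categoricals become ``name=value`` indicators; integers are
    kept numeric; token sequences are emitted both as one joined categorical
    and as per-item indicators.
    """
    out: dict[str, float] = {}
    for name in sorted(fv):
        value = fv[name]
        if isinstance(value, bool):
            out[f"{name}={value}"] = 1.0
        elif isinstance(value, (int, float)):
            out[name] = float(value)
        elif isinstance(value, str):
            out[f"{name}={value}"] = 1.0
        elif isinstance(value, tuple):
            joined = "_".join(
                "/".join(item) if isinstance(item, tuple) else str(item) for item in value
            )
            out[f"{name}={joined}"] = 1.0
            for item in value:
                key = "/".join(item) if isinstance(item, tuple) else str(item)
                out[f"{name}:{key}"] = 1.0
        else:
            raise TypeError(f"unsupported feature value for {name!r}: {value!r}")
    return out
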
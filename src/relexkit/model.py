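"""MaxEnt classification and structured inference for relation extraction.

Contains the L-BFGS-trained maximum entropy model, the exact dynamic
program for non-overlapping ARG/NONE assignment over a constituency tree,
the bottom-up top-k joint semantic typing re-ranker, trigger proposal with
the iterative trigger/argument optimisation, and the per-signature relation
classifiers used in evaluation.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from relexkit.corpus import (
    AnnotatedDocument,
    EntityMention,
    RelationMention,
    RelationSignature,
)
from relexkit.features import (
    EntityPairContext,
    RuleConfig,
    extract_feature_vector,
    lexical_only_vector,
    vectorize,
)
from relexkit.parse import ConstituencyNode, ParsedSentence, ParserAdapter, ParseFailure

__all__ = [
    "MaxEntModel",
    "ConstantModel",
    "NodeAssignment",
    "JointTyping",
    "TriggerCandidate",
    "train_maxent",
    "label_arguments_nonoverlap",
    "topk_joint_semantic_typing",
    "propose_triggers",
    "iterate_trigger_entity",
    "candidate_pairs",
    "train_relation_classifier",
    "predict_relations",
]


# --------------------------------------------------------------------------
# MaxEnt (multinomial logistic regression, L-BFGS, zero-initialised)
# --------------------------------------------------------------------------


@dataclass
class MaxEntModel:
    labels: list[str]
    feature_names: list[str]
    weights: np.ndarray  # shape (n_labels, n_features + 1); last column bias
    l2: float
    iterations: int = 0
    converged: bool = False

    def _row(self, features: Mapping[str, float]) -> np.ndarray:
        x = np.zeros(len(self.feature_names) + 1)
        index = self._feature_index
        for name, value in features.items():
            j = index.get(name)
            if j is not None:
                x[j] = value
        x[-1] = 1.0
        return x

    @property
    def _feature_index(self) -> dict[str, int]:
        cache = getattr(self, "_fidx", None)
        if cache is None:
            cache = {name: j for j, name in enumerate(self.feature_names)}
            object.__setattr__(self, "_fidx", cache)
        return cache

    def predict_proba(self, features: Mapping[str, float]) -> dict[str, float]:
        scores = self.weights @ self._row(features)
        scores -= scores.max()
        exp = np.exp(scores)
        probs = exp / exp.sum()
        return {label: float(p) for label, p in zip(self.labels, probs)}

    def predict(self, features: Mapping[str, float]) -> str:
        probs = self.predict_proba(features)
        return max(sorted(probs), key=lambda lbl: probs[lbl])

    # -- versioned text serialisation -------------------------------------
    def dumps(self) -> str:
        label_field = "\t".join(self.labels)
        lines = ["relexkit-maxent 1", f"l2 {self.l2!r}", f"labels {label_field}"]
        for j, name in enumerate(self.feature_names + ["__bias__"]):
            col = "\t".join(repr(float(w)) for w in self.weights[:, j])
            lines.append(f"w {name}\t{col}")
        return "\n".join(lines) + "\n"

    @classmethod
    def loads(cls, text: str) -> "MaxEntModel":
        lines = text.splitlines()
        if not lines or not lines[0].startswith("relexkit-maxent"):
            raise ValueError("not a relexkit model file")
        l2 = float(lines[1].split(" ", 1)[1])
        labels = lines[2].split(" ", 1)[1].split("\t")
        names: list[str] = []
        cols: list[list[float]] = []
        for line in lines[3:]:
            if not line.startswith("w "):
                continue
            name, *vals = line[2:].split("\t")
            names.append(name)
            cols.append([float(v) for v in vals])
        assert names[-1] == "__bias__"
        weights = np.array(cols).T
        return cls(labels=labels, feature_names=names[:-1], weights=weights, l2=l2)


def train_maxent(
    examples: Sequence[tuple[Mapping[str, float], str]],
    labels: Sequence[str] | None = None,
    l2: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> MaxEntModel:
    """Fit an L2-penalised multinomial logistic model with L-BFGS.

    Deterministic: zero-initialised weights, fixed example order.  Raises if
    a declared label has no examples or a feature value is non-finite.
    """
    if not examples:
        raise ValueError("no training examples")
    seen_labels = {y for _, y in examples}
    if labels is None:
        label_list = sorted(seen_labels)
    else:
        label_list = list(labels)
        missing = set(label_list) - seen_labels
        if missing:
            raise ValueError(f"labels with no training examples: {sorted(missing)}")
    if len(label_list) < 2:
        raise ValueError("need at least two labels")
    names = sorted({name for fv, _ in examples for name in fv})
    name_index = {n: j for j, n in enumerate(names)}
    n, d, k = len(examples), len(names) + 1, len(label_list)
    X = np.zeros((n, d))
    y = np.zeros(n, dtype=int)
    label_index = {lbl: i for i, lbl in enumerate(label_list)}
    for i, (fv, lbl) in enumerate(examples):
        for name, value in fv.items():
            if not math.isfinite(value):
                raise ValueError(f"non-finite feature value for {name!r}")
            X[i, name_index[name]] = value
        X[i, -1] = 1.0
        y[i] = label_index[lbl]

    onehot = np.zeros((n, k))
    onehot[np.arange(n), y] = 1.0
    history: list[float] = []

    def objective(flat: np.ndarray) -> tuple[float, np.ndarray]:
        W = flat.reshape(k, d)
        scores = X @ W.T
        scores -= scores.max(axis=1, keepdims=True)
        exp = np.exp(scores)
        probs = exp / exp.sum(axis=1, keepdims=True)
        ll = np.sum(np.log(probs[np.arange(n), y] + 1e-300))
        penalty = 0.5 * l2 * np.sum(W[:, :-1] ** 2)
        nll = -ll + penalty
        grad = (probs - onehot).T @ X
        grad[:, :-1] += l2 * W[:, :-1]
        history.append(nll)
        return nll, grad.ravel()

    result = minimize(
        objective,
        np.zeros(k * d),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": tol},
    )
    return MaxEntModel(
        labels=label_list,
        feature_names=names,
        weights=result.x.reshape(k, d),
        l2=l2,
        iterations=int(result.nit),
        converged=bool(result.success),
    )


@dataclass
class ConstantModel:
    """Degenerate predictor used when training data has a single class."""

    label: str
    labels: list[str] = field(default_factory=list)

    def predict(self, features: Mapping[str, float]) -> str:
        return self.label

    def predict_proba(self, features: Mapping[str, float]) -> dict[str, float]:
        return {lbl: (1.0 if lbl == self.label else 0.0) for lbl in (self.labels or [self.label])}


# --------------------------------------------------------------------------
# Non-overlap dynamic program (ARG / NONE)
# --------------------------------------------------------------------------


@dataclass
class NodeAssignment:
    """Optimal ARG/NONE labeling of tree nodes under non-overlap."""

    labels: dict[int, str]  # id(node) -> "ARG" | "NONE"
    score: float

    def arg_nodes(self, tree: ConstituencyNode) -> list[ConstituencyNode]:
        return [n for n in tree.iter_nodes() if self.labels[id(n)] == "ARG"]


def label_arguments_nonoverlap(
    tree: ConstituencyNode, node_probs: Mapping[int, float]
) -> NodeAssignment:
    """Maximise ∏ P(chosen label) s.t. no ARG dominates another ARG.

    ``node_probs`` maps ``id(node)`` to P(ARG).  Exact optimum via the
    bottom-up dynamic program; ties resolved toward NONE for determinism.
    """

    def solve(node: ConstituencyNode) -> tuple[float, float, dict[int, str], dict[int, str]]:
        # returns (best score, all-NONE score, best labels, all-NONE labels)
        p = node_probs[id(node)]
        if not (0.0 <= p <= 1.0):
            raise ValueError("node probability outside [0, 1]")
        child_results = [solve(c) for c in node.children]
        none_below = 1.0
        none_labels: dict[int, str] = {id(node): "NONE"}
        for _, nb, _, nl in child_results:
            none_below *= nb
            none_labels.update(nl)
        all_none_score = (1.0 - p) * none_below

        arg_score = p * none_below
        arg_labels = dict(none_labels)
        arg_labels[id(node)] = "ARG"

        free_score = 1.0 - p
        free_labels: dict[int, str] = {id(node): "NONE"}
        for best, _, bl, _ in child_results:
            free_score *= best
            free_labels.update(bl)

        if arg_score > free_score:
            return arg_score, all_none_score, arg_labels, none_labels
        return free_score, all_none_score, free_labels, none_labels

    best, _, labels, _ = solve(tree)
    return NodeAssignment(labels=labels, score=best)


# --------------------------------------------------------------------------
# Top-k joint semantic typing
# --------------------------------------------------------------------------


@dataclass
class JointTyping:
    """One joint assignment of semantic types (or NONE) to all tree nodes."""

    labels: dict[int, str]  # id(node) -> type or "NONE"
    probability: float
    rank: int = 0


def topk_joint_semantic_typing(
    tree: ConstituencyNode,
    type_probs: Mapping[int, Mapping[str, float]],
    k: int = 5,
) -> list[JointTyping]:
    """Up to ``k`` best joint labelings under the non-overlap constraint.

    A non-NONE node forces every descendant to NONE.  Bottom-up: each
    sub-tree keeps its own top-k candidate list; at internal nodes the
    NONE case merges children candidate lists with a lazy k-best product.
    Ties broken by lexicographically smallest labeling (preorder).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    order = list(tree.iter_nodes())
    preorder_pos = {id(n): i for i, n in enumerate(order)}

    def key_of(labels: dict[int, str]) -> tuple[str, ...]:
        return tuple(labels[id(n)] for n in order if id(n) in labels)

    def none_prob_below(node: ConstituencyNode) -> float:
        p = type_probs[id(node)].get("NONE", 0.0)
        for c in node.children:
            p *= none_prob_below(c)
        return p

    def solve(node: ConstituencyNode) -> list[tuple[float, dict[int, str]]]:
        dist = type_probs[id(node)]
        total = sum(dist.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("node type distribution must sum to 1")
        candidates: list[tuple[float, dict[int, str]]] = []
        # node is an argument: all descendants NONE
        below = 1.0
        none_below_labels: dict[int, str] = {}
        for c in node.children:
            below *= none_prob_below(c)
            for d in c.iter_nodes():
                none_below_labels[id(d)] = "NONE"
        for t, p in dist.items():
            if t == "NONE":
                continue
            labels = dict(none_below_labels)
            labels[id(node)] = t
            candidates.append((p * below, labels))
        # node is NONE: combine children top-k lists
        p_none = dist.get("NONE", 0.0)
        child_lists = [solve(c) for c in node.children]
        if all(child_lists) or not node.children:
            for prob, parts in _kbest_product(child_lists, k):
                labels: dict[int, str] = {id(node): "NONE"}
                for part in parts:
                    labels.update(part)
                candidates.append((p_none * prob, labels))
        candidates.sort(key=lambda item: (-item[0], key_of(item[1])))
        return candidates[:k]

    results = solve(tree)
    return [
        JointTyping(labels=labels, probability=prob, rank=i)
        for i, (prob, labels) in enumerate(results)
    ]


def _kbest_product(
    lists: list[list[tuple[float, dict[int, str]]]], k: int
) -> list[tuple[float, list[dict[int, str]]]]:
    """Top-k combinations (by probability product) of one pick per list."""
    if not lists:
        return [(1.0, [])]
    if any(not lst for lst in lists):
        return []
    start = tuple(0 for _ in lists)

    def prob_of(idx: tuple[int, ...]) -> float:
        p = 1.0
        for lst, i in zip(lists, idx):
            p *= lst[i][0]
        return p

    heap = [(-prob_of(start), start)]
    seen = {start}
    out: list[tuple[float, list[dict[int, str]]]] = []
    while heap and len(out) < k:
        neg, idx = heapq.heappop(heap)
        out.append((-neg, [lists[j][i][1] for j, i in enumerate(idx)]))
        for j in range(len(lists)):
            nxt = idx[:j] + (idx[j] + 1,) + idx[j + 1 :]
            if nxt[j] < len(lists[j]) and nxt not in seen:
                seen.add(nxt)
                heapq.heappush(heap, (-prob_of(nxt), nxt))
    return out


# --------------------------------------------------------------------------
# Trigger proposal and iterative optimisation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TriggerCandidate:
    token: int
    source: str  # verb_lexicon | nominalization | classifier
    score: float


def propose_triggers(
    parsed: ParsedSentence,
    cfg: RuleConfig,
    model: MaxEntModel | None = None,
    threshold: float = 0.5,
    trigger_features: Callable[[ParsedSentence, int], Mapping[str, float]] | None = None,
) -> list[TriggerCandidate]:
    """Union of lexicon-matched and classifier-scored trigger candidates."""
    candidates: dict[int, TriggerCandidate] = {}
    for tok in parsed.tokens:
        if tok.simple_pos == "verb" and tok.lemma in cfg.verb_lexicon:
            candidates[tok.index] = TriggerCandidate(tok.index, "verb_lexicon", 1.0)
        elif tok.lemma in cfg.nominalization_lexicon:
            candidates[tok.index] = TriggerCandidate(tok.index, "nominalization", 1.0)
    if model is not None:
        featurise = trigger_features or _default_trigger_features
        for tok in parsed.tokens:
            if tok.index in candidates:
                continue
            probs = model.predict_proba(featurise(parsed, tok.index))
            score = probs.get("TRIGGER", 0.0)
            if score > threshold:
                candidates[tok.index] = TriggerCandidate(tok.index, "classifier", score)
    return sorted(candidates.values(), key=lambda c: (-c.score, c.token))


def _default_trigger_features(parsed: ParsedSentence, index: int) -> dict[str, float]:
    tok = parsed.tokens[index]
    return vectorize(
        {
            "lemma": tok.lemma,
            "pos": tok.pos,
            "simple_pos": tok.simple_pos,
            "dep_label": parsed.dep.labels[index],
            "is_root": parsed.dep.root == index,
        }
    )


def iterate_trigger_entity(
    parsed: ParsedSentence,
    cfg: RuleConfig,
    arg_probs: Callable[[ParsedSentence, Sequence[TriggerCandidate]], Mapping[int, float]],
    trigger_model: MaxEntModel | None = None,
    rounds: int = 2,
) -> tuple[list[TriggerCandidate], NodeAssignment]:
    """Alternate trigger proposal and non-overlap argument labeling.

    ``arg_probs`` maps (sentence, current triggers) to per-node P(ARG)
    keyed by ``id(node)``.  Stops at ``rounds`` or earlier on a fixed point.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    triggers = propose_triggers(parsed, cfg, trigger_model)
    assignment = _label_for_triggers(parsed, triggers, arg_probs)
    for _ in range(rounds - 1):
        new_triggers = propose_triggers(parsed, cfg, trigger_model)
        new_assignment = _label_for_triggers(parsed, new_triggers, arg_probs)
        if new_triggers == triggers and new_assignment.labels == assignment.labels:
            break
        triggers, assignment = new_triggers, new_assignment
    return triggers, assignment


def _label_for_triggers(parsed, triggers, arg_probs) -> NodeAssignment:
    if not triggers:
        return NodeAssignment(
            labels={id(n): "NONE" for n in parsed.tree.iter_nodes()}, score=1.0
        )
    probs = arg_probs(parsed, triggers)
    full = {id(n): probs.get(id(n), 0.0) for n in parsed.tree.iter_nodes()}
    return label_arguments_nonoverlap(parsed.tree, full)


# --------------------------------------------------------------------------
# Per-signature relation classifiers (gold-entity evaluation protocol)
# --------------------------------------------------------------------------


def candidate_pairs(
    doc: AnnotatedDocument, signature: RelationSignature
) -> list[tuple[EntityMention, EntityMention, int]]:
    """All same-sentence ordered gold entity pairs matching the signature.

    Returns (arg1 entity, arg2 entity, sentence index); when the two
    argument types are equal both orderings are distinct candidates.
    """
    out = []
    for sent in doc.sentences:
        ents = [doc.entities[i] for i in sent.entity_ids]
        for a in ents:
            if a.etype != signature.arg1_type:
                continue
            for b in ents:
                if b.id == a.id or b.etype != signature.arg2_type:
                    continue
                out.append((a, b, sent.index))
    return out


def _pair_features(
    doc: AnnotatedDocument,
    a: EntityMention,
    b: EntityMention,
    sent_index: int,
    cfg: RuleConfig,
    parses: Mapping[int, ParsedSentence],
) -> dict[str, float]:
    sent = doc.sentences[sent_index]
    ents = [doc.entities[i] for i in sent.entity_ids]
    e1, e2 = (a, b) if a.start <= b.start else (b, a)
    order = "forward" if e1 is a else "reversed"
    parsed = parses.get(sent_index)
    if parsed is not None:
        try:
            ctx = EntityPairContext(
                e1=e1, e2=e2, parsed=parsed, sentence_entities=ents, arg_order=order
            )
            return vectorize(extract_feature_vector(ctx, cfg))
        except ValueError:
            pass
    fv = lexical_only_vector(
        e1, e2, doc.text[sent.start : sent.end], sent.start, ents, cfg, arg_order=order
    )
    return vectorize(fv)


def _doc_parses(
    doc: AnnotatedDocument, adapter: ParserAdapter | None
) -> dict[int, ParsedSentence]:
    parses: dict[int, ParsedSentence] = {}
    if adapter is None:
        return parses
    for sent in doc.sentences:
        try:
            parses[sent.index] = adapter.parse(
                doc.text[sent.start : sent.end].rstrip()
            )
        except ParseFailure:
            continue  # unparsed sentences fall back to lexical features
        parsed = parses[sent.index]
        # adapters return sentence-local offsets; re-anchor into doc space
        if parsed.char_offset == 0 and sent.start != 0:
            parsed.char_offset = sent.start
            for t in parsed.tokens:
                object.__setattr__(t, "char_start", t.char_start + sent.start)
                object.__setattr__(t, "char_end", t.char_end + sent.start)
    return parses


def _gold_pair_keys(doc: AnnotatedDocument, signature: RelationSignature) -> set:
    keys = set()
    for rel in doc.relations.values():
        if doc.signature_of(rel) != signature:
            continue
        e1, e2 = doc.entities[rel.arg1], doc.entities[rel.arg2]
        keys.add((e1.span, e2.span))
    return keys


def train_relation_classifier(
    corpus: Sequence[AnnotatedDocument],
    signature: RelationSignature,
    cfg: RuleConfig,
    adapter: ParserAdapter | None = None,
    l2: float = 1.0,
) -> MaxEntModel | ConstantModel:
    """Binary present/absent classifier over signature-matching gold pairs.

    Positives are candidate pairs attested as gold relations of this
    signature; negatives are the remaining candidates.  With no negatives
    the degenerate always-positive predictor is returned; with no positives
    an error naming the signature is raised.
    """
    examples: list[tuple[dict[str, float], str]] = []
    for doc in corpus:
        gold = _gold_pair_keys(doc, signature)
        parses = _doc_parses(doc, adapter)
        for a, b, sent_index in candidate_pairs(doc, signature):
            label = "REL" if (a.span, b.span) in gold else "NONE"
            examples.append((_pair_features(doc, a, b, sent_index, cfg, parses), label))
    n_pos = sum(1 for _, y in examples if y == "REL")
    if n_pos == 0:
        raise ValueError(f"no positive training candidates for signature {signature}")
    if n_pos == len(examples):
        return ConstantModel(label="REL", labels=["NONE", "REL"])
    return train_maxent(examples, labels=["NONE", "REL"], l2=l2)


def predict_relations(
    model: MaxEntModel | ConstantModel,
    doc: AnnotatedDocument,
    signature: RelationSignature,
    cfg: RuleConfig,
    adapter: ParserAdapter | None = None,
) -> set[RelationMention]:
    """Classify every same-sentence candidate pair; emit the positives.

    By construction the output is a subset of the co-occurrence baseline's
    extractions on the same inputs.
    """
    parses = _doc_parses(doc, adapter)
    out: set[RelationMention] = set()
    for i, (a, b, sent_index) in enumerate(candidate_pairs(doc, signature)):
        fv = _pair_features(doc, a, b, sent_index, cfg, parses)
        if model.predict(fv) == "REL":
            out.add(
                RelationMention(
                    id=f"P{i+1}", predicate=signature.predicate, arg1=a.id, arg2=b.id
                )
            )
    return out
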
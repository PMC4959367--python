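"""Shared fixtures: hand-built parses, random trees, and brute-force oracles.

The oracles here are deliberately independent of the library code paths
they check: exhaustive enumeration for the tree labeling problems and a
plain double loop for co-occurrence extraction.
"""

from __future__ import annotations

import itertools
import random

import pytest

from relexkit.corpus import RelationSignature
from relexkit.parse import (
    ConstituencyNode,
    DependencyGraph,
    ParsedSentence,
    SimpleEnglishAdapter,
    Token,
    phrase,
    pre_terminal,
)


@pytest.fixture(scope="session")
def adapter():
    return SimpleEnglishAdapter()


def make_tokens(spec: list[tuple[str, str]], lemmas: dict[str, str] | None = None):
    """Build a token list from (surface, POS) pairs; offsets from joining
    with single spaces."""
    lemmas = lemmas or {}
    tokens = []
    pos = 0
    for i, (surface, tag) in enumerate(spec):
        tokens.append(
            Token(
                index=i,
                surface=surface,
                lemma=lemmas.get(surface, surface.lower()),
                pos=tag,
                char_start=pos,
                char_end=pos + len(surface),
            )
        )
        pos += len(surface) + 1
    return tokens


def hand_parse(
    token_spec: list[tuple[str, str]],
    heads: list[int],
    labels: list[str],
    tree: ConstituencyNode,
    lemmas: dict[str, str] | None = None,
) -> ParsedSentence:
    tokens = make_tokens(token_spec, lemmas)
    return ParsedSentence(tokens=tokens, dep=DependencyGraph(heads, labels), tree=tree)


@pytest.fixture
def epa_parse(adapter):
    """The dose-dependent down-regulation sentence, parsed by the adapter."""
    return adapter.parse("EPA reduce the vasoconstriction in a dose-dependent manner")


# --------------------------------------------------------------------------
# Random trees and exhaustive oracles
# --------------------------------------------------------------------------


def random_tree(n_nodes: int, rng: random.Random) -> ConstituencyNode:
    """A random rooted tree of n nodes; leaves become pre-terminals."""
    assert n_nodes >= 1
    children: dict[int, list[int]] = {i: [] for i in range(n_nodes)}
    for i in range(1, n_nodes):
        children[rng.randrange(i)].append(i)
    next_token = itertools.count()

    def build(i: int) -> ConstituencyNode:
        if not children[i]:
            return pre_terminal("NN", next(next_token))
        return phrase("XP", *[build(c) for c in children[i]])

    return build(0)


def brute_force_nonoverlap(tree: ConstituencyNode, probs: dict[int, float]):
    """Best ARG/NONE labeling by exhaustive enumeration over 2^n options."""
    nodes = list(tree.iter_nodes())
    parents = tree.parent_map()

    def ancestors(node):
        out = []
        while id(node) in parents:
            node = parents[id(node)]
            out.append(node)
        return out

    best_score, best_labels = -1.0, None
    for bits in itertools.product([False, True], repeat=len(nodes)):
        chosen = {id(n) for n, b in zip(nodes, bits) if b}
        valid = all(
            not any(id(a) in chosen for a in ancestors(n))
            for n, b in zip(nodes, bits)
            if b
        )
        if not valid:
            continue
        score = 1.0
        for n, b in zip(nodes, bits):
            score *= probs[id(n)] if b else 1.0 - probs[id(n)]
        labels = {id(n): ("ARG" if b else "NONE") for n, b in zip(nodes, bits)}
        if score > best_score:
            best_score, best_labels = score, labels
    return best_score, best_labels


def brute_force_topk(tree: ConstituencyNode, dists: dict[int, dict[str, float]], k: int):
    """Top-k valid joint typings by full enumeration and filtering."""
    nodes = list(tree.iter_nodes())
    parents = tree.parent_map()

    def ancestors(node):
        out = []
        while id(node) in parents:
            node = parents[id(node)]
            out.append(node)
        return out

    label_sets = [sorted(dists[id(n)]) for n in nodes]
    results = []
    for combo in itertools.product(*label_sets):
        assignment = {id(n): lbl for n, lbl in zip(nodes, combo)}
        valid = True
        for n, lbl in zip(nodes, combo):
            if lbl != "NONE" and any(assignment[id(a)] != "NONE" for a in ancestors(n)):
                valid = False
                break
        if not valid:
            continue
        prob = 1.0
        for n, lbl in zip(nodes, combo):
            prob *= dists[id(n)][lbl]
        results.append((prob, combo, assignment))
    results.sort(key=lambda item: (-item[0], item[1]))
    return results[:k]


def brute_force_cooccurrence(doc, signature: RelationSignature):
    """Independent double-loop re-implementation of the baseline.

    Returns the set of (predicate, arg1 span, arg2 span) tuples.
    """
    out = set()
    for sent in doc.sentences:
        ents = [doc.entities[i] for i in sent.entity_ids]
        for a in ents:
            for b in ents:
                if a.id == b.id:
                    continue
                if a.etype == signature.arg1_type and b.etype == signature.arg2_type:
                    out.add((signature.predicate, a.span, b.span))
    return out
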
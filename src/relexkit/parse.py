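"""Parsed-sentence substrate: tokens, dependency graph, constituency tree.

Parsing itself is delegated to a pluggable adapter (any object with a
``parse(sentence_text) -> ParsedSentence`` method whose tokenisation is
offset-aligned to the input).  A small deterministic rule-based adapter,
:class:`SimpleEnglishAdapter`, is shipped so the whole pipeline runs with no
external models; tests may also hand-build trees with :func:`pre_terminal`
and :func:`phrase`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Protocol, Sequence

__all__ = [
    "Token",
    "DependencyGraph",
    "ConstituencyNode",
    "ParsedSentence",
    "ParserAdapter",
    "ParseFailure",
    "SimpleEnglishAdapter",
    "simplify_pos",
    "dependency_path",
    "find_head_token",
    "anchor_entity_node",
    "pre_terminal",
    "phrase",
    "UP",
    "DOWN",
]

UP = "↑"  # step toward the dependency head
DOWN = "↓"  # step away from the head


class ParseFailure(RuntimeError):
    """Raised by an adapter when a sentence cannot be parsed."""


@dataclass(frozen=True)
class Token:
    index: int
    surface: str
    lemma: str
    pos: str
    char_start: int
    char_end: int

    @property
    def simple_pos(self) -> str:
        return simplify_pos(self.pos)


def simplify_pos(pos: str) -> str:
    """Collapse a Penn Treebank tag into one of seven coarse categories."""
    if pos.startswith("NN"):
        return "noun"
    if pos.startswith("VB"):
        return "verb"
    if pos.startswith("RB"):
        return "adverb"
    if pos.startswith("JJ"):
        return "adjective"
    if pos == "CD":
        return "number"
    if pos == "FW":
        return "foreign"
    return "other"


class DependencyGraph:
    """Single-head, acyclic dependency structure over a token sequence.

    ``heads[i]`` is the head index of token *i* (-1 for the root) and
    ``labels[i]`` the label of the arc into *i*.
    """

    def __init__(self, heads: Sequence[int], labels: Sequence[str]):
        if len(heads) != len(labels):
            raise ValueError("heads and labels must align")
        self.heads = list(heads)
        self.labels = list(labels)
        roots = [i for i, h in enumerate(self.heads) if h < 0]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]
        for i in range(len(self.heads)):  # acyclicity check
            seen = set()
            j = i
            while j >= 0:
                if j in seen:
                    raise ValueError(f"dependency cycle through token {i}")
                seen.add(j)
                j = self.heads[j]

    def __len__(self) -> int:
        return len(self.heads)

    def children(self, index: int) -> list[int]:
        return [i for i, h in enumerate(self.heads) if h == index]

    def arcs(self) -> Iterator[tuple[int, int, str]]:
        for i, h in enumerate(self.heads):
            if h >= 0:
                yield (h, i, self.labels[i])

    def dependents_with_label(self, index: int, label: str) -> list[int]:
        return [i for i in self.children(index) if self.labels[i] == label]

    def depth(self, index: int) -> int:
        d = 0
        while self.heads[index] >= 0:
            index = self.heads[index]
            d += 1
        return d


def dependency_path(
    dep: DependencyGraph, a: int, b: int
) -> list[tuple[str, str]]:
    """The unique tree path from token ``a`` to ``b``.

    Each step is ``(arc label, direction)`` with :data:`UP` when moving
    toward a head and :data:`DOWN` when moving toward a dependent.
    """
    if a == b:
        return []
    if not (0 <= a < len(dep) and 0 <= b < len(dep)):
        raise ValueError("token index outside sentence")
    ancestors_a = [a]
    i = a
    while dep.heads[i] >= 0:
        i = dep.heads[i]
        ancestors_a.append(i)
    ancestors_b = [b]
    i = b
    while dep.heads[i] >= 0:
        i = dep.heads[i]
        ancestors_b.append(i)
    set_a = set(ancestors_a)
    lca = next(i for i in ancestors_b if i in set_a)
    steps: list[tuple[str, str]] = []
    for node in ancestors_a[: ancestors_a.index(lca)]:
        steps.append((dep.labels[node], UP))
    down_part = ancestors_b[: ancestors_b.index(lca)]
    for node in reversed(down_part):
        steps.append((dep.labels[node], DOWN))
    return steps


def path_tokens(dep: DependencyGraph, a: int, b: int) -> list[int]:
    """All token indices on the path from ``a`` to ``b``, inclusive."""
    if a == b:
        return [a]
    ancestors_a = [a]
    i = a
    while dep.heads[i] >= 0:
        i = dep.heads[i]
        ancestors_a.append(i)
    ancestors_b = [b]
    i = b
    while dep.heads[i] >= 0:
        i = dep.heads[i]
        ancestors_b.append(i)
    set_a = set(ancestors_a)
    lca = next(i for i in ancestors_b if i in set_a)
    up = ancestors_a[: ancestors_a.index(lca) + 1]
    down = ancestors_b[: ancestors_b.index(lca)]
    return up + list(reversed(down))


@dataclass
class ConstituencyNode:
    """A phrase-structure node; pre-terminals subsume exactly one token."""

    label: str
    children: list["ConstituencyNode"] = field(default_factory=list)
    token: int | None = None  # set on pre-terminals only
    _span: tuple[int, int] | None = field(default=None, repr=False)

    @property
    def is_preterminal(self) -> bool:
        return self.token is not None

    @property
    def span(self) -> tuple[int, int]:
        """Half-open token index range covered by this node."""
        if self._span is None:
            if self.is_preterminal:
                self._span = (self.token, self.token + 1)
            else:
                starts = [c.span[0] for c in self.children]
                ends = [c.span[1] for c in self.children]
                self._span = (min(starts), max(ends))
        return self._span

    def iter_nodes(self) -> Iterator["ConstituencyNode"]:
        yield self
        for child in self.children:
            yield from child.iter_nodes()

    def parent_map(self) -> dict[int, "ConstituencyNode"]:
        parents: dict[int, ConstituencyNode] = {}
        for node in self.iter_nodes():
            for child in node.children:
                parents[id(child)] = node
        return parents


def pre_terminal(label: str, token: int) -> ConstituencyNode:
    return ConstituencyNode(label=label, token=token)


def phrase(label: str, *children: ConstituencyNode) -> ConstituencyNode:
    return ConstituencyNode(label=label, children=list(children))


# --------------------------------------------------------------------------
# Collins head finding
# --------------------------------------------------------------------------

# Priority tables: (search direction, ordered tag preferences).  "left"
# scans children left-to-right for each preferred tag in turn.
_HEAD_RULES: dict[str, tuple[str, tuple[str, ...]]] = {
    "ADJP": ("left", ("NNS", "QP", "NN", "$", "ADVP", "JJ", "VBN", "VBG", "ADJP",
                      "JJR", "NP", "JJS", "DT", "FW", "RBR", "RBS", "SBAR", "RB")),
    "ADVP": ("right", ("RB", "RBR", "RBS", "FW", "ADVP", "TO", "CD", "JJR", "JJ",
                       "IN", "NP", "JJS", "NN")),
    "CONJP": ("right", ("CC", "RB", "IN")),
    "FRAG": ("right", ()),
    "INTJ": ("left", ()),
    "LST": ("right", ("LS", ":")),
    "NAC": ("left", ("NN", "NNS", "NNP", "NNPS", "NP", "NAC", "EX", "$", "CD",
                     "QP", "PRP", "VBG", "JJ", "JJS", "JJR", "ADJP", "FW")),
    "PP": ("right", ("IN", "TO", "VBG", "VBN", "RP", "FW")),
    "PRN": ("left", ()),
    "PRT": ("right", ("RP",)),
    "QP": ("left", ("$", "IN", "NNS", "NN", "JJ", "RB", "DT", "CD", "NCD", "QP",
                    "JJR", "JJS")),
    "RRC": ("right", ("VP", "NP", "ADVP", "ADJP", "PP")),
    "S": ("left", ("TO", "IN", "VP", "S", "SBAR", "ADJP", "UCP", "NP")),
    "SBAR": ("left", ("WHNP", "WHPP", "WHADVP", "WHADJP", "IN", "DT", "S", "SQ",
                      "SINV", "SBAR", "FRAG")),
    "SBARQ": ("left", ("SQ", "S", "SINV", "SBARQ", "FRAG")),
    "SINV": ("left", ("VBZ", "VBD", "VBP", "VB", "MD", "VP", "S", "SINV", "ADJP", "NP")),
    "SQ": ("left", ("VBZ", "VBD", "VBP", "VB", "MD", "VP", "SQ")),
    "UCP": ("right", ()),
    "VP": ("left", ("TO", "VBD", "VBN", "MD", "VBZ", "VB", "VBG", "VBP", "VP",
                    "ADJP", "NN", "NNS", "NP")),
    "WHADJP": ("left", ("CC", "WRB", "JJ", "ADJP")),
    "WHADVP": ("right", ("CC", "WRB")),
    "WHNP": ("left", ("WDT", "WP", "WP$", "WHADJP", "WHPP", "WHNP")),
    "WHPP": ("right", ("IN", "TO", "FW")),
}

_NP_RIGHT_FIRST = ("NN", "NNP", "NNPS", "NNS", "NX", "POS", "JJR")
_NP_LEFT_SECOND = ("NP",)
_NP_RIGHT_THIRD = ("$", "ADJP", "PRN")
_NP_RIGHT_FOURTH = ("CD",)
_NP_RIGHT_FIFTH = ("JJ", "JJS", "RB", "QP")


def _head_child(node: ConstituencyNode) -> ConstituencyNode:
    """Pick the head child of an internal node via the Collins tables."""
    children = node.children
    if node.label in ("NP", "NX"):
        if children[-1].label == "POS":
            return children[-1]
        for tags, direction in (
            (_NP_RIGHT_FIRST, "right"),
            (_NP_LEFT_SECOND, "left"),
            (_NP_RIGHT_THIRD, "right"),
            (_NP_RIGHT_FOURTH, "right"),
            (_NP_RIGHT_FIFTH, "right"),
        ):
            order = reversed(children) if direction == "right" else children
            for child in order:
                if child.label in tags:
                    return child
        return children[-1]
    direction, prefs = _HEAD_RULES.get(node.label, ("right", ()))
    for tag in prefs:
        order = children if direction == "left" else list(reversed(children))
        for child in order:
            if child.label == tag:
                return child
    return children[0] if direction == "left" and not prefs else children[-1]


def find_head_token(node: ConstituencyNode) -> int:
    """Head token of a constituency node (Collins head percolation)."""
    while not node.is_preterminal:
        node = _head_child(node)
    return node.token  # type: ignore[return-value]


@dataclass
class ParsedSentence:
    """Tokens + dependency graph + constituency tree for one sentence."""

    tokens: list[Token]
    dep: DependencyGraph
    tree: ConstituencyNode
    char_offset: int = 0  # document offset of the sentence start

    def __post_init__(self) -> None:
        n = len(self.tokens)
        if len(self.dep) != n:
            raise ValueError("dependency graph does not cover the token sequence")
        if self.tree.span != (0, n):
            raise ValueError("constituency tree does not cover the token sequence")

    def tokens_in_char_span(self, start: int, end: int) -> list[int]:
        """Token indices overlapping a document character span."""
        return [
            t.index
            for t in self.tokens
            if t.char_start < end and t.char_end > start
        ]

    def entity_head_token(self, token_indices: Sequence[int]) -> int:
        """The token of a span whose dependency head lies outside the span."""
        inside = set(token_indices)
        for i in token_indices:
            if self.dep.heads[i] not in inside:
                return i
        return token_indices[0]


def anchor_entity_node(
    entity_tokens: Sequence[int], parsed: ParsedSentence
) -> ConstituencyNode:
    """Anchor an entity to the constituency node covering its tokens.

    If no single node covers the full token span, tokens are trimmed from
    the end of the span until a covering node exists; failing that, trimming
    restarts from the beginning.  Ties between several covering nodes go to
    the smallest.  If every trim fails, the pre-terminal of the entity's
    head-most token is returned.
    """
    if not entity_tokens:
        raise ValueError("entity covers no tokens")
    toks = sorted(entity_tokens)
    lo, hi = toks[0], toks[-1] + 1

    def smallest_covering(a: int, b: int) -> ConstituencyNode | None:
        # iter_nodes is preorder, so the last exact match is the deepest
        best: ConstituencyNode | None = None
        for node in parsed.tree.iter_nodes():
            if node.span == (a, b):
                best = node
        return best

    for b in range(hi, lo, -1):  # suffix trimming first
        node = smallest_covering(lo, b)
        if node is not None:
            return node
    for a in range(lo, hi):  # then prefix trimming
        node = smallest_covering(a, hi)
        if node is not None:
            return node
    head = parsed.entity_head_token(toks)
    for node in parsed.tree.iter_nodes():
        if node.is_preterminal and node.token == head:
            return node
    raise ValueError("no pre-terminal for entity head token")


class ParserAdapter(Protocol):
    def parse(self, sentence_text: str) -> ParsedSentence: ...


# --------------------------------------------------------------------------
# Deterministic rule-based adapter
# --------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\w+(?:[-./']\w+)*|\S")

_CLOSED_CLASS: dict[str, str] = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "these": "DT",
    "that": "WDT", "which": "WDT", "who": "WP", "all": "DT", "each": "DT",
    "several": "JJ", "some": "DT", "no": "DT",
    "of": "IN", "in": "IN", "with": "IN", "for": "IN", "by": "IN",
    "on": "IN", "from": "IN", "at": "IN", "near": "IN", "after": "IN",
    "without": "IN", "during": "IN", "among": "IN", "as": "IN",
    "to": "TO", "and": "CC", "or": "CC", "but": "CC",
    "not": "RB", "never": "RB", "also": "RB", "only": "RB",
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
    "been": "VBN", "has": "VBZ", "have": "VBP", "had": "VBD",
    "can": "MD", "may": "MD", "will": "MD", "would": "MD",
    "it": "PRP", "they": "PRP", "we": "PRP",
}

_COPULAS = {"is", "are", "was", "were", "be", "been"}

#: Inflected form -> (lemma, tag); extensible per adapter instance.
_DEFAULT_VERB_FORMS: dict[str, tuple[str, str]] = {}
for _lemma in (
    "reduce", "increase", "decrease", "inhibit", "activate", "regulate",
    "carry", "harbour", "harbor", "develop", "show", "suffer", "involve",
    "display", "exhibit", "affect", "cause", "include", "report", "observe",
    "suggest", "indicate", "enumerate", "contain", "reveal", "express",
    "fail", "lack", "present", "span", "comprise", "mention", "accompany",
    "precede",
):
    _DEFAULT_VERB_FORMS[_lemma] = (_lemma, "VB")
    if _lemma.endswith("y") and _lemma[-2] not in "aeiou":
        _DEFAULT_VERB_FORMS[_lemma[:-1] + "ies"] = (_lemma, "VBZ")
        _DEFAULT_VERB_FORMS[_lemma[:-1] + "ied"] = (_lemma, "VBD")
    else:
        _DEFAULT_VERB_FORMS[_lemma + "s"] = (_lemma, "VBZ")
        _e = _lemma + "d" if _lemma.endswith("e") else _lemma + "ed"
        _DEFAULT_VERB_FORMS[_e] = (_lemma, "VBD")
    _ing = (_lemma[:-1] if _lemma.endswith("e") else _lemma) + "ing"
    _DEFAULT_VERB_FORMS[_ing] = (_lemma, "VBG")

_NUMBER_RE = re.compile(r"^\d+([.,]\d+)?$")


class SimpleEnglishAdapter:
    """Deterministic heuristic parser for simple SVO/prepositional English.

    Built for the controlled vocabulary of templated corpora: a closed-class
    lexicon, a verb-form table (extensible via ``extra_verbs``), and
    suffix heuristics produce POS tags; dependencies and a shallow
    constituency tree come from NP/PP/VP chunking.  Not a general parser —
    the adapter contract lets a real one be dropped in.
    """

    def __init__(self, extra_verbs: Mapping[str, str] | None = None):
        self.verb_forms = dict(_DEFAULT_VERB_FORMS)
        if extra_verbs:
            for form, lemma in extra_verbs.items():
                tag = "VBD" if form.endswith("ed") else ("VBZ" if form.endswith("s") else "VB")
                self.verb_forms[form] = (lemma, tag)

    # -- tagging ----------------------------------------------------------
    def _tag(self, words: list[str]) -> list[tuple[str, str]]:
        tagged: list[tuple[str, str]] = []
        for i, w in enumerate(words):
            lw = w.lower()
            prev = words[i - 1].lower() if i > 0 else ""
            if lw in self.verb_forms:
                lemma, tag = self.verb_forms[lw]
                if tag == "VBD" and prev in _COPULAS:
                    tag = "VBN"
                tagged.append((lemma, tag))
            elif lw in _CLOSED_CLASS:
                tagged.append((lw, _CLOSED_CLASS[lw]))
            elif _NUMBER_RE.match(w) or w == "%":
                tagged.append((w, "CD"))
            elif not w[0].isalnum():
                tagged.append((w, "."))
            elif lw.endswith("ly"):
                tagged.append((lw, "RB"))
            elif "-" in w or lw.endswith(("ous", "ive", "ic", "al", "able")):
                tagged.append((lw, "JJ"))
            elif prev in _COPULAS and lw.endswith("ed"):
                tagged.append((lw[:-1] if lw.endswith("ed") else lw, "VBN"))
            elif w[0].isupper() and i > 0:
                tagged.append((w, "NNP"))
            elif lw.endswith("s") and not lw.endswith("ss"):
                tagged.append((lw[:-1], "NNS"))
            else:
                tagged.append((lw, "NN"))
        return tagged

    # -- chunking ---------------------------------------------------------
    @staticmethod
    def _np_chunks(tags: list[str]) -> list[tuple[int, int]]:
        chunks = []
        i, n = 0, len(tags)
        while i < n:
            if tags[i] == "DT" or tags[i].startswith(("NN", "JJ")) or tags[i] in ("CD", "PRP"):
                j = i
                while j < n and (
                    tags[j] in ("DT", "CD", "PRP") or tags[j].startswith(("NN", "JJ"))
                ):
                    j += 1
                while j > i and not (tags[j - 1].startswith("NN") or tags[j - 1] in ("CD", "PRP")):
                    j -= 1
                if j > i:
                    chunks.append((i, j))
                    i = j
                    continue
            i += 1
        return chunks

    def parse(self, sentence_text: str, char_offset: int = 0) -> ParsedSentence:
        if not sentence_text.strip():
            raise ParseFailure("empty sentence")
        matches = list(_TOKEN_RE.finditer(sentence_text))
        words = [m.group(0) for m in matches]
        tagged = self._tag(words)
        tokens = [
            Token(
                index=i,
                surface=words[i],
                lemma=tagged[i][0],
                pos=tagged[i][1],
                char_start=char_offset + matches[i].start(),
                char_end=char_offset + matches[i].end(),
            )
            for i in range(len(words))
        ]
        tags = [t.pos for t in tokens]
        n = len(tokens)

        np_spans = self._np_chunks(tags)
        in_np = {}
        for span in np_spans:
            for k in range(*span):
                in_np[k] = span
        np_heads = {}
        for a, b in np_spans:
            head = b - 1
            while head > a and not (tags[head].startswith("NN") or tags[head] in ("CD", "PRP")):
                head -= 1
            np_heads[(a, b)] = head

        verb_idxs = [i for i, t in enumerate(tags) if t.startswith("VB") and i not in in_np]
        main_verb = None
        for i in verb_idxs:
            if tokens[i].surface.lower() not in _COPULAS:
                main_verb = i
                break
        if main_verb is None and verb_idxs:
            main_verb = verb_idxs[0]

        heads = [-1] * n
        labels = ["dep"] * n
        passive = main_verb is not None and any(
            tokens[j].surface.lower() in _COPULAS for j in verb_idxs if j < main_verb
        ) and tags[main_verb] == "VBN"

        # NP-internal arcs
        for (a, b), h in np_heads.items():
            for k in range(a, b):
                if k == h:
                    continue
                heads[k] = h
                if tags[k] == "DT":
                    labels[k] = "det"
                elif tags[k].startswith("JJ"):
                    labels[k] = "amod"
                elif tags[k] == "CD":
                    labels[k] = "num"
                else:
                    labels[k] = "nn"

        root = main_verb if main_verb is not None else (
            np_heads[np_spans[0]] if np_spans else 0
        )

        subj_seen = False
        last_attach = root
        for a, b in np_spans:
            h = np_heads[(a, b)]
            if h == root:
                last_attach = h
                continue
            if a > 0 and tags[a - 1] in ("IN", "TO"):
                prep = tokens[a - 1].lemma
                # post-verbal preps attach to the verb unless material after
                # the verb (e.g. an object) has already been attached
                if main_verb is not None and a > main_verb and last_attach < main_verb:
                    heads[h] = main_verb
                else:
                    heads[h] = last_attach
                labels[h] = f"prep_{prep}"
            elif main_verb is not None and b <= main_verb and not subj_seen:
                heads[h] = main_verb
                labels[h] = "nsubjpass" if passive else "nsubj"
                subj_seen = True
            elif main_verb is not None and a > main_verb:
                prev_conj = tags[a - 1] == "CC" if a > 0 else False
                if prev_conj:
                    heads[h] = last_attach
                    labels[h] = f"conj_{tokens[a - 1].lemma}"
                elif labels[h] == "dep" and not any(
                    labels[k].startswith("dobj") for k in range(n) if heads[k] == main_verb
                ):
                    heads[h] = main_verb
                    labels[h] = "dobj"
                else:
                    heads[h] = main_verb
                    labels[h] = "dep"
            else:
                heads[h] = root
                labels[h] = "dep"
            last_attach = h

        for i in range(n):
            if i == root or heads[i] != -1 or i in in_np:
                continue
            if tags[i].startswith("VB") and main_verb is not None and i != main_verb:
                heads[i] = main_verb
                if tokens[i].surface.lower() in _COPULAS:
                    labels[i] = "auxpass" if passive else "aux"
                else:
                    labels[i] = "dep"
            elif tags[i] == "RB":
                target = main_verb if main_verb is not None else root
                heads[i] = target
                labels[i] = "neg" if tokens[i].lemma in ("not", "never") else "advmod"
            elif tags[i] in ("IN", "TO"):
                # collapsed preps: the IN token hangs off its object's head
                obj = None
                for a, b in np_spans:
                    if a == i + 1:
                        obj = np_heads[(a, b)]
                        break
                heads[i] = obj if obj is not None else root
                labels[i] = "prep" if obj is not None else "dep"
            else:
                heads[i] = root
                labels[i] = "punct" if tags[i] == "." else "dep"
        heads[root] = -1
        labels[root] = "root"

        dep = DependencyGraph(heads, labels)
        tree = self._build_tree(tokens, tags, np_spans, main_verb)
        return ParsedSentence(tokens=tokens, dep=dep, tree=tree, char_offset=char_offset)

    @staticmethod
    def _build_tree(
        tokens: list[Token],
        tags: list[str],
        np_spans: list[tuple[int, int]],
        main_verb: int | None,
    ) -> ConstituencyNode:
        n = len(tokens)
        np_start = {a: b for a, b in np_spans}
        units: list[ConstituencyNode] = []
        i = 0
        while i < n:
            if i in np_start:
                b = np_start[i]
                np = phrase("NP", *[pre_terminal(tags[k], k) for k in range(i, b)])
                if units and units[-1].label in ("IN", "TO") and units[-1].is_preterminal:
                    prep = units.pop()
                    units.append(phrase("PP", prep, np))
                else:
                    units.append(np)
                i = b
            else:
                units.append(pre_terminal(tags[i], i))
                i += 1
        if main_verb is None:
            return phrase("S", *units) if len(units) > 1 else (
                units[0] if not units[0].is_preterminal else phrase("S", units[0])
            )
        # group the verb and everything after it into a VP
        split = next(k for k, u in enumerate(units) if u.span[0] <= main_verb < u.span[1])
        before, after = units[:split], units[split:]
        vp = phrase("VP", *after) if len(after) > 1 else after[0]
        if not before:
            return vp if not vp.is_preterminal else phrase("S", vp)
        return phrase("S", *before, vp)


def write_conll(parsed: ParsedSentence) -> str:
    """Serialise tokens and dependencies to CoNLL-style columns."""
    lines = []
    for t in parsed.tokens:
        head = parsed.dep.heads[t.index]
        lines.append(
            f"{t.index}\t{t.surface}\t{t.lemma}\t{t.pos}\t{head}\t{parsed.dep.labels[t.index]}"
        )
    return "\n".join(lines) + "\n"
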
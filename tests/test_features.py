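import pytest

from conftest import hand_parse
from relexkit.corpus import EntityMention
from relexkit.features import (
    DEFAULT_NOMINALIZATION_LEXICON,
    NO_CLAUSE_SENTINEL,
    EntityPairContext,
    RuleConfig,
    clause_features,
    extract_feature_vector,
    lexical_window_features,
    negation_feature,
    no_verb_in_dependency_path,
    nominalization_features,
    same_head_and_path_features,
    supplementary_features,
    vectorize,
    verb_in_dependency_path,
    voice_feature,
)
from relexkit.parse import phrase, pre_terminal


def ctx_for(parsed, e1_span, e2_span, etypes=("gene", "disease"), extra_entities=()):
    text = " ".join(t.surface for t in parsed.tokens)
    e1 = EntityMention("T1", etypes[0], *e1_span, text[e1_span[0] : e1_span[1]])
    e2 = EntityMention("T2", etypes[1], *e2_span, text[e2_span[0] : e2_span[1]])
    ents = [e1, e2, *extra_entities]
    return EntityPairContext(e1=e1, e2=e2, parsed=parsed, sentence_entities=ents)


@pytest.fixture
def epa_ctx(epa_parse):
    # EPA(0..3) ... vasoconstriction(15..31)
    text = "EPA reduce the vasoconstriction in a dose-dependent manner"
    assert text[15:31] == "vasoconstriction"
    return ctx_for(epa_parse, (0, 3), (15, 31))


class TestVerbInPath:
    def test_epa_worked_example(self, epa_ctx):
        feats = verb_in_dependency_path(epa_ctx, RuleConfig())
        assert feats["verb_in_path"] is True
        assert feats["path_signature"] == "nsubj↑ AND dobj↓"
        assert feats["verb_lemma"] == "reduce"
        assert feats["relation_verb_class"] == "DOWN_REGULATE"

    def test_no_verb_on_path(self):
        # "mutation of MLH1 in patients": noun-rooted, no verb anywhere
        tree = phrase(
            "NP",
            pre_terminal("NN", 0),
            phrase("PP", pre_terminal("IN", 1), phrase("NP", pre_terminal("NN", 2))),
            phrase("PP", pre_terminal("IN", 3), phrase("NP", pre_terminal("NNS", 4))),
        )
        parsed = hand_parse(
            [("mutation", "NN"), ("of", "IN"), ("MLH1", "NN"), ("in", "IN"),
             ("patients", "NNS")],
            [-1, 2, 0, 4, 0],
            ["root", "prep", "prep_of", "prep", "prep_in"],
            tree,
        )
        ctx = ctx_for(parsed, (12, 16), (20, 28), etypes=("gene", "cohort"))
        assert verb_in_dependency_path(ctx, RuleConfig()) == {"verb_in_path": False}
        assert no_verb_in_dependency_path(ctx, RuleConfig()) == {"no_verb": True}

    def test_two_verbs_anchor_rootmost(self):
        # X suggests (that) Y increases Z: path X -> suggests -> increases -> Z
        tree = phrase(
            "S",
            phrase("NP", pre_terminal("NN", 0)),
            phrase(
                "VP",
                pre_terminal("VBZ", 1),
                phrase(
                    "SBAR",
                    phrase("NP", pre_terminal("NN", 2)),
                    phrase("VP", pre_terminal("VBZ", 3), phrase("NP", pre_terminal("NN", 4))),
                ),
            ),
        )
        parsed = hand_parse(
            [("X", "NN"), ("suggests", "VBZ"), ("Y", "NN"), ("increases", "VBZ"),
             ("Z", "NN")],
            [1, -1, 3, 1, 3],
            ["nsubj", "root", "nsubj", "ccomp", "dobj"],
            tree,
            lemmas={"suggests": "suggest", "increases": "increase"},
        )
        ctx = ctx_for(parsed, (0, 1), (14, 15))
        feats = verb_in_dependency_path(ctx, RuleConfig())
        assert feats["verb_lemma"] == "suggest"  # root-most of the two

    def test_epa_no_verb_is_false(self, epa_ctx):
        assert no_verb_in_dependency_path(epa_ctx, RuleConfig()) == {"no_verb": False}


class TestClause:
    def test_no_sbar(self, epa_ctx):
        feats = clause_features(epa_ctx)
        assert feats == {
            "contains_clause": False,
            "sbar_between": False,
            "clause_distance_left": NO_CLAUSE_SENTINEL,
            "clause_distance_right": NO_CLAUSE_SENTINEL,
        }

    def _sbar_parse(self):
        # "X increases , which suggests Y": SBAR over tokens 3..6
        tree = phrase(
            "S",
            phrase("NP", pre_terminal("NN", 0)),
            phrase("VP", pre_terminal("VBZ", 1)),
            pre_terminal(",", 2),
            phrase(
                "SBAR",
                pre_terminal("WDT", 3),
                phrase("VP", pre_terminal("VBZ", 4), phrase("NP", pre_terminal("NN", 5))),
            ),
        )
        return hand_parse(
            [("X", "NN"), ("increases", "VBZ"), (",", ","), ("which", "WDT"),
             ("suggests", "VBZ"), ("Y", "NN")],
            [1, -1, 1, 4, 1, 4],
            ["nsubj", "root", "punct", "nsubj", "ccomp", "dobj"],
            tree,
        )

    def test_entity_inside_sbar(self):
        parsed = self._sbar_parse()
        # X at chars 0..1; Y at end
        text = "X increases , which suggests Y"
        ctx = ctx_for(parsed, (0, 1), (text.index("Y"), text.index("Y") + 1))
        feats = clause_features(ctx)
        assert feats["contains_clause"] is True
        assert feats["sbar_between"] is True
        assert feats["clause_distance_left"] != NO_CLAUSE_SENTINEL

    def test_both_entities_outside_sbar_not_between(self):
        # SBAR covers the tail; both entities before it
        tree = phrase(
            "S",
            phrase("NP", pre_terminal("NN", 0)),
            phrase("VP", pre_terminal("VBZ", 1), phrase("NP", pre_terminal("NN", 2))),
            phrase("SBAR", pre_terminal("IN", 3), phrase("NP", pre_terminal("NN", 4))),
        )
        parsed = hand_parse(
            [("X", "NN"), ("binds", "VBZ"), ("Y", "NN"), ("because", "IN"), ("Z", "NN")],
            [1, -1, 1, 4, 1],
            ["nsubj", "root", "dobj", "mark", "advcl"],
            tree,
        )
        ctx = ctx_for(parsed, (0, 1), (8, 9))
        feats = clause_features(ctx)
        assert feats["contains_clause"] is True
        assert feats["sbar_between"] is False


class TestSameHeadAndPaths:
    def test_same_parent_vp(self):
        tree = phrase(
            "VP",
            pre_terminal("VB", 0),
            phrase("NP", pre_terminal("NN", 1)),
            phrase("NP", pre_terminal("NN", 2)),
        )
        parsed = hand_parse(
            [("binds", "VB"), ("X", "NN"), ("Y", "NN")],
            [-1, 0, 0],
            ["root", "dobj", "iobj"],
            tree,
        )
        ctx = ctx_for(parsed, (6, 7), (8, 9))
        feats = same_head_and_path_features(ctx)
        assert feats["same_head"] is True
        assert feats["full_tree_path"] == "NP-VP-NP"
        assert feats["path_length"] == 2

    def test_identical_node_zero_length(self, epa_parse):
        e = EntityMention("T1", "gene", 0, 3, "EPA")
        e2 = EntityMention("T2", "gene", 0, 3, "EPA")
        ctx = EntityPairContext(
            e1=e, e2=EntityMention("T2x", "gene", 0, 3, "EPA"), parsed=epa_parse,
            sentence_entities=[e, e2],
        )
        feats = same_head_and_path_features(ctx)
        assert feats["path_length"] == 0


class TestNegationVoice:
    def _neg_parse(self, neg_on_path: bool):
        # "X does not regulate Y . Z works" style single-clause variants
        if neg_on_path:
            tokens = [("X", "NN"), ("not", "RB"), ("regulate", "VB"), ("Y", "NN")]
            heads = [2, 2, -1, 2]
            labels = ["nsubj", "neg", "root", "dobj"]
            tree = phrase(
                "S",
                phrase("NP", pre_terminal("NN", 0)),
                phrase("VP", pre_terminal("RB", 1), pre_terminal("VB", 2),
                       phrase("NP", pre_terminal("NN", 3))),
            )
        else:
            # neg attaches to a verb off the X..Y path
            tokens = [("X", "NN"), ("regulates", "VBZ"), ("Y", "NN"), ("not", "RB"),
                      ("shown", "VBN")]
            heads = [1, -1, 1, 4, 1]
            labels = ["nsubj", "root", "dobj", "neg", "xcomp"]
            tree = phrase(
                "S",
                phrase("NP", pre_terminal("NN", 0)),
                phrase("VP", pre_terminal("VBZ", 1), phrase("NP", pre_terminal("NN", 2)),
                       phrase("VP", pre_terminal("RB", 3), pre_terminal("VBN", 4))),
            )
        return hand_parse(tokens, heads, labels, tree,
                          lemmas={"regulates": "regulate", "shown": "show"})

    def test_neg_arc_on_path(self):
        parsed = self._neg_parse(True)
        ctx = ctx_for(parsed, (0, 1), (15, 16))
        assert negation_feature(ctx, RuleConfig()) == {"negated": True}

    def test_neg_arc_off_path(self):
        parsed = self._neg_parse(False)
        ctx = ctx_for(parsed, (0, 1), (12, 13))
        assert negation_feature(ctx, RuleConfig()) == {"negated": False}

    def test_lexicon_negative_modifying_path_verb(self):
        # "X fails to regulate Y": "fails" governs path verb "regulate"
        tree = phrase(
            "S",
            phrase("NP", pre_terminal("NN", 0)),
            phrase("VP", pre_terminal("VBZ", 1),
                   phrase("VP", pre_terminal("TO", 2), pre_terminal("VB", 3),
                          phrase("NP", pre_terminal("NN", 4)))),
        )
        parsed = hand_parse(
            [("X", "NN"), ("fails", "VBZ"), ("to", "TO"), ("regulate", "VB"), ("Y", "NN")],
            [3, 3, 3, -1, 3],
            ["nsubj", "aux_fail", "aux", "root", "dobj"],
            tree,
            lemmas={"fails": "fails"},
        )
        text = "X fails to regulate Y"
        ctx = ctx_for(parsed, (0, 1), (text.index("Y"), text.index("Y") + 1))
        assert negation_feature(ctx, RuleConfig()) == {"negated": True}

    def test_passive_on_path(self, adapter):
        parsed = adapter.parse("TP53 is regulated by MDM2")
        ctx = ctx_for(parsed, (0, 4), (21, 25))
        assert voice_feature(ctx) == {"passive": True}

    def test_active_epa_not_passive(self, epa_ctx):
        assert voice_feature(epa_ctx) == {"passive": False}


class TestLexicalWindows:
    def test_adjacent_entities_empty_between(self):
        tree = phrase("NP", pre_terminal("NN", 0), pre_terminal("NN", 1))
        parsed = hand_parse(
            [("MLH1", "NN"), ("mutations", "NNS")], [1, -1], ["nn", "root"], tree
        )
        ctx = ctx_for(parsed, (0, 4), (5, 14))
        feats = lexical_window_features(ctx, RuleConfig())
        assert feats["words_between"] == ()
        assert feats["surface_distance"] == 2

    def test_inclusive_surface_distance(self):
        # widths 1 and 2 with 3 tokens between -> 6
        spec = [("A", "NN"), ("x", "NN"), ("y", "NN"), ("z", "NN"), ("B", "NN"),
                ("C", "NN")]
        tree = phrase("NP", *[pre_terminal("NN", i) for i in range(6)])
        parsed = hand_parse(spec, [-1, 0, 0, 0, 0, 4], ["root"] + ["dep"] * 5, tree)
        text = "A x y z B C"
        ctx = ctx_for(parsed, (0, 1), (text.index("B"), text.index("C") + 1))
        feats = lexical_window_features(ctx, RuleConfig())
        assert feats["surface_distance"] == 6
        assert feats["words_between"] == ("x", "y", "z")

    def test_window_clipped_at_edges(self, epa_ctx):
        feats = lexical_window_features(epa_ctx, RuleConfig(window_k=3))
        assert feats["window_left_e1"] == ()  # entity at sentence start
        assert len(feats["window_right_e2"]) == 3

    def test_symmetry_of_distance(self, epa_parse):
        text = "EPA reduce the vasoconstriction in a dose-dependent manner"
        c1 = ctx_for(epa_parse, (0, 3), (15, 31))
        f1 = lexical_window_features(c1, RuleConfig())
        # same pair, same result regardless of which argument is which type
        c2 = ctx_for(epa_parse, (0, 3), (15, 31), etypes=("disease", "gene"))
        f2 = lexical_window_features(c2, RuleConfig())
        assert f1["surface_distance"] == f2["surface_distance"]


class TestNominalization:
    def _inhibition_parse(self):
        # "inhibition of X by Y"
        tree = phrase(
            "NP",
            pre_terminal("NN", 0),
            phrase("PP", pre_terminal("IN", 1), phrase("NP", pre_terminal("NN", 2))),
            phrase("PP", pre_terminal("IN", 3), phrase("NP", pre_terminal("NN", 4))),
        )
        return hand_parse(
            [("inhibition", "NN"), ("of", "IN"), ("X", "NN"), ("by", "IN"), ("Y", "NN")],
            [-1, 2, 0, 4, 0],
            ["root", "prep", "prep_of", "prep", "prep_by"],
            tree,
        )

    def test_strict_nominalization(self):
        parsed = self._inhibition_parse()
        text = "inhibition of X by Y"
        ctx = ctx_for(parsed, (text.index("X"), text.index("X") + 1),
                      (text.index("Y"), text.index("Y") + 1))
        feats = nominalization_features(ctx, RuleConfig())
        assert feats["nominalization"] is True

    def test_weak_nominalization_single_entity(self):
        # "mutation in MLH1 was common": only MLH1 fits the pattern
        tree = phrase(
            "S",
            phrase("NP", pre_terminal("NN", 0),
                   phrase("PP", pre_terminal("IN", 1), phrase("NP", pre_terminal("NN", 2)))),
            phrase("VP", pre_terminal("VBD", 3), pre_terminal("JJ", 4)),
        )
        parsed = hand_parse(
            [("mutation", "NN"), ("in", "IN"), ("MLH1", "NN"), ("was", "VBD"),
             ("common", "JJ")],
            [3, 2, 0, -1, 3],
            ["nsubj", "prep", "prep_in", "root", "acomp"],
            tree,
        )
        text = "mutation in MLH1 was common"
        ctx = ctx_for(parsed, (0, 8), (text.index("MLH1"), text.index("MLH1") + 4),
                      etypes=("mutationtype", "gene"))
        feats = nominalization_features(ctx, RuleConfig())
        assert feats["weak_nominalization"] is True
        assert feats["nominalization"] is False

    def test_empty_lexicon_all_false(self):
        parsed = self._inhibition_parse()
        text = "inhibition of X by Y"
        ctx = ctx_for(parsed, (text.index("X"), text.index("X") + 1),
                      (text.index("Y"), text.index("Y") + 1))
        cfg = RuleConfig(nominalization_lexicon=frozenset())
        feats = nominalization_features(ctx, cfg)
        assert feats["nominalization"] is False
        assert feats["weak_nominalization"] is False


class TestSupplementary:
    def test_entities_between(self, epa_parse):
        mid = EntityMention("T3", "gene", 4, 10, "reduce")
        ctx = ctx_for(epa_parse, (0, 3), (15, 31), extra_entities=[mid])
        feats = supplementary_features(ctx)
        assert feats["n_entities_between"] == 1
        assert feats["entities_between_types"] == ("gene",)
        assert feats["entity_counts"] == 3

    def test_nothing_between(self, epa_ctx):
        feats = supplementary_features(epa_ctx)
        assert feats["n_entities_between"] == 0

    def test_order_flips_with_arg_order(self, epa_parse):
        text = "EPA reduce the vasoconstriction in a dose-dependent manner"
        e1 = EntityMention("T1", "gene", 0, 3, "EPA")
        e2 = EntityMention("T2", "disease", 15, 31, "vasoconstriction")
        fwd = EntityPairContext(e1=e1, e2=e2, parsed=epa_parse,
                                sentence_entities=[e1, e2], arg_order="forward")
        rev = EntityPairContext(e1=e1, e2=e2, parsed=epa_parse,
                                sentence_entities=[e1, e2], arg_order="reversed")
        assert supplementary_features(fwd)["entity_order"] == "gene<disease"
        assert supplementary_features(rev)["entity_order"] == "disease>gene"


class TestFullVector:
    def test_epa_vector_contents(self, epa_ctx):
        fv = extract_feature_vector(epa_ctx, RuleConfig())
        assert fv["path_signature"] == "nsubj↑ AND dobj↓"
        assert fv["relation_verb_class"] == "DOWN_REGULATE"
        assert fv["surface_distance"] == 4
        assert fv["passive"] is False

    def test_determinism(self, epa_ctx):
        cfg = RuleConfig()
        assert extract_feature_vector(epa_ctx, cfg) == extract_feature_vector(epa_ctx, cfg)

    def test_rule_inventory_reachable(self, epa_parse, adapter):
        """Every rule family emits its features across a fixture battery."""
        names = set()
        cfg = RuleConfig()
        contexts = [
            ctx_for(epa_parse, (0, 3), (15, 31)),
        ]
        passive = adapter.parse("TP53 is regulated by MDM2")
        contexts.append(ctx_for(passive, (0, 4), (21, 25)))
        for ctx in contexts:
            names.update(extract_feature_vector(ctx, cfg))
        expected = {
            "verb_in_path", "no_verb", "contains_clause", "sbar_between",
            "clause_distance_left", "clause_distance_right", "same_head",
            "full_tree_path", "full_dep_path", "path_length", "negated",
            "passive", "words_between", "surface_distance", "window_left_e1",
            "window_right_e2", "nominalization", "weak_nominalization",
            "nominalization_side", "nominalization_distance",
            "n_entities_between", "entities_between_types", "entity_counts",
            "entity_order", "e1_type", "e2_type",
        }
        assert expected <= names

    def test_vectorize_types(self, epa_ctx):
        vec = vectorize(extract_feature_vector(epa_ctx, RuleConfig()))
        assert all(isinstance(v, float) for v in vec.values())
        assert "relation_verb_class=DOWN_REGULATE" in vec
        assert vec["surface_distance"] == 4.0

    def test_out_of_order_entities_rejected(self, epa_parse):
        e1 = EntityMention("T1", "gene", 15, 31, "vasoconstriction")
        e2 = EntityMention("T2", "disease", 0, 3, "EPA")
        with pytest.raises(ValueError):
            EntityPairContext(e1=e1, e2=e2, parsed=epa_parse, sentence_entities=[e1, e2])
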
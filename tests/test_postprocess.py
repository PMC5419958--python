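"""Contextual-clue rules, parenthesis repair and abbreviation handling."""

from collections import Counter

import pytest

from genetagger.corpus import RawSentence, bio_to_mentions
from genetagger.postprocess import (
    KeywordLexicon,
    PostKeywordList,
    SenseInventory,
    apply_contextual_rules,
    build_pkl,
    disambiguate,
    extract_abbreviation_pairs,
    fix_parentheses,
    postprocess_labels,
    propagate_abbreviation_labels,
)
from genetagger.corpus import GeneMention
from genetagger.preprocess import tokenize


def _ts(text):
    return tokenize(RawSentence("S1", text))


class TestPostKeywordList:
    def test_three_occurrences_matchable(self):
        pkl = build_pkl([GeneMention("S", i * 5, i * 5 + 1, "C4") for i in range(3)])
        assert pkl.matchable("C4")

    def test_two_occurrences_not_matchable(self):
        pkl = build_pkl([GeneMention("S", i * 5, i * 5 + 1, "C4") for i in range(2)])
        assert not pkl.matchable("C4")

    def test_empty_corpus(self):
        assert not build_pkl([]).matchable("anything")


class TestContextualRules:
    def test_connective_tags_pkl_neighbor(self):
        ts = _ts("Early complement components , C1q and C4 , and IgA secretory piece were absent")
        labels = ["O"] * len(ts.tokens)
        labels[ts.surfaces.index("C1q")] = "B"
        pkl = PostKeywordList(Counter({"C4": 3}))
        out = apply_contextual_rules(ts, labels, pkl=pkl)
        assert out[ts.surfaces.index("C4")] == "B"
        assert out[ts.surfaces.index("C1q")] == "B"

    def test_relation_keyword_tags_neighbor(self):
        ts = _ts("TRX2 binds ALB4 strongly")
        pkl = PostKeywordList(Counter({"ALB4": 5, "TRX2": 5}))
        out = apply_contextual_rules(ts, ["O"] * 4, pkl=pkl)
        assert out[:3] == ["B", "O", "B"]

    def test_no_lexicon_words_unchanged(self):
        ts = _ts("plain words only here")
        labels = ["O", "B", "O", "O"]
        assert apply_contextual_rules(ts, labels, pkl=PostKeywordList()) == labels

    def test_neighbor_not_in_pkl_unchanged(self):
        ts = _ts("AAA and BBB")
        out = apply_contextual_rules(ts, ["O"] * 3, pkl=PostKeywordList())
        assert out == ["O"] * 3

    def test_never_removes_existing_labels(self, rng):
        ts = _ts("X1 and Y2 binds Z3 or W4")
        pkl = PostKeywordList(Counter({s: 4 for s in ts.surfaces}))
        for _ in range(50):
            labels = [["B", "I", "O"][int(rng.integers(3))] for _ in ts.tokens]
            out = apply_contextual_rules(ts, labels, pkl=pkl)
            assert all(
                o in ("B", "I") for o, l in zip(out, labels) if l in ("B", "I")
            )


class TestFixParentheses:
    def test_open_bracket_ejected_and_reheaded(self):
        ts = _ts("( HNF - 3 )")
        assert fix_parentheses(ts, ["B", "I", "I", "I", "O"]) == [
            "O", "B", "I", "I", "O",
        ]

    def test_balanced_pair_inside_mention_kept(self):
        ts = _ts("Brown adipose tissue ( BAT )")
        labels = ["B", "I", "I", "I", "I", "I"]
        assert fix_parentheses(ts, labels) == labels

    def test_all_o_unchanged(self):
        ts = _ts("( x )")
        assert fix_parentheses(ts, ["O", "O", "O"]) == ["O", "O", "O"]

    def test_unpartnered_bracket_ejected(self):
        ts = _ts("the ( gene was")
        assert fix_parentheses(ts, ["O", "B", "I", "O"]) == ["O", "O", "B", "O"]

    def test_closing_bracket_ejected(self):
        ts = _ts("( HNF - 3 )")
        assert fix_parentheses(ts, ["O", "B", "I", "I", "I"]) == [
            "O", "B", "I", "I", "O",
        ]

    def test_no_unbalanced_bracket_in_output(self, rng):
        vocab = ["(", ")", "A1", "bb", "[", "]", "CC2"]
        for trial in range(200):
            n = int(rng.integers(1, 10))
            text = " ".join(vocab[int(rng.integers(len(vocab)))] for _ in range(n))
            ts = tokenize(RawSentence(f"T{trial}", text))
            labels = [["B", "I", "O"][int(rng.integers(3))] for _ in range(len(ts.tokens))]
            out = fix_parentheses(ts, labels)
            for m in bio_to_mentions(ts, out):
                inner = m.text
                for o, c in (("(", ")"), ("[", "]"), ("{", "}")):
                    assert inner.count(o) == inner.count(c), (text, labels, out)


class TestAbbreviationExtraction:
    def test_bat_pair(self):
        pairs = extract_abbreviation_pairs(_ts("Brown adipose tissue ( BAT ) here"))
        assert len(pairs) == 1
        assert pairs[0].short_form == "BAT"
        assert pairs[0].long_form == "Brown adipose tissue"

    def test_wat_pair(self):
        pairs = extract_abbreviation_pairs(
            _ts("brown-like cells in white adipose tissue ( WAT ) can dissipate")
        )
        assert any(
            p.short_form == "WAT" and p.long_form == "white adipose tissue"
            for p in pairs
        )

    def test_statistical_parenthetical_rejected(self):
        assert extract_abbreviation_pairs(_ts("measured ( p < 0.05 )")) == []

    def test_overlong_short_form_rejected(self):
        assert (
            extract_abbreviation_pairs(
                _ts("some thing ( averyverylongform ) end")
            )
            == []
        )


class TestAbbreviationPropagation:
    def test_sf_to_lf(self):
        ts = _ts("Brown adipose tissue ( BAT ) and cells")
        pairs = extract_abbreviation_pairs(ts)
        labels = ["O"] * len(ts.tokens)
        labels[3:6] = ["B", "I", "I"]  # ( BAT )
        out = propagate_abbreviation_labels(labels, pairs)
        assert out[:3] == ["B", "I", "I"]

    def test_lf_to_sf(self):
        ts = _ts("Brown adipose tissue ( BAT ) and cells")
        pairs = extract_abbreviation_pairs(ts)
        labels = ["O"] * len(ts.tokens)
        labels[:3] = ["B", "I", "I"]
        out = propagate_abbreviation_labels(labels, pairs)
        assert out[4] == "B"  # BAT

    def test_both_tagged_unchanged(self):
        ts = _ts("Brown adipose tissue ( BAT )")
        pairs = extract_abbreviation_pairs(ts)
        labels = ["B", "I", "I", "O", "B", "O"]
        assert propagate_abbreviation_labels(labels, pairs) == labels

    def test_neither_tagged_never_creates(self):
        ts = _ts("Brown adipose tissue ( BAT )")
        pairs = extract_abbreviation_pairs(ts)
        labels = ["O"] * 6
        assert propagate_abbreviation_labels(labels, pairs) == labels


class TestDisambiguation:
    @pytest.fixture
    def inventory(self):
        inv = SenseInventory()
        inv.add("ACE", "ace1", "angiotensin converting enzyme", ["blood", "pressure"])
        inv.add("ACE", "ace2", "acetylcholinesterase", ["nerve", "synapse"])
        return inv

    def test_long_form_in_sentence_wins(self, inventory):
        ctx = "angiotensin converting enzyme ( ACE ) was measured".split()
        assert disambiguate("ACE", ctx, inventory) == "ace1"

    def test_context_overlap(self, inventory):
        ctx = "the nerve synapse assay of ACE".split()
        assert disambiguate("ACE", ctx, inventory) == "ace2"

    def test_single_sense(self):
        inv = SenseInventory()
        inv.add("BAT", "bat1", "brown adipose tissue", [])
        assert disambiguate("BAT", ["anything"], inv) == "bat1"

    def test_tie_goes_to_first_sense(self, inventory):
        assert disambiguate("ACE", ["unrelated"], inventory) == "ace1"

    def test_unknown_sf_returns_none(self, inventory):
        assert disambiguate("XYZ", ["whatever"], inventory) is None

    def test_duplicate_sense_id_rejected(self, inventory):
        with pytest.raises(ValueError, match="duplicate"):
            inventory.add("ACE", "ace1", "another", [])

    def test_inventory_file_round_trip(self, tmp_path, inventory):
        p = tmp_path / "senses.tsv"
        p.write_text(
            "ACE\tace1\tangiotensin converting enzyme\tblood, pressure\n"
            "ACE\tace2\tacetylcholinesterase\tnerve, synapse\n"
        )
        loaded = SenseInventory.from_file(p)
        assert [s.sense_id for s in loaded.senses["ACE"]] == ["ace1", "ace2"]


class TestIdempotence:
    def _random_case(self, rng, trial):
        vocab = ["(", ")", "C4", "and", "binds", "tissue", "BAT", "Brown", "adipose"]
        n = int(rng.integers(2, 12))
        text = " ".join(vocab[int(rng.integers(len(vocab)))] for _ in range(n))
        ts = tokenize(RawSentence(f"I{trial}", text))
        labels = [["B", "I", "O"][int(rng.integers(3))] for _ in ts.tokens]
        return ts, labels

    def test_each_operation_idempotent(self, rng):
        pkl = PostKeywordList(Counter({"C4": 3, "BAT": 3}))
        lexicon = KeywordLexicon()
        for trial in range(150):
            ts, labels = self._random_case(rng, trial)
            once = apply_contextual_rules(ts, labels, lexicon, pkl)
            assert apply_contextual_rules(ts, once, lexicon, pkl) == once
            once = fix_parentheses(ts, labels)
            assert fix_parentheses(ts, once) == once
            pairs = extract_abbreviation_pairs(ts)
            once = propagate_abbreviation_labels(labels, pairs)
            assert propagate_abbreviation_labels(once, pairs) == once
            full = postprocess_labels(ts, labels, lexicon, pkl)
            assert postprocess_labels(ts, full, lexicon, pkl) == full

    def test_lexicon_file_loading(self, tmp_path):
        p = tmp_path / "rel.txt"
        p.write_text("binds\nActivates\n\n")
        lex = KeywordLexicon.from_file(p)
        assert lex.relation_words == frozenset({"binds", "activates"})
        assert "and" in lex.connective_words
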
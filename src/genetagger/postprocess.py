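"""Rule-based post-processing of B/I/O label sequences.

Three rule families repair typical CRF tagging errors, applied in a fixed
order: contextual keyword clues, parenthesis-mismatch repair, abbreviation
propagation, then optional abbreviation sense disambiguation.

* **Contextual clues** — connective words ("and", "or") and
  relation/interaction keywords ("binding", "activate", ...) signal that a
  neighboring token may be a gene name.  The non-punctuation neighbors of
  each keyword are looked up in the post-keyword list (pkl): gene surfaces
  seen three or more times in the training annotations.  A neighbor found
  there and currently labeled O becomes a single-token mention (B); existing
  labels are never removed.
* **Parenthesis repair** — a bracket tagged inside a mention whose partner
  lies outside (or is absent) is ejected from the mention, so no predicted
  mention carries an unbalanced bracket.
* **Abbreviation handling** — ``Long Form (SF)`` constructs are paired with
  a right-to-left character-matching test; when only one of the two spans
  was tagged, the label is propagated to the other.  An ambiguous short
  form can additionally be resolved against a user-supplied sense inventory
  by context-term overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from collections import Counter

from .corpus import GeneMention
from .preprocess import TokenizedSentence

#: Seed interaction-keyword list.  The full lexicon used operationally is
#: much larger and should be supplied via file for serious use; this seed
#: covers the common protein-interaction vocabulary.
DEFAULT_RELATION_WORDS = frozenset(
    """bind binds binding bound activate activates activated activation
    inhibit inhibits inhibited inhibition interact interacts interaction
    phosphorylate phosphorylates phosphorylated phosphorylation regulate
    regulates regulated regulation express expresses expressed expression
    encode encodes encoded induce induces induced suppress suppresses
    mediate mediates mediated associate associates associated stimulates
    transactivates cleaves ubiquitinates acetylates methylates recruits
    represses dimerizes complexes cotransfected coimmunoprecipitated
    """.split()
)

DEFAULT_CONNECTIVE_WORDS = frozenset({"and", "or"})

_STOPWORDS = frozenset(
    """a an the of and or in to is was were are be by with for on as at
    from this that it its""".split()
)

_OPEN_TO_CLOSE = {"(": ")", "[": "]", "{": "}"}
_CLOSE_TO_OPEN = {v: k for k, v in _OPEN_TO_CLOSE.items()}


@dataclass(frozen=True)
class KeywordLexicon:
    """Relation and connective keyword sets (lowercase-normalized)."""

    relation_words: frozenset[str] = DEFAULT_RELATION_WORDS
    connective_words: frozenset[str] = DEFAULT_CONNECTIVE_WORDS

    @classmethod
    def from_file(
        cls, relation_path: str | Path, connective_path: str | Path | None = None
    ) -> "KeywordLexicon":
        relation = frozenset(
            w.strip().lower()
            for w in Path(relation_path).read_text(encoding="utf-8").splitlines()
            if w.strip()
        )
        connective = DEFAULT_CONNECTIVE_WORDS
        if connective_path is not None:
            connective = frozenset(
                w.strip().lower()
                for w in Path(connective_path).read_text(encoding="utf-8").splitlines()
                if w.strip()
            )
        return cls(relation_words=relation, connective_words=connective)


@dataclass
class PostKeywordList:
    """Gene-name surfaces with their training-corpus mention counts.

    Only surfaces counted ``min_count`` (default 3) or more times are
    matchable by the contextual rules.
    """

    counts: Counter = field(default_factory=Counter)
    min_count: int = 3

    def matchable(self, surface: str) -> bool:
        return self.counts.get(surface, 0) >= self.min_count


def build_pkl(
    mentions: Iterable[GeneMention], min_count: int = 3
) -> PostKeywordList:
    return PostKeywordList(Counter(m.text for m in mentions), min_count)


def _neighbor(labels_len: int, surfaces: Sequence[str], i: int, step: int) -> int | None:
    """Index of the nearest non-punctuation token in the given direction."""
    j = i + step
    while 0 <= j < labels_len:
        if any(c.isalnum() for c in surfaces[j]):
            return j
        j += step
    return None


def apply_contextual_rules(
    sentence: TokenizedSentence,
    labels: Sequence[str],
    lexicon: KeywordLexicon | None = None,
    pkl: PostKeywordList | None = None,
) -> list[str]:
    """Tag pkl-listed neighbors of connective and relation keywords.

    Two passes: connective words first, then relation keywords.  For each
    keyword occurrence the nearest non-punctuation neighbor on either side
    is checked against the pkl; a match currently labeled O becomes a
    single-token B.  Existing B/I labels are never altered.
    """
    lexicon = lexicon or KeywordLexicon()
    out = list(labels)
    if pkl is None:
        return out
    surfaces = sentence.surfaces
    for wordset in (lexicon.connective_words, lexicon.relation_words):
        for i, surf in enumerate(surfaces):
            if surf.lower() not in wordset:
                continue
            for step in (-1, 1):
                j = _neighbor(len(out), surfaces, i, step)
                if j is None or out[j] != "O":
                    continue
                if pkl.matchable(surfaces[j]):
                    out[j] = "B"
    return out


def _match_brackets(surfaces: Sequence[str]) -> tuple[list[tuple[int, int]], list[int]]:
    """Matched (open, close) token index pairs plus unmatched bracket indices."""
    stacks: dict[str, list[int]] = {k: [] for k in _OPEN_TO_CLOSE}
    pairs: list[tuple[int, int]] = []
    unmatched: list[int] = []
    for i, s in enumerate(surfaces):
        if s in _OPEN_TO_CLOSE:
            stacks[s].append(i)
        elif s in _CLOSE_TO_OPEN:
            stack = stacks[_CLOSE_TO_OPEN[s]]
            if stack:
                pairs.append((stack.pop(), i))
            else:
                unmatched.append(i)
    for stack in stacks.values():
        unmatched.extend(stack)
    return pairs, sorted(unmatched)


def _mention_id(labels: Sequence[str], i: int) -> int | None:
    """Ordinal of the mention covering token i, or None."""
    if labels[i] == "O":
        return None
    mid = -1
    for k in range(i + 1):
        if labels[k] == "B" or (labels[k] == "I" and (k == 0 or labels[k - 1] == "O")):
            mid += 1
    return mid


def fix_parentheses(
    sentence: TokenizedSentence, labels: Sequence[str]
) -> list[str]:
    """Eject unbalanced brackets from predicted mentions.

    A bracket inside a mention is kept only when its partner lies in the
    same mention; otherwise it is relabeled O and, if it headed the mention,
    the following mention token is promoted to B.  Output mentions never
    contain an unbalanced bracket.
    """
    out = list(labels)
    surfaces = sentence.surfaces
    for _ in range(len(out) + 1):  # iterate to a fixpoint; bounded
        pairs, unmatched = _match_brackets(surfaces)
        eject: list[int] = []
        for i, j in pairs:
            mi, mj = _mention_id(out, i), _mention_id(out, j)
            if mi == mj:
                continue
            if mi is not None:
                eject.append(i)
            if mj is not None:
                eject.append(j)
        for i in unmatched:
            if _mention_id(out, i) is not None:
                eject.append(i)
        if not eject:
            break
        for i in eject:
            out[i] = "O"
            # the remainder of the mention starts a fresh mention
            if i + 1 < len(out) and out[i + 1] == "I":
                out[i + 1] = "B"
    return out


@dataclass(frozen=True)
class AbbreviationPair:
    """A ``Long Form ( SF )`` construct located by token spans (inclusive).

    ``sf_span`` covers the short-form tokens between — not including — the
    parentheses; ``lf_span`` covers the long-form tokens immediately before
    the opening parenthesis.
    """

    sentence_id: str
    short_form: str
    long_form: str
    sf_span: tuple[int, int]
    lf_span: tuple[int, int]


def _find_long_form(sf: str, lf: str) -> int | None:
    """Start char index of the long form within ``lf``, or None.

    Classic right-to-left pairing test: every alphanumeric short-form
    character must appear in order (case-insensitive) in the long form, and
    the short form's first character must match the initial character of a
    word.
    """
    s_index = len(sf) - 1
    l_index = len(lf) - 1
    while s_index >= 0:
        c = sf[s_index].lower()
        if not c.isalnum():
            s_index -= 1
            continue
        while (l_index >= 0 and lf[l_index].lower() != c) or (
            s_index == 0 and l_index > 0 and lf[l_index - 1].isalnum()
        ):
            l_index -= 1
        if l_index < 0:
            return None
        s_index -= 1
        l_index -= 1
    start = lf.rfind(" ", 0, l_index + 1) + 1
    return start


def extract_abbreviation_pairs(
    sentence: TokenizedSentence,
    max_sf_chars: int = 10,
    window_slack: int = 5,
) -> list[AbbreviationPair]:
    """Find ``Long Form ( SF )`` pairs in a sentence.

    A parenthesized candidate short form has at most ``max_sf_chars``
    non-space characters, at least one letter; the long-form search window
    spans ``min(|SF| + window_slack, 2 * |SF|)`` tokens before the opening
    parenthesis.  Candidates failing the character-pairing test yield no
    pair.
    """
    surfaces = sentence.surfaces
    pairs_out: list[AbbreviationPair] = []
    matched, _ = _match_brackets(surfaces)
    for p, q in sorted(matched):
        if surfaces[p] != "(" or q - p < 2 or p == 0:
            continue
        sf_tokens = surfaces[p + 1 : q]
        sf = " ".join(sf_tokens)
        n_chars = sum(len(t) for t in sf_tokens)
        if n_chars > max_sf_chars or not any(c.isalpha() for c in sf):
            continue
        window = min(n_chars + window_slack, 2 * n_chars)
        lf_start_tok = max(0, p - window)
        lf_tokens = surfaces[lf_start_tok:p]
        if not lf_tokens:
            continue
        lf = " ".join(lf_tokens)
        start_char = _find_long_form(sf, lf)
        if start_char is None:
            continue
        # map the character start back to a token index within the window
        offset = 0
        lf_tok = None
        for k, t in enumerate(lf_tokens):
            if offset == start_char:
                lf_tok = lf_start_tok + k
                break
            offset += len(t) + 1
        if lf_tok is None:
            continue
        pairs_out.append(
            AbbreviationPair(
                sentence_id=sentence.sentence_id,
                short_form=sf,
                long_form=" ".join(surfaces[lf_tok:p]),
                sf_span=(p + 1, q - 1),
                lf_span=(lf_tok, p - 1),
            )
        )
    return pairs_out


def _span_tagged(labels: Sequence[str], span: tuple[int, int]) -> bool:
    return any(labels[k] in ("B", "I") for k in range(span[0], span[1] + 1))


def _tag_span(labels: list[str], span: tuple[int, int]) -> None:
    labels[span[0]] = "B"
    for k in range(span[0] + 1, span[1] + 1):
        labels[k] = "I"


def propagate_abbreviation_labels(
    labels: Sequence[str], pairs: Sequence[AbbreviationPair]
) -> list[str]:
    """Copy mention status between paired long and short forms.

    If exactly one member of a pair overlaps a mention, the other member's
    span becomes ``B I ... I``.  Pairs that are already consistent — both
    tagged or both untagged — are left alone; the rule only propagates,
    never creates.
    """
    out = list(labels)
    for pair in pairs:
        sf_tagged = _span_tagged(out, pair.sf_span)
        lf_tagged = _span_tagged(out, pair.lf_span)
        if sf_tagged and not lf_tagged:
            _tag_span(out, pair.lf_span)
        elif lf_tagged and not sf_tagged:
            _tag_span(out, pair.sf_span)
    return out


@dataclass(frozen=True)
class Sense:
    sense_id: str
    long_form: str
    context_terms: frozenset[str]


@dataclass
class SenseInventory:
    """Short form -> candidate senses, each with a bag of context terms.

    File format (tab-separated): ``SF<TAB>sense_id<TAB>long form<TAB>terms``
    with comma-separated context terms.
    """

    senses: dict[str, list[Sense]] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "SenseInventory":
        inv = cls()
        for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            sf, sid, lf, terms = parts
            inv.add(sf, sid, lf, [t.strip() for t in terms.split(",") if t.strip()])
        return inv

    def add(
        self, sf: str, sense_id: str, long_form: str, terms: Iterable[str]
    ) -> None:
        bucket = self.senses.setdefault(sf, [])
        if any(s.sense_id == sense_id for s in bucket):
            raise ValueError(f"duplicate sense id {sense_id!r} for {sf!r}")
        bucket.append(
            Sense(sense_id, long_form, frozenset(t.lower() for t in terms))
        )


def disambiguate(
    short_form: str,
    context: Sequence[str],
    inventory: SenseInventory,
) -> str | None:
    """Pick the sense of an ambiguous short form from sentence context.

    If the sentence itself spells out one sense's long form, that sense
    wins outright.  Otherwise senses are ranked by overlap between their
    context-term bags and the (stopword-filtered, lowercased) sentence
    tokens; ties go to inventory order.  Returns None when the short form
    is not in the inventory.
    """
    senses = inventory.senses.get(short_form)
    if not senses:
        return None
    joined = " ".join(t.lower() for t in context)
    for sense in senses:
        if sense.long_form.lower() in joined:
            return sense.sense_id
    ctx = {t.lower() for t in context} - _STOPWORDS
    best = max(senses, key=lambda s: (len(ctx & s.context_terms), -senses.index(s)))
    return best.sense_id


def postprocess_labels(
    sentence: TokenizedSentence,
    labels: Sequence[str],
    lexicon: KeywordLexicon | None = None,
    pkl: PostKeywordList | None = None,
) -> list[str]:
    """Full rule pipeline in the fixed order: contextual clues, parenthesis
    repair, abbreviation propagation."""
    out = apply_contextual_rules(sentence, labels, lexicon, pkl)
    out = fix_parentheses(sentence, out)
    pairs = extract_abbreviation_pairs(sentence)
    out = propagate_abbreviation_labels(out, pairs)
    return out
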
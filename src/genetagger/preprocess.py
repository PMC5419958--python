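"""Sentence splitting, tokenization and pluggable token annotation.

Tokenization splits on whitespace and then isolates punctuation so that
parentheses, brackets, commas, periods, double quotes, slashes and hyphens
become their own tokens, while digits stay attached to letters (``p53`` is a
single token).  Two exceptions keep biomedical identifiers intact:
alphanumeric slash compounds such as ``P42/44`` remain one token, and
apostrophes stay attached to the preceding characters (``C'``).  Hyphenated
names such as ``HNF-3`` are split into three tokens, so mentions may span
multiple tokens.

POS tagging, lemmatization and chunking are pluggable: any callable mapping
a list of token surfaces to equal-length POS/lemma/chunk lists can serve as
a backend.  The built-in :class:`DefaultBackend` is a deliberately simple
suffix-rule tagger (documented as approximate) so that heavyweight NLP
toolchains remain optional.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Callable, Protocol, Sequence

from .corpus import RawSentence

# Greek-letter lexicon shared by the tokenizer-adjacent code and the feature
# extractor.
GREEK_WORDS = frozenset(
    """alpha beta gamma delta epsilon zeta eta theta iota kappa lambda mu nu
    xi omicron pi rho sigma tau upsilon phi chi psi omega""".split()
) | frozenset("αβγδεζηθικλμνξοπρστυφχψω")

_ROMAN_RE = re.compile(r"^[IVXLCDM]+$")


def is_greek_word(s: str) -> bool:
    return s.lower() in GREEK_WORDS


def is_roman_numeral(s: str) -> bool:
    return bool(_ROMAN_RE.match(s))


@dataclass(frozen=True)
class Token:
    """A token with dual offsets: raw (half-open) and non-space (inclusive)."""

    surface: str
    raw_start: int
    raw_end: int
    ns_start: int
    ns_end: int
    pos: str = ""
    lemma: str = ""
    chunk: str = ""


@dataclass(frozen=True)
class TokenizedSentence:
    sentence_id: str
    text: str
    tokens: tuple[Token, ...]

    @property
    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]


_SENTENCE_END = re.compile(r"[.!?]+(?=\s+[A-Z(\"])")
# words after which a period never ends a sentence
_ABBREV_STOPLIST = frozenset(
    """e.g i.e etc al cf vs fig figs eq eqs ref refs dr mr mrs ms prof no
    approx ca wt mol sp spp st""".split()
)


def split_sentences(document: str) -> list[str]:
    """Split a document into sentences at terminal punctuation.

    A split happens after ``.``, ``!`` or ``?`` followed by whitespace and a
    capital letter (or an opening quote/parenthesis), unless the preceding
    word is on a fixed abbreviation stop-list (``e.g.``, ``et al.`` ...).
    """
    if not document.strip():
        return []
    cuts: list[int] = []
    for m in _SENTENCE_END.finditer(document):
        prefix = document[: m.start()]
        last_word = re.split(r"\s+", prefix.strip())[-1] if prefix.strip() else ""
        if last_word.lower().rstrip(".") in _ABBREV_STOPLIST:
            continue
        if last_word.lower() in _ABBREV_STOPLIST:
            continue
        cuts.append(m.end())
    sentences: list[str] = []
    prev = 0
    for cut in cuts:
        piece = document[prev:cut].strip()
        if piece:
            sentences.append(piece)
        prev = cut
    tail = document[prev:].strip()
    if tail:
        sentences.append(tail)
    return sentences


# punctuation characters that always become their own token; apostrophes and
# '+' deliberately absent so surfaces like C' and HexA+ survive
_SPLIT_PUNCT = set("()[]{}<>.,;:!?“”\"/-")
_SLASH_COMPOUND = re.compile(r"^[A-Za-z0-9]+(?:/[A-Za-z0-9]+)+$")


def _split_chunk(chunk: str) -> list[tuple[int, str]]:
    """Split one whitespace-free chunk into (offset, surface) subtokens."""
    if _SLASH_COMPOUND.match(chunk):
        return [(0, chunk)]
    pieces: list[tuple[int, str]] = []
    buf_start = 0
    i = 0
    while i < len(chunk):
        c = chunk[i]
        if c in _SPLIT_PUNCT:
            # keep a period between two digits (decimals such as 0.05)
            if (
                c == "."
                and 0 < i < len(chunk) - 1
                and chunk[i - 1].isdigit()
                and chunk[i + 1].isdigit()
            ):
                i += 1
                continue
            if i > buf_start:
                pieces.append((buf_start, chunk[buf_start:i]))
            pieces.append((i, c))
            buf_start = i + 1
        i += 1
    if buf_start < len(chunk):
        pieces.append((buf_start, chunk[buf_start:]))
    return pieces


def tokenize(sentence: RawSentence | str, sentence_id: str = "") -> TokenizedSentence:
    """Tokenize a sentence, recording raw and non-space offsets per token."""
    if isinstance(sentence, str):
        sentence = RawSentence(sentence_id or "S0", sentence)
    text = sentence.text
    # running count of non-space characters before each raw position
    ns_before = [0] * (len(text) + 1)
    for i, c in enumerate(text):
        ns_before[i + 1] = ns_before[i] + (0 if c.isspace() else 1)
    tokens: list[Token] = []
    for m in re.finditer(r"\S+", text):
        for off, surface in _split_chunk(m.group()):
            raw_start = m.start() + off
            raw_end = raw_start + len(surface)
            ns_start = ns_before[raw_start]
            tokens.append(
                Token(
                    surface=surface,
                    raw_start=raw_start,
                    raw_end=raw_end,
                    ns_start=ns_start,
                    ns_end=ns_start + len(surface) - 1,
                )
            )
    return TokenizedSentence(sentence.sentence_id, text, tuple(tokens))


class AnnotationBackend(Protocol):
    """Contract: token surfaces in, equal-length POS/lemma/chunk lists out."""

    def __call__(
        self, surfaces: Sequence[str]
    ) -> tuple[list[str], list[str], list[str]]: ...


_CLOSED_CLASS = {
    "and": "CC", "or": "CC", "but": "CC",
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "these": "DT",
    "of": "IN", "in": "IN", "by": "IN", "with": "IN", "for": "IN",
    "on": "IN", "from": "IN", "at": "IN", "as": "IN",
    "to": "TO",
    "was": "VBD", "were": "VBD", "is": "VBZ", "are": "VBP", "be": "VB",
    "can": "MD", "may": "MD", "not": "RB",
}

_VERB_SUFFIXES = ("ed", "ing", "ate", "ates", "ize", "izes", "yze", "yzes", "ify")


def _default_pos(surface: str) -> str:
    low = surface.lower()
    if low in _CLOSED_CLASS:
        return _CLOSED_CLASS[low]
    if all(not c.isalnum() for c in surface):
        return "PUNCT"
    if re.fullmatch(r"[\d.,]+", surface):
        return "CD"
    if low.endswith(_VERB_SUFFIXES) and len(low) > 4:
        return "VB"
    if low.endswith("s") and not low.endswith(("ss", "us", "is")) and _stem(low) and low[:-1].endswith(_VERB_SUFFIXES):
        return "VBZ"
    # capitalized or unknown tokens default to noun
    return "NN"


def _stem(low: str) -> str:
    return low[:-1]


def _default_lemma(surface: str) -> str:
    low = surface.lower()
    if low.endswith("ies") and len(surface) > 4:
        return surface[:-3] + "y"
    if low.endswith("sses"):
        return surface[:-2]
    if low.endswith("s") and not low.endswith(("ss", "us", "is")) and len(surface) > 3:
        return surface[:-1]
    return surface


class DefaultBackend:
    """Naive suffix-rule POS tagger, plural-stripping lemmatizer and NP chunker.

    This backend is intentionally approximate; it exists so the pipeline runs
    without an external NLP toolchain.  Its one load-bearing property is that
    gene-like and unknown tokens default to noun, which the corpus-frequency
    feature relies on.
    """

    def __call__(
        self, surfaces: Sequence[str]
    ) -> tuple[list[str], list[str], list[str]]:
        pos = [_default_pos(s) for s in surfaces]
        lemma = [_default_lemma(s) for s in surfaces]
        chunk: list[str] = []
        prev_np = False
        for p in pos:
            if p.startswith("NN") or p == "CD":
                chunk.append("I-NP" if prev_np else "B-NP")
                prev_np = True
            else:
                chunk.append("O")
                prev_np = False
        return pos, lemma, chunk


class IdentityBackend:
    """Leaves annotations untouched (surfaces echoed as POS/lemma)."""

    def __call__(
        self, surfaces: Sequence[str]
    ) -> tuple[list[str], list[str], list[str]]:
        s = list(surfaces)
        return s, s, ["O"] * len(s)


def annotate(
    sentence: TokenizedSentence,
    backend: AnnotationBackend | Callable | None = None,
) -> TokenizedSentence:
    """Fill POS/lemma/chunk slots using the given backend (default naive)."""
    if backend is None:
        backend = DefaultBackend()
    surfaces = sentence.surfaces
    try:
        pos, lemma, chunk = backend(surfaces)
    except Exception as exc:
        raise RuntimeError(
            f"annotation backend failed on sentence {sentence.sentence_id!r}: {exc}"
        ) from exc
    if not (len(pos) == len(lemma) == len(chunk) == len(surfaces)):
        raise RuntimeError(
            f"annotation backend returned misaligned lists for sentence "
            f"{sentence.sentence_id!r}"
        )
    tokens = tuple(
        replace(t, pos=p, lemma=l, chunk=c)
        for t, p, l, c in zip(sentence.tokens, pos, lemma, chunk)
    )
    return TokenizedSentence(sentence.sentence_id, sentence.text, tokens)


def preprocess_sentence(
    sentence: RawSentence, backend: AnnotationBackend | None = None
) -> TokenizedSentence:
    """Tokenize and annotate in one step."""
    return annotate(tokenize(sentence), backend)
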
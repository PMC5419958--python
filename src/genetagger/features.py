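"""Token feature extraction and PCA-based feature selection.

Each token receives a sparse set of string feature identifiers drawn from:

* a registry of exactly 32 basic orthographic/morphologic/affix feature
  types (INITCAPS, ALLCAPS, ... 2PREFIX..4SUFFIX, HASGREEK, PUNCTUATION);
* character N-grams over a sliding window of 4 characters;
* offset conjunctions copying the basic features of the two preceding and
  two following tokens with positional prefixes ``@-2:`` .. ``@+2:``;
* a corpus-frequency indicator that fires for noun tokens whose surface was
  seen as a training-corpus gene mention between 1 and ``theta_freq``
  (default 10) times — rare names get a dedicated signal so they are tagged
  consistently across sentences.

Identifiers are flat strings ``NAME`` or ``NAME=value``, optionally carrying
a positional prefix ``@±k:``.  Feature selection scores each original
feature by its maximum absolute loading over the first L principal
components of the sentence×feature occurrence matrix and keeps the top K,
so the CRF keeps working with sparse indicators.
"""

from __future__ import annotations

import re
import string
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .corpus import GeneMention
from .preprocess import Token, TokenizedSentence, is_greek_word, is_roman_numeral

_PUNCT = set(string.punctuation) | {"“", "”", "’", "‘"}


def _caps_count(s: str) -> int:
    return sum(1 for c in s if c.isupper())


def _alpha(s: str) -> str:
    return "".join(c for c in s if c.isalpha())


def _parts(s: str) -> list[str]:
    """Hyphen- or space-delimited parts of a surface."""
    return [p for p in re.split(r"[-\s]+", s) if p]


def _initcaps(s: str) -> bool:
    if not s or not s[0].isupper():
        return False
    rest = _alpha(s[1:])
    return not (rest and rest.isupper())


def _allcaps(s: str) -> bool:
    a = _alpha(s)
    return len(s) >= 2 and bool(a) and a.isupper()


def _endcaps(s: str) -> bool:
    # terminal uppercase preceded by a lowercase letter somewhere (IgA)
    if not s or not s[-1].isupper():
        return False
    i = len(s) - 1
    while i >= 0 and s[i].isupper():
        i -= 1
    return any(c.islower() for c in s[: i + 1])


def _upper_lower(s: str) -> bool:
    return len(s) >= 2 and s[0].isupper() and s[1:].isalpha() and s[1:].islower()


def _mixedcaps(s: str) -> bool:
    return bool(re.search(r"[a-z][A-Z]", s))


def _lowercase(s: str) -> bool:
    return s.isalpha() and s.islower()


def _alphanumeric(s: str) -> bool:
    return s.isalnum() and any(c.isdigit() for c in s) and any(c.isalpha() for c in s)


def _numbers_letters(s: str) -> bool:
    # digit/letter mix written in uppercase letters only (UR2)
    return _alphanumeric(s) and _alpha(s).isupper()


def _has_greek_part(s: str) -> bool:
    return any(is_greek_word(p) for p in _parts(s))


def _has_roman_part(s: str) -> bool:
    return any(is_roman_numeral(p) and len(p) >= 1 for p in _parts(s))


def _punctuation(s: str) -> bool:
    return bool(s) and all(c in _PUNCT for c in s)


def _bool_feature(name: str, pred: Callable[[str], bool]) -> Callable[[str], list[str]]:
    return lambda s: [name] if pred(s) else []


def _prefix_feature(n: int) -> Callable[[str], list[str]]:
    return lambda s: [f"{n}PREFIX={s[:n].lower()}"] if len(s) >= n else []


def _suffix_feature(n: int) -> Callable[[str], list[str]]:
    return lambda s: [f"{n}SUFFIX={s[-n:].lower()}"] if len(s) >= n else []


#: The 32 basic feature types.  Each entry maps a surface string to zero or
#: more feature identifiers; predicates are pure and not mutually exclusive.
FEATURE_REGISTRY: dict[str, Callable[[str], list[str]]] = {
    "INITCAPS": _bool_feature("INITCAPS", _initcaps),
    "ALLCAPS": _bool_feature("ALLCAPS", _allcaps),
    "ENDCAPS": _bool_feature("ENDCAPS", _endcaps),
    "UPPER-LOWER": _bool_feature("UPPER-LOWER", _upper_lower),
    "TWOCAPS": _bool_feature("TWOCAPS", lambda s: _caps_count(s) == 2),
    "THREECAPS": _bool_feature("THREECAPS", lambda s: _caps_count(s) == 3),
    "MORECAPS": _bool_feature("MORECAPS", lambda s: _caps_count(s) >= 4),
    "MIXEDCAPS": _bool_feature("MIXEDCAPS", _mixedcaps),
    "LOWERCASE": _bool_feature("LOWERCASE", _lowercase),
    "ENDDIGIT": _bool_feature("ENDDIGIT", lambda s: bool(s) and s[-1].isdigit()),
    "ALPHANUMERIC": _bool_feature("ALPHANUMERIC", _alphanumeric),
    "SINGLECHAR": _bool_feature("SINGLECHAR", lambda s: len(s) == 1),
    "NUMBERS_LETTERS": _bool_feature("NUMBERS_LETTERS", _numbers_letters),
    "HASDIGIT": _bool_feature("HASDIGIT", lambda s: any(c.isdigit() for c in s)),
    "GREEK": _bool_feature("GREEK", is_greek_word),
    "ROMAN": _bool_feature("ROMAN", is_roman_numeral),
    "HAS_QUOTE": _bool_feature("HAS_QUOTE", lambda s: any(c in "'’" for c in s)),
    "HAS_SLASH": _bool_feature("HAS_SLASH", lambda s: "/" in s),
    "END_PLUS": _bool_feature("END_PLUS", lambda s: s.endswith("+")),
    "END_QUOTE": _bool_feature("END_QUOTE", lambda s: bool(s) and s[-1] in "'’"),
    "HASDASH": _bool_feature("HASDASH", lambda s: "-" in s),
    "INITDASH": _bool_feature("INITDASH", lambda s: s.startswith("-")),
    "ENDDASH": _bool_feature("ENDDASH", lambda s: s.endswith("-")),
    "2PREFIX": _prefix_feature(2),
    "3PREFIX": _prefix_feature(3),
    "4PREFIX": _prefix_feature(4),
    "2SUFFIX": _suffix_feature(2),
    "3SUFFIX": _suffix_feature(3),
    "4SUFFIX": _suffix_feature(4),
    "HASGREEK": _bool_feature("HASGREEK", _has_greek_part),
    "HASROMAN": _bool_feature("HASROMAN", _has_roman_part),
    "PUNCTUATION": _bool_feature("PUNCTUATION", _punctuation),
}

assert len(FEATURE_REGISTRY) == 32


def basic_features(token: Token | str) -> set[str]:
    """All registry features firing on the token surface."""
    surface = token.surface if isinstance(token, Token) else token
    out: set[str] = set()
    for extract in FEATURE_REGISTRY.values():
        out.update(extract(surface))
    return out


def char_ngrams(
    token: Token | str, window: int = 4, mode: str = "window"
) -> set[str]:
    """Character N-gram features over a sliding window of ``window`` chars.

    ``mode="window"`` emits every contiguous window-sized substring (a token
    shorter than the window emits its whole surface); ``mode="prefix"``
    instead emits the leading substrings of length 1..window.  Single-char
    and pure-punctuation tokens emit nothing (noise control).
    """
    surface = token.surface if isinstance(token, Token) else token
    if len(surface) < 2 or _punctuation(surface):
        return set()
    if mode == "prefix":
        return {f"NGRAM={surface[:n]}" for n in range(1, min(window, len(surface)) + 1)}
    if mode != "window":
        raise ValueError(f"unknown ngram mode {mode!r}")
    if len(surface) <= window:
        return {f"NGRAM={surface}"}
    return {
        f"NGRAM={surface[i : i + window]}" for i in range(len(surface) - window + 1)
    }


def offset_conjunction(
    per_token_basic: Sequence[set[str]],
    position: int,
    offsets: Sequence[int] = (-2, -1, 1, 2),
) -> set[str]:
    """Copy neighbors' basic features with positional prefixes.

    Out-of-range offsets contribute an ``EDGE`` boundary marker instead, so
    sentence-initial and sentence-final contexts are distinguishable.
    """
    if not 0 <= position < len(per_token_basic):
        raise IndexError(f"position {position} outside sentence")
    out: set[str] = set()
    for off in offsets:
        j = position + off
        prefix = f"@{off:+d}:"
        if 0 <= j < len(per_token_basic):
            out.update(prefix + f for f in per_token_basic[j])
        else:
            out.add(prefix + "EDGE")
    return out


_POSITION_PREFIX = re.compile(r"^@([+-])(\d+):(.*)$")


def mirror_feature_id(fid: str) -> str:
    """Swap the sign of a positional prefix (``@-1:`` <-> ``@+1:``).

    Used when re-orienting features between forward and backward reading
    order; identifiers without a positional prefix are unchanged.
    """
    m = _POSITION_PREFIX.match(fid)
    if not m:
        return fid
    sign = "+" if m.group(1) == "-" else "-"
    return f"@{sign}{m.group(2)}:{m.group(3)}"


@dataclass
class FrequencyTable:
    """Occurrence counts of gene-mention surfaces over a training corpus.

    ``theta_freq`` is the upper bound of the frequency band: the
    corpus-frequency feature fires for phrases seen between 1 and
    ``theta_freq`` times, flagging rare names so they are tagged uniformly.
    """

    counts: Counter = field(default_factory=Counter)
    theta_freq: int = 10

    @classmethod
    def build(
        cls, mentions: Iterable[GeneMention], theta_freq: int = 10
    ) -> "FrequencyTable":
        counts = Counter(m.text for m in mentions)
        return cls(counts=counts, theta_freq=theta_freq)

    def cf(self, phrase: str) -> int:
        return self.counts.get(phrase, 0)


def build_frequency_table(
    mentions: Iterable[GeneMention], theta_freq: int = 10
) -> FrequencyTable:
    return FrequencyTable.build(mentions, theta_freq)


def corpus_frequency_feature(
    token: Token, table: FrequencyTable, inverse: bool = False
) -> set[str]:
    """CORPUS_FREQ indicator for noun tokens inside the frequency band.

    With ``inverse=True`` the band is flipped (fires for frequent names
    instead), exposed for experimentation.
    """
    if not token.pos.startswith("NN"):
        return set()
    c = table.cf(token.surface)
    in_band = 1 <= c <= table.theta_freq
    if inverse:
        in_band = c > table.theta_freq
    return {"CORPUS_FREQ"} if in_band else set()


@dataclass
class FeatureExtractorConfig:
    ngram_window: int = 4
    ngram_mode: str = "window"  # or "prefix"
    conjunction_offsets: tuple[int, ...] = (-2, -1, 1, 2)
    theta_freq: int = 10
    freq_inverse: bool = False
    include_pos: bool = True
    include_ngrams: bool = True


class FeatureExtractor:
    """Assemble the full per-token feature sets for a tokenized sentence."""

    def __init__(self, config: FeatureExtractorConfig | None = None) -> None:
        self.config = config or FeatureExtractorConfig()

    def extract(
        self,
        sentence: TokenizedSentence,
        freq_table: FrequencyTable | None = None,
        keep: frozenset[str] | None = None,
    ) -> list[frozenset[str]]:
        """Per-token feature sets; ``keep`` optionally restricts identifiers
        (the output of PCA selection)."""
        cfg = self.config
        basics = [basic_features(t) for t in sentence.tokens]
        out: list[frozenset[str]] = []
        for i, tok in enumerate(sentence.tokens):
            feats = set(basics[i])
            if cfg.include_ngrams:
                feats |= char_ngrams(tok, cfg.ngram_window, cfg.ngram_mode)
            feats |= offset_conjunction(basics, i, cfg.conjunction_offsets)
            if cfg.include_pos and tok.pos:
                feats.add(f"POS={tok.pos}")
            if freq_table is not None:
                feats |= corpus_frequency_feature(tok, freq_table, cfg.freq_inverse)
            if keep is not None:
                feats &= keep
            out.append(frozenset(feats))
        return out


def dump_features(per_token: Sequence[Iterable[str]]) -> str:
    """One token per line, tab-separated sorted identifiers (debug format)."""
    return "\n".join("\t".join(sorted(feats)) for feats in per_token)


def occurrence_matrix(
    sentence_features: Sequence[Sequence[Iterable[str]]],
) -> tuple[np.ndarray, list[str]]:
    """Sentence×feature binary occurrence matrix over all seen identifiers."""
    names = sorted({f for sent in sentence_features for tok in sent for f in tok})
    index = {f: j for j, f in enumerate(names)}
    X = np.zeros((len(sentence_features), len(names)))
    for i, sent in enumerate(sentence_features):
        for tok in sent:
            for f in tok:
                X[i, index[f]] = 1.0
    return X, names


class PcaFeatureSelector(BaseEstimator):
    """Select original sparse features by principal-component loadings.

    Columns are mean-centered, the eigendecomposition of the feature
    covariance is computed, every feature is scored by its maximum absolute
    loading over the first ``n_components`` eigenvectors, and the
    ``n_keep`` best-scoring features are retained.  The selector keeps the
    original indicator features (it does not project tokens into dense
    space), so downstream CRF training still sees sparse indicators.
    """

    def __init__(self, n_components: int = 10, n_keep: int | None = None) -> None:
        self.n_components = n_components
        self.n_keep = n_keep

    def fit(self, X: np.ndarray, y: None = None) -> "PcaFeatureSelector":
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("empty occurrence matrix")
        if np.allclose(X.var(axis=0), 0.0):
            raise ValueError("degenerate matrix: every feature has zero variance")
        n_samples, n_features = X.shape
        L = min(self.n_components, n_samples - 1 if n_samples > 1 else 1, n_features)
        pca = PCA(n_components=L, svd_solver="full")
        pca.fit(X)
        self.eigenvalues_ = np.asarray(pca.explained_variance_)
        self.components_ = np.asarray(pca.components_)  # (L, n_features)
        self.scores_ = np.abs(self.components_).max(axis=0)
        k = n_features if self.n_keep is None else min(self.n_keep, n_features)
        # stable top-K: higher score first, ties by lower column index
        order = np.lexsort((np.arange(n_features), -self.scores_))
        sel = np.sort(order[:k])
        self.support_ = np.zeros(n_features, dtype=bool)
        self.support_[sel] = True
        self.selected_indices_ = sel
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X)[:, self.support_]


def pca_select(
    X: np.ndarray,
    names: Sequence[str],
    n_components: int,
    n_keep: int,
) -> tuple[list[str], np.ndarray]:
    """Retained feature identifiers and the PCA eigenvalues (descending)."""
    sel = PcaFeatureSelector(n_components=n_components, n_keep=n_keep).fit(X)
    return [names[j] for j in sel.selected_indices_], sel.eigenvalues_
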
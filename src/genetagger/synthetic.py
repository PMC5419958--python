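"""Deterministic toy-corpus generator in the BC2GM plain-text formats.

The generator writes sentence and annotation files whose gene surfaces
follow the orthographic morphology real gene/protein names exhibit —
all-caps symbols, letter+digit identifiers, mixed-case restriction-enzyme
style names, Greek-letter and Roman-numeral compounds, trailing
plus/dash/apostrophe variants — while the non-gene vocabulary is lowercase
common words.  Configurable fractions of sentences contain ``Long Form
(SF)`` abbreviation constructs, parenthesized mentions, and
relation/connective keyword contexts, so every feature predicate and every
post-processing rule is exercised.  Generation is a pure function of the
config: identical configs produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .corpus import GeneMention, RawSentence
from .postprocess import DEFAULT_RELATION_WORDS

_COMMON_WORDS = (
    "study results showed that levels increased decreased cells patients "
    "samples analysis treatment response observed measured significant "
    "role effect pathway process membrane signal tissue model system "
    "method assay control group present absent early late total serum "
    "human mouse rat liver brain blood tumor normal clinical expression"
).split()

_VERBS = (
    "activates inhibits binds regulates phosphorylates induces suppresses "
    "mediates encodes stimulates"
).split()

# long-form word pools; these words appear only inside long-form mentions
_LF_FIRST = "Brown Nuclear Hepatic Vascular Epidermal Insulin Tumor Basic".split()
_LF_MIDDLE = (
    "adipose nuclear receptor growth necrosis derived endothelial "
    "fibroblast transcription epithelial"
).split()
_LF_LAST = "tissue factor kinase enzyme protein antigen".split()

_GREEK = "alpha beta gamma delta kappa sigma".split()
_ROMAN = "II III IV IX XI".split()


@dataclass(frozen=True)
class ToyCorpusConfig:
    """Study conditions for one generated corpus.

    Probabilities select a sentence template; the remainder are plain or
    connective sentences.  Generation is deterministic in ``seed``.
    """

    seed: int = 0
    n_sentences: int = 200
    gene_lexicon_size: int = 200
    p_abbreviation: float = 0.15
    p_parenthesized: float = 0.2
    p_relation_keyword: float = 0.3
    id_prefix: str = "SYN"

    def __post_init__(self) -> None:
        for p in (self.p_abbreviation, self.p_parenthesized, self.p_relation_keyword):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.gene_lexicon_size < 1:
            raise ValueError("gene lexicon must be non-empty")


def _caps(rng: np.random.Generator, lo: int = 2, hi: int = 4) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(chr(int(rng.integers(65, 91))) for _ in range(n))


def _lower(rng: np.random.Generator, lo: int = 3, hi: int = 7) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(chr(int(rng.integers(97, 123))) for _ in range(n))


def generate_gene_lexicon(size: int, rng: np.random.Generator) -> list[str]:
    """Gene surfaces mixing the orthographic styles real symbols show."""
    makers = [
        lambda: _caps(rng, 2, 5),                                   # SGPT
        lambda: _lower(rng, 1, 2) + str(rng.integers(1, 100)),      # p53
        lambda: _caps(rng, 2, 3) + "-" + str(rng.integers(1, 20)),  # Ap-2
        lambda: _caps(rng, 2, 4) + "-" + _GREEK[int(rng.integers(len(_GREEK)))],
        lambda: _lower(rng, 3, 5).capitalize() + _caps(rng, 1, 2),  # EcoRI-ish
        lambda: _lower(rng, 3, 6).capitalize() + str(rng.integers(1, 20)),
        lambda: _caps(rng, 1, 1) + _lower(rng, 1, 2) + _caps(rng, 1, 1),  # IgA
        lambda: _caps(rng, 2, 3) + str(rng.integers(10, 99)),       # CD45, UR2
        lambda: _lower(rng, 4, 7),                                  # insulin
        lambda: _lower(rng, 3, 5).capitalize(),                     # Sonic
        lambda: _caps(rng, 2, 4) + str(rng.integers(1, 50)) + "/" + str(rng.integers(1, 50)),
        lambda: _caps(rng, 3, 4) + "+",                             # HexA+
        lambda: _caps(rng, 2, 3) + str(rng.integers(10, 60)) + "-", # CD45-
        lambda: _lower(rng, 2, 3) + _caps(rng, 1, 1) + "'",         # gstC'
        lambda: _lower(rng, 4, 6) + " " + _ROMAN[int(rng.integers(len(_ROMAN)))],
        lambda: _GREEK[int(rng.integers(len(_GREEK)))].capitalize(),
    ]
    lexicon: list[str] = []
    seen: set[str] = set()
    while len(lexicon) < size:
        surface = makers[int(rng.integers(len(makers)))]()
        if surface not in seen:
            seen.add(surface)
            lexicon.append(surface)
    return lexicon


def _nonspace_len(s: str) -> int:
    return sum(1 for c in s if not c.isspace())


class _SentenceBuilder:
    """Accumulates words and mention spans with non-space offset tracking."""

    def __init__(self) -> None:
        self.words: list[str] = []
        self.spans: list[tuple[int, int, str]] = []
        self._ns = 0

    def word(self, w: str) -> None:
        self.words.append(w)
        self._ns += _nonspace_len(w)

    def words_from(self, ws: str) -> None:
        for w in ws.split():
            self.word(w)

    def gene(self, surface: str) -> None:
        start = self._ns
        self.word(surface)
        self.spans.append((start, self._ns - 1, surface))

    @property
    def text(self) -> str:
        return " ".join(self.words)


def _pick(rng: np.random.Generator, seq: list[str]) -> str:
    return seq[int(rng.integers(len(seq)))]


def _make_abbreviation(rng: np.random.Generator) -> tuple[str, str]:
    words = [
        _pick(rng, _LF_FIRST),
        _pick(rng, _LF_MIDDLE),
        _pick(rng, _LF_LAST),
    ]
    sf = "".join(w[0].upper() for w in words)
    return " ".join(words), sf


_RELATION_SAMPLE = sorted(DEFAULT_RELATION_WORDS)


def _build_sentence(
    rng: np.random.Generator,
    lexicon: list[str],
    cfg: ToyCorpusConfig,
) -> _SentenceBuilder:
    b = _SentenceBuilder()
    gene = lambda: _pick(rng, lexicon)
    w = lambda: _pick(rng, _COMMON_WORDS)
    v = lambda: _pick(rng, _VERBS)
    r = rng.random()
    if r < cfg.p_abbreviation:
        lf, sf = _make_abbreviation(rng)
        b.words_from(f"the {w()}")
        start = b._ns
        b.words_from(lf)
        b.spans.append((start, b._ns - 1, lf))
        b.word("(")
        b.gene(sf)
        b.word(")")
        b.words_from(f"{v()} {w()} in {w()} {w()} .")
    elif r < cfg.p_abbreviation + cfg.p_parenthesized:
        b.words_from(f"the {w()} {w()} (")
        b.gene(gene())
        b.words_from(f") was {w()} in {w()} .")
    elif r < cfg.p_abbreviation + cfg.p_parenthesized + cfg.p_relation_keyword:
        b.gene(gene())
        b.word(_pick(rng, _RELATION_SAMPLE))
        b.gene(gene())
        b.words_from(f"in {w()} {w()} .")
    elif r < cfg.p_abbreviation + cfg.p_parenthesized + cfg.p_relation_keyword + 0.2:
        b.words_from(f"{w()} {w()} ,")
        b.gene(gene())
        b.word(_pick(rng, ["and", "or"]))
        b.gene(gene())
        b.words_from(f", were {w()} .")
    else:
        b.words_from(f"the {w()} of")
        b.gene(gene())
        b.words_from(f"was {w()} in {w()} {w()} .")
    return b


def generate_corpus(
    config: ToyCorpusConfig, lexicon: list[str] | None = None
) -> tuple[str, str]:
    """Generate (sentence file content, annotation file content).

    A caller may supply the gene lexicon (e.g. a held-out lexicon mixing
    seen and unseen surfaces); by default one is generated from the config.
    """
    if config.n_sentences < 1:
        raise ValueError("n_sentences must be >= 1")
    rng = np.random.default_rng(config.seed)
    if lexicon is None:
        lexicon = generate_gene_lexicon(config.gene_lexicon_size, rng)
    if not lexicon:
        raise ValueError("gene lexicon must be non-empty")
    sent_lines: list[str] = []
    ann_lines: list[str] = []
    for i in range(config.n_sentences):
        sid = f"{config.id_prefix}{i:05d}"
        b = _build_sentence(rng, lexicon, config)
        sent_lines.append(f"{sid} {b.text}")
        for start, end, surface in b.spans:
            ann_lines.append(f"{sid}|{start} {end}|{surface}")
    return "\n".join(sent_lines) + "\n", "\n".join(ann_lines) + "\n"


def parse_corpus_strings(
    sentence_content: str, annotation_content: str
) -> tuple[list[RawSentence], list[GeneMention]]:
    """Parse generated corpus content without touching the filesystem."""
    sentences = []
    for line in sentence_content.splitlines():
        if line.strip():
            sid, text = line.split(" ", 1)
            sentences.append(RawSentence(sid, text))
    mentions = []
    for line in annotation_content.splitlines():
        if line.strip():
            sid, span, text = line.split("|", 2)
            s, e = span.split()
            mentions.append(GeneMention(sid, int(s), int(e), text))
    return sentences, mentions


def generate_train_test(
    seed: int = 0,
    n_train: int = 300,
    n_test: int = 100,
    gene_lexicon_size: int = 200,
    unseen_fraction: float = 0.2,
    **kwargs,
) -> tuple[
    tuple[list[RawSentence], list[GeneMention]],
    tuple[list[RawSentence], list[GeneMention]],
]:
    """Generate a train/test split sharing most — not all — gene surfaces.

    The test lexicon keeps ``1 - unseen_fraction`` of the training surfaces
    and replaces the rest with fresh ones, so orthographic generalization
    (not memorization) is required of a tagger scoring well on the test
    half.
    """
    rng = np.random.default_rng(seed)
    train_lexicon = generate_gene_lexicon(gene_lexicon_size, rng)
    n_unseen = int(round(unseen_fraction * gene_lexicon_size))
    kept = list(train_lexicon[: gene_lexicon_size - n_unseen])
    fresh: list[str] = []
    taken = set(train_lexicon)
    while len(fresh) < n_unseen:
        cand = generate_gene_lexicon(1, rng)[0]
        if cand not in taken:
            taken.add(cand)
            fresh.append(cand)
    test_lexicon = kept + fresh

    train_cfg = ToyCorpusConfig(
        seed=seed + 1, n_sentences=n_train,
        gene_lexicon_size=gene_lexicon_size, id_prefix="TRN", **kwargs,
    )
    test_cfg = ToyCorpusConfig(
        seed=seed + 2, n_sentences=n_test,
        gene_lexicon_size=gene_lexicon_size, id_prefix="TST", **kwargs,
    )
    train = parse_corpus_strings(*generate_corpus(train_cfg, train_lexicon))
    test = parse_corpus_strings(*generate_corpus(test_cfg, test_lexicon))
    return train, test
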
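"""BioCreative II GM corpus I/O and span/label conversions.

The corpus distribution uses two plain-text formats:

* a sentence file with one sentence per line, ``<sentence_id> <text>``;
* an annotation file with one gene mention per line,
  ``<sentence_id>|<start> <end>|<mention text>``, where ``start`` and ``end``
  are 0-based inclusive character offsets counted over the *non-whitespace*
  characters of the sentence.

This module parses and writes both formats and converts between mention
spans and per-token B/I/O label sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

if TYPE_CHECKING:  # pragma: no cover - type-only import
    from .preprocess import TokenizedSentence

LABELS = ("B", "I", "O")


class FormatError(ValueError):
    """A corpus file line does not follow the expected format."""


class AlignmentError(ValueError):
    """A mention span does not align with token boundaries."""


@dataclass(frozen=True)
class RawSentence:
    """A sentence as read from a BC2GM sentence file."""

    sentence_id: str
    text: str

    def __post_init__(self) -> None:
        if any(c.isspace() for c in self.sentence_id):
            raise FormatError(f"sentence id contains whitespace: {self.sentence_id!r}")
        if not self.text:
            raise FormatError(f"empty sentence text for id {self.sentence_id!r}")


@dataclass(frozen=True, order=True)
class GeneMention:
    """A gene/protein mention located by non-space character offsets.

    ``start`` and ``end`` are 0-based inclusive indices into the sequence of
    non-whitespace characters of the sentence; ``text`` is the surface string
    with the original intervening whitespace restored.
    """

    sentence_id: str
    start: int
    end: int
    text: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start > self.end:
            raise FormatError(
                f"invalid mention span {self.start}..{self.end} in {self.sentence_id!r}"
            )

    @property
    def key(self) -> tuple[str, int, int]:
        """Identity used for exact-span matching."""
        return (self.sentence_id, self.start, self.end)


def parse_sentence_file(path: str | Path) -> list[RawSentence]:
    """Read a BC2GM sentence file: one ``<id> <text>`` per non-blank line."""
    sentences: list[RawSentence] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if " " not in line:
                raise FormatError(f"{path}:{lineno}: no space separator in {line!r}")
            sid, text = line.split(" ", 1)
            sentences.append(RawSentence(sid, text))
    return sentences


def write_sentence_file(path: str | Path, sentences: Iterable[RawSentence]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sentences:
            fh.write(f"{s.sentence_id} {s.text}\n")


def _parse_annotation_line(line: str, context: str) -> GeneMention:
    parts = line.split("|", 2)
    if len(parts) != 3:
        raise FormatError(f"{context}: expected two '|' separators in {line!r}")
    sid, span, text = parts
    fields = span.split()
    if len(fields) != 2:
        raise FormatError(f"{context}: expected '<start> <end>' in {span!r}")
    try:
        start, end = int(fields[0]), int(fields[1])
    except ValueError as exc:
        raise FormatError(f"{context}: non-integer offsets in {span!r}") from exc
    try:
        return GeneMention(sid, start, end, text)
    except FormatError as exc:
        raise FormatError(f"{context}: {exc}") from exc


def parse_annotation_file(path: str | Path) -> list[GeneMention]:
    """Read a GENE/ALTGENE annotation file, one mention per line."""
    mentions: list[GeneMention] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            mentions.append(_parse_annotation_line(line, f"{path}:{lineno}"))
    return mentions


def format_annotation(mention: GeneMention) -> str:
    return f"{mention.sentence_id}|{mention.start} {mention.end}|{mention.text}"


def write_annotation_file(path: str | Path, mentions: Iterable[GeneMention]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in mentions:
            fh.write(format_annotation(m) + "\n")


def group_by_sentence(mentions: Iterable[GeneMention]) -> dict[str, list[GeneMention]]:
    grouped: dict[str, list[GeneMention]] = {}
    for m in mentions:
        grouped.setdefault(m.sentence_id, []).append(m)
    return grouped


@dataclass(frozen=True)
class NonspaceMap:
    """Bijection between raw character positions and non-space positions."""

    to_raw: tuple[int, ...]  # non-space index -> raw index

    def raw_to_nonspace(self, raw_index: int) -> int:
        # binary search not needed: build the inverse lazily via dict lookup
        try:
            return self._inverse()[raw_index]
        except KeyError as exc:
            raise KeyError(f"raw index {raw_index} is whitespace or out of range") from exc

    def nonspace_to_raw(self, ns_index: int) -> int:
        return self.to_raw[ns_index]

    def _inverse(self) -> dict[int, int]:
        inv = self.__dict__.get("_inv")
        if inv is None:
            inv = {raw: ns for ns, raw in enumerate(self.to_raw)}
            object.__setattr__(self, "_inv", inv)
        return inv

    def __len__(self) -> int:
        return len(self.to_raw)


def nonspace_index_map(text: str) -> NonspaceMap:
    """Map every non-whitespace character to its non-space ordinal and back."""
    return NonspaceMap(tuple(i for i, c in enumerate(text) if not c.isspace()))


def mentions_to_bio(
    sentence: "TokenizedSentence", mentions: Sequence[GeneMention]
) -> list[str]:
    """Convert token-aligned mention spans to a B/I/O label sequence.

    The first token of each mention is labeled B and subsequent tokens I;
    every other token is O.  A mention whose span does not coincide with
    token boundaries raises :class:`AlignmentError`.
    """
    starts = {t.ns_start: i for i, t in enumerate(sentence.tokens)}
    ends = {t.ns_end: i for i, t in enumerate(sentence.tokens)}
    labels = ["O"] * len(sentence.tokens)
    for m in mentions:
        if m.start not in starts or m.end not in ends:
            raise AlignmentError(
                f"mention {format_annotation(m)!r} does not align with token "
                f"boundaries of sentence {sentence.sentence_id!r}"
            )
        i, j = starts[m.start], ends[m.end]
        if j < i:
            raise AlignmentError(f"mention {format_annotation(m)!r} spans no token")
        if any(labels[k] != "O" for k in range(i, j + 1)):
            raise AlignmentError(
                f"mention {format_annotation(m)!r} overlaps another mention"
            )
        labels[i] = "B"
        for k in range(i + 1, j + 1):
            labels[k] = "I"
    return labels


def bio_to_mentions(
    sentence: "TokenizedSentence", labels: Sequence[str]
) -> list[GeneMention]:
    """Decode a B/I/O label sequence into mentions.

    Maximal ``B I*`` runs become mentions.  An orphan I (an I following O or
    at sentence start) is healed to B so that every label sequence decodes,
    which matters after rule-based label edits.
    """
    if len(labels) != len(sentence.tokens):
        raise AlignmentError(
            f"{len(labels)} labels for {len(sentence.tokens)} tokens in "
            f"sentence {sentence.sentence_id!r}"
        )
    mentions: list[GeneMention] = []
    run_start: int | None = None
    for i, lab in enumerate(labels):
        if lab not in LABELS:
            raise AlignmentError(f"unknown label {lab!r} at position {i}")
        if lab == "B" or (lab == "I" and run_start is None):
            if run_start is not None:
                mentions.append(_span_to_mention(sentence, run_start, i - 1))
            run_start = i
        elif lab == "O":
            if run_start is not None:
                mentions.append(_span_to_mention(sentence, run_start, i - 1))
                run_start = None
    if run_start is not None:
        mentions.append(_span_to_mention(sentence, run_start, len(labels) - 1))
    return mentions


def _span_to_mention(sentence: "TokenizedSentence", i: int, j: int) -> GeneMention:
    first, last = sentence.tokens[i], sentence.tokens[j]
    text = sentence.text[first.raw_start : last.raw_end]
    return GeneMention(sentence.sentence_id, first.ns_start, last.ns_end, text)
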
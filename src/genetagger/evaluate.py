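"""Exact-span mention evaluation: TP/FP/FN and precision/recall/F-score.

A predicted mention counts as a true positive when its
(sentence, start, end) span exactly equals a gold span — or, when an
alternate-annotation set is supplied (the ALTGENE convention), any of that
gold mention's acceptable alternate spans.  Each gold mention is credited
at most once.  No partial credit is given.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .corpus import GeneMention


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_score: float

    def as_dict(self) -> dict:
        return {
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f_score,
        }


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F-score with zero-denominator guards."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


def match_mentions(
    gold: Iterable[GeneMention],
    predicted: Iterable[GeneMention],
    alternates: Mapping[tuple, Sequence[GeneMention]] | None = None,
) -> tuple[int, int, int]:
    """Exact-span matching; returns (TP, FP, FN).

    ``alternates`` optionally maps a gold mention key (sentence_id, start,
    end) to acceptable alternate spans; a prediction hitting an alternate
    credits the corresponding gold mention, each gold mention at most once.
    """
    gold = list(gold)
    span_to_gold: dict[tuple, int] = {}
    for gi, m in enumerate(gold):
        span_to_gold.setdefault(m.key, gi)
    if alternates:
        for gkey, alts in alternates.items():
            owners = [gi for gi, m in enumerate(gold) if m.key == gkey]
            if not owners:
                continue
            for alt in alts:
                span_to_gold.setdefault(alt.key, owners[0])
    credited: set[int] = set()
    tp = fp = 0
    for p in predicted:
        gi = span_to_gold.get(p.key)
        if gi is not None and gi not in credited:
            credited.add(gi)
            tp += 1
        else:
            fp += 1
    fn = len(gold) - len(credited)
    return tp, fp, fn


def evaluate_mentions(
    gold: Iterable[GeneMention],
    predicted: Iterable[GeneMention],
    alternates: Mapping[tuple, Sequence[GeneMention]] | None = None,
) -> EvalResult:
    tp, fp, fn = match_mentions(gold, predicted, alternates)
    p, r, f = prf(tp, fp, fn)
    return EvalResult(tp, fp, fn, p, r, f)


def alternates_from_mentions(
    alt_mentions: Iterable[GeneMention],
    gold: Iterable[GeneMention],
) -> dict[tuple, list[GeneMention]]:
    """Group an ALTGENE-style flat mention list by the gold mention whose
    span overlaps each alternate (sentence-local overlap heuristic)."""
    grouped: dict[tuple, list[GeneMention]] = {}
    gold = list(gold)
    for alt in alt_mentions:
        owner = None
        for g in gold:
            if g.sentence_id == alt.sentence_id and not (
                alt.end < g.start or alt.start > g.end
            ):
                owner = g
                break
        if owner is not None:
            grouped.setdefault(owner.key, []).append(alt)
    return grouped


def format_report(result: EvalResult, title: str = "overall") -> str:
    return (
        f"{title}\tTP={result.tp}\tFP={result.fp}\tFN={result.fn}\t"
        f"P={result.precision:.4f}\tR={result.recall:.4f}\tF={result.f_score:.4f}"
    )


def per_sentence_results(
    gold: Iterable[GeneMention],
    predicted: Iterable[GeneMention],
) -> dict[str, EvalResult]:
    by_sid_gold: dict[str, list[GeneMention]] = {}
    by_sid_pred: dict[str, list[GeneMention]] = {}
    for m in gold:
        by_sid_gold.setdefault(m.sentence_id, []).append(m)
    for m in predicted:
        by_sid_pred.setdefault(m.sentence_id, []).append(m)
    out = {}
    for sid in sorted(set(by_sid_gold) | set(by_sid_pred)):
        out[sid] = evaluate_mentions(
            by_sid_gold.get(sid, []), by_sid_pred.get(sid, [])
        )
    return out
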
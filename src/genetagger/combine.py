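"""Combining forward and backward directional models.

Three integration strategies are provided:

* **union / intersection** of the two models' mention sets — the classical
  trade-off (union raises recall, intersection raises precision);
* **MIRA combination**: the backward model's weights are re-oriented into
  forward reading order and summed with the forward weights, then the
  margin-infused relaxed algorithm refines the summed vector online.  For
  each training sentence, if the current weights already decode the gold
  labels nothing changes; otherwise the minimal-norm update

      w <- w + tau * (Phi(x, y) - Phi(x, y_hat)),
      tau = max(0, [L(y, y_hat) - (score(x,y) - score(x,y_hat))] / ||dPhi||^2)

  is applied, with L the Hamming label loss, so the gold sequence outscores
  the decoded one by at least its loss.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .corpus import GeneMention
from .crf import (
    LABELS,
    LABEL_INDEX,
    N_LABELS,
    START,
    CrfModel,
    CrfTagger,
    FeatureSets,
    _mention_spans,
    encode_direction,
    reverse_labels,
)
from .features import mirror_feature_id


def union_mentions(
    a: Iterable[GeneMention], b: Iterable[GeneMention]
) -> list[GeneMention]:
    """Set union by (sentence_id, start, end), first-seen surface kept."""
    seen: dict[tuple, GeneMention] = {}
    for m in list(a) + list(b):
        seen.setdefault(m.key, m)
    return sorted(seen.values())


def intersect_mentions(
    a: Iterable[GeneMention], b: Iterable[GeneMention]
) -> list[GeneMention]:
    """Exact-span set intersection."""
    keys_b = {m.key for m in b}
    seen: dict[tuple, GeneMention] = {}
    for m in a:
        if m.key in keys_b:
            seen.setdefault(m.key, m)
    return sorted(seen.values())


def mirror_weights(
    feature_index: dict[str, int],
    state_weights: np.ndarray,
    trans_weights: np.ndarray,
) -> tuple[dict[str, int], np.ndarray, np.ndarray]:
    """Re-orient a weight map between reading directions (an involution on
    real-label trigrams and position-prefixed features).

    State features keep their weights under mirrored identifiers
    (``@-k:`` <-> ``@+k:``); a transition trigram (a, b, c) becomes
    (c, b, a).  Trigrams whose two-back context is START describe the start
    of the reversed reading order — the end of the forward order, which the
    forward parameterization does not model — and are dropped.
    """
    names = sorted(feature_index, key=feature_index.get)
    new_names = [mirror_feature_id(n) for n in names]
    order = np.argsort(new_names, kind="stable")
    new_index = {new_names[j]: i for i, j in enumerate(order)}
    W = state_weights[order]
    T = np.zeros_like(trans_weights)
    for a in range(3):  # real labels only; START-context trigrams dropped
        for b in range(3):
            for c in range(3):
                T[c, b, a] = trans_weights[a, b, c]
    return new_index, W, T


def map_backward_weights(backward: CrfModel) -> CrfModel:
    """Forward-oriented copy of a backward-trained model's weights."""
    if backward.direction != "backward":
        raise ValueError(f"expected a backward model, got {backward.direction!r}")
    idx, W, T = mirror_weights(
        backward.feature_index, backward.state_weights, backward.trans_weights
    )
    return CrfModel(
        direction="forward",
        feature_index=idx,
        state_weights=W,
        trans_weights=T,
        meta={"mapped_from": "backward"},
    )


def global_feature_vector(
    feats_idx: Sequence[np.ndarray], labels: Sequence[str]
) -> dict[tuple, int]:
    """Phi(x, y): sentence-level feature-context counts for one labeling.

    Keys are ``("s", feature_index, label)`` for state features and
    ``("t", a, b, c)`` for transition trigrams; values are non-negative
    counts.
    """
    y = [LABEL_INDEX[l] for l in labels]
    phi: dict[tuple, int] = {}
    for i, idx in enumerate(feats_idx):
        for f in idx:
            key = ("s", int(f), y[i])
            phi[key] = phi.get(key, 0) + 1
    for i in range(1, len(y)):
        a = START if i == 1 else y[i - 2]
        key = ("t", a, y[i - 1], y[i])
        phi[key] = phi.get(key, 0) + 1
    return phi


def _phi_diff(
    phi_gold: dict[tuple, int], phi_pred: dict[tuple, int]
) -> dict[tuple, int]:
    diff = dict(phi_gold)
    for k, v in phi_pred.items():
        diff[k] = diff.get(k, 0) - v
        if diff[k] == 0:
            del diff[k]
    return diff


def hamming_loss(y: Sequence[str], y_hat: Sequence[str]) -> int:
    return sum(1 for a, b in zip(y, y_hat) if a != b)


def mira_update(
    W: np.ndarray,
    T: np.ndarray,
    diff: dict[tuple, int],
    loss: float,
    margin: float,
) -> float:
    """Apply the closed-form 1-best MIRA update in place; returns tau."""
    norm2 = float(sum(v * v for v in diff.values()))
    if norm2 == 0.0:
        return 0.0
    tau = max(0.0, (loss - margin) / norm2)
    if tau > 0.0:
        for key, v in diff.items():
            if key[0] == "s":
                W[key[1], key[2]] += tau * v
            else:
                T[key[1], key[2], key[3]] += tau * v
    return tau


def mira_combine(
    forward: CrfModel,
    backward: CrfModel,
    X: Sequence[FeatureSets],
    y: Sequence[Sequence[str]],
    epochs: int = 5,
) -> CrfModel:
    """Sum the two directional weight maps and refine with 1-best MIRA.

    The combined vector is forward-oriented over the union feature space.
    Training sentences are visited in corpus order (no shuffling) for each
    epoch; sentences already decoded correctly trigger no update.
    """
    mapped = map_backward_weights(backward)
    names = sorted(set(forward.feature_index) | set(mapped.feature_index))
    index = {n: i for i, n in enumerate(names)}
    W = np.zeros((len(names), N_LABELS))
    for n, i in forward.feature_index.items():
        W[index[n]] += forward.state_weights[i]
    for n, i in mapped.feature_index.items():
        W[index[n]] += mapped.state_weights[i]
    T = forward.trans_weights + mapped.trans_weights

    prepared = []
    for feats, labels in zip(X, y):
        idx = [
            np.array(sorted(index[f] for f in fs if f in index), dtype=int)
            for fs in feats
        ]
        prepared.append((idx, list(labels)))

    from .crf import _emissions, sequence_score, viterbi_path

    updates_per_epoch: list[int] = []
    for _ in range(epochs):
        n_updates = 0
        for feats_idx, labels in prepared:
            emit = _emissions(W, feats_idx)
            y_hat = viterbi_path(emit, T)
            if y_hat == labels:
                continue
            phi_gold = global_feature_vector(feats_idx, labels)
            phi_pred = global_feature_vector(feats_idx, y_hat)
            diff = _phi_diff(phi_gold, phi_pred)
            if not diff:
                warnings.warn(
                    "identical feature vectors for distinct labelings; "
                    "skipping MIRA update"
                )
                continue
            margin = sequence_score(emit, T, labels) - sequence_score(
                emit, T, y_hat
            )
            tau = mira_update(W, T, diff, float(hamming_loss(labels, y_hat)), margin)
            if tau > 0:
                n_updates += 1
        updates_per_epoch.append(n_updates)

    return CrfModel(
        direction="combined",
        feature_index=index,
        state_weights=W,
        trans_weights=T,
        meta={
            "mira_epochs": epochs,
            "updates_per_epoch": updates_per_epoch,
            "parents": ["forward", "backward"],
        },
    )


def _spans_to_labels(spans: Iterable[tuple[int, int]], n: int) -> list[str]:
    labels = ["O"] * n
    placed: list[tuple[int, int]] = []
    # longer spans first so overlaps resolve deterministically toward the
    # longer mention; remaining overlapping spans are skipped
    for i, j in sorted(spans, key=lambda s: (s[0], s[0] - s[1])):
        if any(not (j < p or i > q) for p, q in placed):
            continue
        labels[i] = "B"
        for k in range(i + 1, j + 1):
            labels[k] = "I"
        placed.append((i, j))
    return labels


class BidirectionalTagger(BaseEstimator):
    """Forward + backward CRFs with a configurable integration mode.

    ``mode`` is one of ``forward``, ``backward``, ``union``,
    ``intersection`` or ``mira``.  All modes other than ``forward`` /
    ``backward`` train both directional models; ``mira`` additionally
    builds the combined weight vector.  Prediction operates on per-token
    feature sets and returns label sequences; union/intersection act on the
    mention spans decoded from each direction.
    """

    def __init__(
        self,
        mode: str = "mira",
        c2: float = 1.0,
        max_iter: int = 100,
        mira_epochs: int = 5,
    ) -> None:
        self.mode = mode
        self.c2 = c2
        self.max_iter = max_iter
        self.mira_epochs = mira_epochs

    def fit(
        self, X: Sequence[FeatureSets], y: Sequence[Sequence[str]]
    ) -> "BidirectionalTagger":
        if self.mode not in ("forward", "backward", "union", "intersection", "mira"):
            raise ValueError(f"unknown mode {self.mode!r}")
        need_fwd = self.mode != "backward"
        need_bwd = self.mode != "forward"
        if need_fwd:
            self.forward_ = CrfTagger(
                direction="forward", c2=self.c2, max_iter=self.max_iter
            ).fit(X, y)
        if need_bwd:
            self.backward_ = CrfTagger(
                direction="backward", c2=self.c2, max_iter=self.max_iter
            ).fit(X, y)
        if self.mode == "mira":
            self.combined_ = mira_combine(
                self.forward_.model_,
                self.backward_.model_,
                X,
                y,
                epochs=self.mira_epochs,
            )
        return self

    def predict(
        self, X: Sequence[FeatureSets], mode: str | None = None
    ) -> list[list[str]]:
        mode = mode or self.mode
        if mode == "forward":
            return self.forward_.predict(X)
        if mode == "backward":
            return self.backward_.predict(X)
        if mode == "mira":
            return [self.combined_.viterbi(feats) for feats in X]
        fwd = self.forward_.predict(X)
        bwd = self.backward_.predict(X)
        out: list[list[str]] = []
        for feats, lf, lb in zip(X, fwd, bwd):
            sf, sb = set(_mention_spans(lf)), set(_mention_spans(lb))
            spans = sf | sb if mode == "union" else sf & sb
            out.append(_spans_to_labels(spans, len(feats)))
        return out
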
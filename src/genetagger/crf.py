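"""Second-order linear-chain CRF over sparse string features.

The model assigns each sentence-label pair the unnormalized score

    score(y | x) = sum_i sum_{f in x_i} W[f, y_i]  +  sum_{i>=1} T[y_{i-2}, y_{i-1}, y_i]

with labels in {B, I, O}, a distinguished START value filling y_{-1} at the
second position, and the conditional probability P(y|x) =
exp(score - logZ(x)).  Transition features are label trigrams; position 0
carries state features only, so a single-token sentence is scored purely by
its state features.  Training maximizes the L2-regularized conditional
log-likelihood with batch L-BFGS; gradients come from the forward-backward
recursions over (previous label, current label) pair states.

Both reading directions are supported: a backward model is trained on
reversed sequences whose features carry mirrored positional prefixes and
whose B/I/O labels are re-encoded so mentions are again B I* runs in the
reversed reading order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .features import mirror_feature_id

LABELS = ("B", "I", "O")
LABEL_INDEX = {lab: i for i, lab in enumerate(LABELS)}
N_LABELS = 3
START = 3  # index of the synthetic start label in transition contexts
NEG_INF = -1e30  # large finite value; keeps arithmetic NaN-free

FeatureSets = Sequence[frozenset[str] | set[str]]


def _mention_spans(labels: Sequence[str]) -> list[tuple[int, int]]:
    spans: list[tuple[int, int]] = []
    start = None
    for i, lab in enumerate(labels):
        if lab == "B" or (lab == "I" and start is None):
            if start is not None:
                spans.append((start, i - 1))
            start = i
        elif lab == "O" and start is not None:
            spans.append((start, i - 1))
            start = None
    if start is not None:
        spans.append((start, len(labels) - 1))
    return spans


def reverse_labels(labels: Sequence[str]) -> list[str]:
    """Re-encode B/I/O for reversed token order.

    Mentions are located as spans, the token order is reversed, and each
    mention's first token in the new reading order takes B so the sequence
    is valid BIO again.  The operation is an involution.
    """
    n = len(labels)
    out = ["O"] * n
    for i, j in _mention_spans(labels):
        ri, rj = n - 1 - j, n - 1 - i
        out[ri] = "B"
        for k in range(ri + 1, rj + 1):
            out[k] = "I"
    return out


def encode_direction(
    featuresets: FeatureSets,
    labels: Sequence[str] | None,
    direction: str,
) -> tuple[list[frozenset[str]], list[str] | None]:
    """Orient a (features, labels) sequence for the given parsing direction.

    Forward is the identity.  Backward reverses the token order, mirrors the
    positional prefixes of conjunction features (@-k <-> @+k), and re-encodes
    the labels with :func:`reverse_labels`.
    """
    if direction == "forward":
        return [frozenset(f) for f in featuresets], list(labels) if labels else None
    if direction != "backward":
        raise ValueError(f"unknown direction {direction!r}")
    feats = [
        frozenset(mirror_feature_id(f) for f in fs) for fs in reversed(featuresets)
    ]
    labs = reverse_labels(labels) if labels is not None else None
    return feats, labs


@dataclass
class CrfModel:
    """Weights of a trained second-order CRF.

    ``state_weights`` has shape (n_features, 3); ``trans_weights`` has shape
    (4, 3, 3) indexed by (label two back or START, previous label, current
    label).  ``direction`` records the reading order the model was trained
    in so its weights can later be re-oriented.
    """

    direction: str
    feature_index: dict[str, int]
    state_weights: np.ndarray
    trans_weights: np.ndarray
    labels: tuple[str, ...] = LABELS
    order: int = 2
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.state_weights)):
            raise ValueError("non-finite state weights")
        if not np.all(np.isfinite(self.trans_weights)):
            raise ValueError("non-finite transition weights")

    def to_json(self) -> str:
        features = {
            name: [float(w) for w in self.state_weights[idx]]
            for name, idx in sorted(self.feature_index.items(), key=lambda kv: kv[1])
        }
        ctx = ("B", "I", "O", "START")
        transitions = {
            f"{ctx[a]}|{LABELS[b]}|{LABELS[c]}": float(self.trans_weights[a, b, c])
            for a in range(4)
            for b in range(3)
            for c in range(3)
            if self.trans_weights[a, b, c] != 0.0
        }
        return json.dumps(
            {
                "direction": self.direction,
                "order": self.order,
                "labels": list(self.labels),
                "features": features,
                "transitions": transitions,
                "meta": self.meta,
            },
            indent=None,
            separators=(",", ":"),
        )

    @classmethod
    def from_json(cls, payload: str) -> "CrfModel":
        obj = json.loads(payload)
        names = list(obj["features"])
        feature_index = {name: i for i, name in enumerate(names)}
        W = np.array([obj["features"][n] for n in names], dtype=float).reshape(
            len(names), N_LABELS
        )
        T = np.zeros((4, 3, 3))
        rev = {"B": 0, "I": 1, "O": 2, "START": 3}
        for key, w in obj["transitions"].items():
            a, b, c = key.split("|")
            T[rev[a], rev[b], rev[c]] = w
        return cls(
            direction=obj["direction"],
            feature_index=feature_index,
            state_weights=W,
            trans_weights=T,
            labels=tuple(obj["labels"]),
            order=obj.get("order", 2),
            meta=obj.get("meta", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "CrfModel":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))

    # -- convenience wrappers -------------------------------------------------

    def emissions(self, featuresets: FeatureSets) -> np.ndarray:
        idx = [
            np.array(
                [self.feature_index[f] for f in fs if f in self.feature_index],
                dtype=int,
            )
            for fs in featuresets
        ]
        return _emissions(self.state_weights, idx)

    def viterbi(self, featuresets: FeatureSets) -> list[str]:
        return viterbi_path(self.emissions(featuresets), self.trans_weights)

    def log_partition(self, featuresets: FeatureSets) -> float:
        return log_partition(self.emissions(featuresets), self.trans_weights)

    def sequence_score(self, featuresets: FeatureSets, labels: Sequence[str]) -> float:
        return sequence_score(
            self.emissions(featuresets), self.trans_weights, labels
        )

    def sequence_probability(
        self, featuresets: FeatureSets, labels: Sequence[str]
    ) -> float:
        emit = self.emissions(featuresets)
        return float(
            np.exp(
                sequence_score(emit, self.trans_weights, labels)
                - log_partition(emit, self.trans_weights)
            )
        )


# -- lattice computations -----------------------------------------------------


def _emissions(W: np.ndarray, feats_idx: list[np.ndarray]) -> np.ndarray:
    emit = np.zeros((len(feats_idx), N_LABELS))
    for i, idx in enumerate(feats_idx):
        if len(idx):
            emit[i] = W[idx].sum(axis=0)
    return emit


def sequence_score(
    emit: np.ndarray, trans: np.ndarray, labels: Sequence[str]
) -> float:
    y = [LABEL_INDEX[l] for l in labels]
    s = sum(emit[i, yi] for i, yi in enumerate(y))
    for i in range(1, len(y)):
        a = START if i == 1 else y[i - 2]
        s += trans[a, y[i - 1], y[i]]
    return float(s)


def _forward_lattice(emit: np.ndarray, trans: np.ndarray) -> list[np.ndarray]:
    """Alphas over pair states (y_{i-1}, y_i); index 3 of the first axis is
    the START pseudo-label used only at position 0."""
    n = emit.shape[0]
    alpha = np.full((4, 3), NEG_INF)
    alpha[START, :] = emit[0]
    alphas = [alpha]
    for i in range(1, n):
        m = alpha[:, :, None] + trans  # (a, b, c)
        new = np.full((4, 3), NEG_INF)
        new[:3, :] = logsumexp(m, axis=0) + emit[i][None, :]
        alphas.append(new)
        alpha = new
    return alphas


def _backward_lattice(emit: np.ndarray, trans: np.ndarray) -> list[np.ndarray]:
    n = emit.shape[0]
    beta = np.zeros((4, 3))
    betas = [beta]
    for i in range(n - 2, -1, -1):
        # beta_i[b, c] = lse_d trans[b, c, d] + emit[i+1, d] + beta_{i+1}[c, d]
        # where beta_{i+1} is indexed by the pair (y_i, y_{i+1}) = (c, d)
        m = trans + emit[i + 1][None, None, :] + betas[0][:3][None, :, :]
        beta = logsumexp(m, axis=2)
        betas.insert(0, beta)
    return betas


def log_partition(emit: np.ndarray, trans: np.ndarray) -> float:
    if emit.shape[0] == 0:
        return 0.0
    if emit.shape[0] == 1:
        return float(logsumexp(emit[0]))
    return float(logsumexp(_forward_lattice(emit, trans)[-1]))


def viterbi_path(emit: np.ndarray, trans: np.ndarray) -> list[str]:
    """Highest-scoring label sequence; ties broken by label order B < I < O."""
    n = emit.shape[0]
    if n == 0:
        return []
    if n == 1:
        return [LABELS[int(np.argmax(emit[0]))]]
    delta = np.full((4, 3), NEG_INF)
    delta[START, :] = emit[0]
    backptr: list[np.ndarray] = []
    for i in range(1, n):
        m = delta[:, :, None] + trans  # (a, b, c)
        best_a = np.argmax(m, axis=0)  # (b=4? no: (4,3,3)->(3,3)) over a
        new = np.full((4, 3), NEG_INF)
        new[:3, :] = np.max(m, axis=0) + emit[i][None, :]
        backptr.append(best_a)
        delta = new
    flat = int(np.argmax(delta[:3, :]))
    b, c = divmod(flat, 3)
    path = [c, b]
    for bp in reversed(backptr[1:]):
        a = int(bp[path[-1], path[-2]])
        path.append(a)
    y = list(reversed(path))
    return [LABELS[i] for i in y]


def _posteriors(
    emit: np.ndarray, trans: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """State marginals (n, 3) and summed trigram marginals (4, 3, 3)."""
    n = emit.shape[0]
    if n == 1:
        logZ = float(logsumexp(emit[0]))
        gamma = np.exp(emit[0] - logZ)[None, :]
        return gamma, np.zeros((4, 3, 3)), logZ
    alphas = _forward_lattice(emit, trans)
    betas = _backward_lattice(emit, trans)
    logZ = float(logsumexp(alphas[-1]))
    gamma = np.zeros((n, N_LABELS))
    for i in range(n):
        pair = alphas[i] + betas[i]  # (p, c)
        gamma[i] = np.exp(logsumexp(pair, axis=0) - logZ)
    xi_sum = np.zeros((4, 3, 3))
    for i in range(1, n):
        # xi[a, b, c] at position i
        lo = (
            alphas[i - 1][:, :, None]
            + trans
            + emit[i][None, None, :]
            + betas[i][:3][None, :, :]
        )
        xi_sum += np.exp(lo - logZ)
    return gamma, xi_sum, logZ


# -- training -----------------------------------------------------------------


def _index_features(X: Iterable[FeatureSets]) -> dict[str, int]:
    names = sorted({f for sent in X for fs in sent for f in fs})
    return {name: i for i, name in enumerate(names)}


def _prepare(
    X: Sequence[FeatureSets],
    y: Sequence[Sequence[str]],
    feature_index: dict[str, int],
) -> list[tuple[list[np.ndarray], list[int]]]:
    data = []
    for feats, labels in zip(X, y):
        if len(feats) != len(labels):
            raise ValueError("features/labels length mismatch")
        idx = [
            np.array(sorted(feature_index[f] for f in fs if f in feature_index), dtype=int)
            for fs in feats
        ]
        data.append((idx, [LABEL_INDEX[l] for l in labels]))
    return data


def _empirical_counts(
    data: list[tuple[list[np.ndarray], list[int]]], n_features: int
) -> tuple[np.ndarray, np.ndarray]:
    empW = np.zeros((n_features, N_LABELS))
    empT = np.zeros((4, 3, 3))
    for feats_idx, yseq in data:
        for i, yi in enumerate(yseq):
            empW[feats_idx[i], yi] += 1.0
        for i in range(1, len(yseq)):
            a = START if i == 1 else yseq[i - 2]
            empT[a, yseq[i - 1], yseq[i]] += 1.0
    return empW, empT


def _nll_and_grad(
    theta: np.ndarray,
    data: list[tuple[list[np.ndarray], list[int]]],
    n_features: int,
    empW: np.ndarray,
    empT: np.ndarray,
    c2: float,
) -> tuple[float, np.ndarray]:
    W = theta[: n_features * N_LABELS].reshape(n_features, N_LABELS)
    T = theta[n_features * N_LABELS :].reshape(4, 3, 3)
    nll = 0.0
    gradW = -empW.copy()
    gradT = -empT.copy()
    for feats_idx, yseq in data:
        emit = _emissions(W, feats_idx)
        gamma, xi_sum, logZ = _posteriors(emit, T)
        labels = [LABELS[i] for i in yseq]
        nll += logZ - sequence_score(emit, T, labels)
        for i, idx in enumerate(feats_idx):
            gradW[idx] += gamma[i]
        gradT += xi_sum
    nll += c2 * float(theta @ theta)
    grad = np.concatenate([gradW.ravel(), gradT.ravel()]) + 2.0 * c2 * theta
    return nll, grad


def train_crf(
    X: Sequence[FeatureSets],
    y: Sequence[Sequence[str]],
    direction: str = "forward",
    c2: float = 1.0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[CrfModel, list[float]]:
    """Fit a CRF by L-BFGS on the regularized negative log-likelihood.

    Returns the model and the objective value after each accepted iterate
    (monotonically non-increasing).  Deterministic given identical input
    order and hyperparameters.
    """
    if len(X) == 0:
        raise ValueError("empty training set")
    feature_index = _index_features(X)
    n_features = len(feature_index)
    data = _prepare(X, y, feature_index)
    empW, empT = _empirical_counts(data, n_features)
    x0 = np.zeros(n_features * N_LABELS + 36)
    path: list[float] = []

    def callback(xk: np.ndarray) -> None:
        path.append(
            _nll_and_grad(xk, data, n_features, empW, empT, c2)[0]
        )

    res = minimize(
        _nll_and_grad,
        x0,
        args=(data, n_features, empW, empT, c2),
        method="L-BFGS-B",
        jac=True,
        callback=callback,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-6},
    )
    W = res.x[: n_features * N_LABELS].reshape(n_features, N_LABELS)
    T = res.x[n_features * N_LABELS :].reshape(4, 3, 3)
    model = CrfModel(
        direction=direction,
        feature_index=feature_index,
        state_weights=W,
        trans_weights=T,
        meta={"objective": float(res.fun), "n_iter": int(res.nit)},
    )
    return model, path


class CrfTagger(BaseEstimator):
    """Sklearn-style estimator around the second-order CRF.

    Parameters
    ----------
    direction : "forward" or "backward"
        Reading order.  For ``backward`` the training pairs are re-oriented
        with :func:`encode_direction` before fitting, and predictions are
        mapped back to the original order.
    c2 : float
        L2 regularization strength (the objective adds ``c2 * ||theta||^2``).
    max_iter : int
        L-BFGS iteration cap.
    """

    def __init__(
        self,
        direction: str = "forward",
        c2: float = 1.0,
        max_iter: int = 100,
        tol: float = 1e-6,
    ) -> None:
        self.direction = direction
        self.c2 = c2
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X: Sequence[FeatureSets], y: Sequence[Sequence[str]]) -> "CrfTagger":
        enc = [encode_direction(feats, labels, self.direction) for feats, labels in zip(X, y)]
        Xe = [e[0] for e in enc]
        ye = [e[1] for e in enc]
        self.model_, self.objective_path_ = train_crf(
            Xe, ye, direction=self.direction, c2=self.c2,
            max_iter=self.max_iter, tol=self.tol,
        )
        return self

    def predict(self, X: Sequence[FeatureSets]) -> list[list[str]]:
        out = []
        for feats in X:
            fe, _ = encode_direction(feats, None, self.direction)
            labels = self.model_.viterbi(fe)
            if self.direction == "backward":
                labels = reverse_labels(labels)
            out.append(labels)
        return out

    def score(self, X: Sequence[FeatureSets], y: Sequence[Sequence[str]]) -> float:
        """Token-level accuracy."""
        pred = self.predict(X)
        total = sum(len(l) for l in y)
        hits = sum(
            sum(1 for a, b in zip(p, g) if a == b) for p, g in zip(pred, y)
        )
        return hits / total if total else 0.0
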
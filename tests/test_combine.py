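"""Union/intersection, weight re-orientation and MIRA combination."""

import numpy as np
import pytest

from genetagger.corpus import GeneMention
from genetagger.combine import (
    BidirectionalTagger,
    global_feature_vector,
    hamming_loss,
    intersect_mentions,
    map_backward_weights,
    mira_combine,
    mira_update,
    mirror_weights,
    union_mentions,
)
from genetagger.crf import CrfModel, train_crf
from genetagger.evaluate import evaluate_mentions


def _m(sid, start, end):
    return GeneMention(sid, start, end, "x" * (end - start + 1))


def _random_mentions(rng, n, sid_pool=("S1", "S2", "S3")):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, 40))
        out.append(_m(sid_pool[int(rng.integers(len(sid_pool)))], start, start + int(rng.integers(0, 5))))
    return out


class TestSetOperations:
    def test_disjoint_union(self):
        a = [_m("S1", 0, 2), _m("S1", 5, 7)]
        b = [_m("S2", 0, 2), _m("S2", 4, 4), _m("S3", 1, 1)]
        assert len(union_mentions(a, b)) == 5

    def test_union_idempotent(self):
        a = [_m("S1", 0, 2), _m("S1", 5, 7)]
        assert union_mentions(a, a) == sorted(a)

    def test_disjoint_intersection_empty(self):
        assert intersect_mentions([_m("S1", 0, 2)], [_m("S1", 3, 4)]) == []

    def test_intersection_of_equal_sets(self):
        a = [_m("S1", 0, 2), _m("S2", 1, 3)]
        assert intersect_mentions(a, a) == sorted(a)

    def test_union_recall_dominates(self, rng):
        for _ in range(30):
            gold = _random_mentions(rng, 8)
            a = _random_mentions(rng, 6) + gold[:2]
            b = _random_mentions(rng, 6) + gold[2:4]
            ru = evaluate_mentions(gold, union_mentions(a, b)).recall
            ra = evaluate_mentions(gold, a).recall
            rb = evaluate_mentions(gold, b).recall
            assert ru >= max(ra, rb) - 1e-12

    def test_intersection_subset_of_both(self, rng):
        for _ in range(30):
            a = _random_mentions(rng, 8)
            b = _random_mentions(rng, 8) + a[:3]
            inter = intersect_mentions(a, b)
            keys_a = {m.key for m in a}
            keys_b = {m.key for m in b}
            assert all(m.key in keys_a and m.key in keys_b for m in inter)


class TestWeightMapping:
    def _backward_model(self):
        W = np.array([[0.7, -0.1, 0.2], [0.0, 1.0, -1.0]])
        T = np.zeros((4, 3, 3))
        T[2, 0, 1] = 0.5  # (O, B, I)
        T[3, 0, 1] = 9.0  # START-context trigram: dropped by the mapping
        return CrfModel(
            direction="backward",
            feature_index={"INITCAPS": 0, "@-1:ALLCAPS": 1},
            state_weights=W,
            trans_weights=T,
        )

    def test_state_features_direction_invariant(self):
        mapped = map_backward_weights(self._backward_model())
        i = mapped.feature_index["INITCAPS"]
        assert np.allclose(mapped.state_weights[i], [0.7, -0.1, 0.2])

    def test_positional_prefix_mirrored(self):
        mapped = map_backward_weights(self._backward_model())
        assert "@+1:ALLCAPS" in mapped.feature_index
        assert "@-1:ALLCAPS" not in mapped.feature_index

    def test_transition_trigram_reversed(self):
        mapped = map_backward_weights(self._backward_model())
        assert mapped.trans_weights[1, 0, 2] == 0.5  # (I, B, O)
        assert mapped.trans_weights[3].sum() == 0.0  # START contexts dropped

    def test_mapping_twice_is_identity(self):
        index = {"@-2:X": 0, "PLAIN": 1}
        W = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        T = np.zeros((4, 3, 3))
        T[0, 1, 2] = -0.3
        i2, W2, T2 = mirror_weights(*mirror_weights(index, W, T))
        assert i2 == index
        assert np.array_equal(W2, W)
        assert np.array_equal(T2, T)

    def test_forward_model_rejected(self):
        fwd = CrfModel(
            direction="forward",
            feature_index={},
            state_weights=np.zeros((0, 3)),
            trans_weights=np.zeros((4, 3, 3)),
        )
        with pytest.raises(ValueError, match="backward"):
            map_backward_weights(fwd)


GENE = frozenset({"GENEISH"})
WORD = frozenset({"WORDISH"})
TOY_X = [[WORD, GENE, WORD], [GENE, GENE, WORD], [WORD, WORD, GENE], [GENE]] * 3
TOY_Y = [["O", "B", "O"], ["B", "I", "O"], ["O", "O", "B"], ["B"]] * 3


def _trained_parents():
    fwd, _ = train_crf(TOY_X, TOY_Y, direction="forward", max_iter=60)
    from genetagger.crf import encode_direction

    enc = [encode_direction(x, y, "backward") for x, y in zip(TOY_X, TOY_Y)]
    bwd, _ = train_crf(
        [e[0] for e in enc], [e[1] for e in enc], direction="backward", max_iter=60
    )
    return fwd, bwd


class TestMira:
    def test_no_update_when_already_correct(self):
        fwd, bwd = _trained_parents()
        combined = mira_combine(fwd, bwd, TOY_X, TOY_Y, epochs=3)
        assert combined.meta["updates_per_epoch"] == [0, 0, 0]

    def test_closed_form_tau_on_single_token(self):
        # one token, one feature; initial weights favor the wrong label O
        W = np.array([[0.0, 0.0, 0.5]])
        T = np.zeros((4, 3, 3))
        model = CrfModel(
            direction="combined",
            feature_index={"f1": 0},
            state_weights=W.copy(),
            trans_weights=T,
        )
        X = [[frozenset({"f1"})]]
        y = [["B"]]
        # decode picks O; dPhi = +1 on (f1,B), -1 on (f1,O); ||dPhi||^2 = 2
        # margin = 0 - 0.5; tau = (1 - (-0.5)) / 2 = 0.75
        fwd = model
        bwd = CrfModel(
            direction="backward",
            feature_index={},
            state_weights=np.zeros((0, 3)),
            trans_weights=np.zeros((4, 3, 3)),
        )
        combined = mira_combine(fwd, bwd, X, y, epochs=1)
        i = combined.feature_index["f1"]
        assert np.isclose(combined.state_weights[i, 0], 0.75)
        assert np.isclose(combined.state_weights[i, 2], 0.5 - 0.75)

    def test_margin_holds_after_update(self, rng):
        from genetagger.crf import _emissions, sequence_score, viterbi_path
        from genetagger.combine import _phi_diff, mira_update

        for _ in range(20):
            n_feat, n = 4, int(rng.integers(1, 5))
            W = rng.normal(size=(n_feat, 3))
            T = rng.normal(size=(4, 3, 3)) * 0.5
            feats_idx = [
                np.array(sorted(rng.choice(n_feat, size=2, replace=False)))
                for _ in range(n)
            ]
            gold = [["B", "I", "O"][int(rng.integers(3))] for _ in range(n)]
            emit = _emissions(W, feats_idx)
            y_hat = viterbi_path(emit, T)
            if y_hat == gold:
                continue
            diff = _phi_diff(
                global_feature_vector(feats_idx, gold),
                global_feature_vector(feats_idx, y_hat),
            )
            if not diff:
                continue
            loss = float(hamming_loss(gold, y_hat))
            margin = sequence_score(emit, T, gold) - sequence_score(emit, T, y_hat)
            tau = mira_update(W, T, diff, loss, margin)
            emit2 = _emissions(W, feats_idx)
            new_margin = sequence_score(emit2, T, gold) - sequence_score(
                emit2, T, y_hat
            )
            assert new_margin >= loss - 1e-9
            if tau > 0:
                assert np.isclose(new_margin, loss)

    def test_minimal_norm_update(self):
        # ||w_new - w_old|| equals tau * ||dPhi||
        W = np.array([[0.0, 0.0, 0.5]])
        T = np.zeros((4, 3, 3))
        W0 = W.copy()
        diff = {("s", 0, 0): 1, ("s", 0, 2): -1}
        tau = mira_update(W, T, diff, 1.0, -0.5)
        assert np.isclose(
            np.linalg.norm(W - W0), tau * np.sqrt(2.0)
        )


@pytest.fixture(scope="module")
def fitted():
    return BidirectionalTagger(mode="mira", max_iter=60).fit(TOY_X, TOY_Y)


class TestBidirectionalTagger:
    @pytest.mark.parametrize(
        "mode", ["forward", "backward", "union", "intersection", "mira"]
    )
    def test_all_modes_reproduce_separable_data(self, fitted, mode):
        assert fitted.predict(TOY_X, mode=mode) == TOY_Y

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            BidirectionalTagger(mode="sideways").fit(TOY_X, TOY_Y)
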
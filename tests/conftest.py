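import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from genetagger.crf import LABELS, sequence_score

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def brute_force_best(emit: np.ndarray, trans: np.ndarray):
    """Exhaustive argmax over all 3^n label sequences (first-best on ties
    in the fixed label order B < I < O)."""
    best, best_score = None, -np.inf
    for seq in itertools.product(LABELS, repeat=emit.shape[0]):
        s = sequence_score(emit, trans, seq)
        if s > best_score + 1e-12:
            best, best_score = list(seq), s
    return best, best_score


def brute_force_log_partition(emit: np.ndarray, trans: np.ndarray) -> float:
    scores = [
        sequence_score(emit, trans, seq)
        for seq in itertools.product(LABELS, repeat=emit.shape[0])
    ]
    return float(np.logaddexp.reduce(scores))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
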
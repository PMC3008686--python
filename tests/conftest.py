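import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make the oracle module importable

import hmmenrich as h


@pytest.fixture
def uniform_bg() -> h.DinucleotideBackground:
    return h.uniform_background()


@pytest.fixture
def acg_matrix() -> h.ProbabilityMatrix:
    """Near-deterministic 3-position motif for ACG (tiny off-consensus mass)."""
    eps = 1e-9
    probs = np.full((3, 4), eps)
    for i, b in enumerate([0, 1, 2]):  # A, C, G
        probs[i, b] = 1.0 - 3 * eps
    return h.ProbabilityMatrix("ACGm", probs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_pwm(rng: np.random.Generator, L: int, motif_id: str = "w") -> h.ProbabilityMatrix:
    probs = rng.dirichlet(np.ones(4) * 0.8, size=L)
    probs = np.clip(probs, 1e-9, None)
    probs /= probs.sum(axis=1, keepdims=True)
    return h.ProbabilityMatrix(motif_id, probs)


def random_background(rng: np.random.Generator) -> h.DinucleotideBackground:
    init = rng.dirichlet(np.ones(4))
    trans = rng.dirichlet(np.ones(4), size=4)
    return h.DinucleotideBackground(init, trans)
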
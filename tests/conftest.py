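import numpy as np
import pytest

from regmap import hmm


@pytest.fixture
def toy_model() -> hmm.StateModel:
    """2-state, 1-mark model small enough for exhaustive path enumeration."""
    return hmm.StateModel(
        startprob=np.array([0.5, 0.5]),
        transmat=np.array([[0.9, 0.1], [0.1, 0.9]]),
        emissionprob=np.array([[0.9], [0.1]]),
        mark_order=["H3K27ac"],
    )


@pytest.fixture
def toy_obs() -> hmm.ObservationMatrix:
    return hmm.ObservationMatrix("t", "chr1", np.array([[1], [1], [0]]), ["H3K27ac"])


def random_small_instance(rng: np.random.Generator):
    """Random tiny HMM instance (<= 8 bins, <= 3 states, <= 3 marks)."""
    K = int(rng.integers(1, 4))
    M = int(rng.integers(1, 4))
    T = int(rng.integers(1, 9))
    pi = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K), size=K)
    E = rng.uniform(0.05, 0.95, size=(K, M))
    model = hmm.StateModel(pi, A, E, [f"m{i}" for i in range(M)])
    X = rng.integers(0, 2, size=(T, M))
    obs = hmm.ObservationMatrix("t", "chr", X, model.mark_order)
    return model, obs
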
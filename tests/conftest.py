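import numpy as np
import pytest

from cogmap import (
    compute_sr_matrix,
    compute_transition_matrix,
    load_space,
)


@pytest.fixture(scope="session")
def animals_train():
    return load_space("animals_train")


@pytest.fixture(scope="session")
def animals_test():
    return load_space("animals_test")


@pytest.fixture(scope="session")
def animals_T(animals_train):
    return compute_transition_matrix(animals_train)


@pytest.fixture(scope="session")
def make_animals_sr(animals_T):
    cache = {}

    def _make(gamma, horizon_t=10):
        key = (gamma, horizon_t)
        if key not in cache:
            cache[key] = compute_sr_matrix(animals_T, gamma, horizon_t)
        return cache[key]

    return _make


def random_transition_matrix(n, rng):
    """Random row-stochastic matrix with zero diagonal (test helper)."""
    from cogmap.successor import TransitionMatrix

    w = rng.random((n, n)) + 0.1
    np.fill_diagonal(w, 0.0)
    return TransitionMatrix(w / w.sum(axis=1, keepdims=True), [f"s{i}" for i in range(n)])
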
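import numpy as np
import pytest

from thermirl import (GridSpec, TransitionData, build_grid,
                      gaussian_passive_kernel)


@pytest.fixture
def tiny_grid():
    """5 x 5 mesh around the cultivation temperature."""
    return build_grid(GridSpec(18.0, 22.0, 5, -0.01, 0.01, 5, delta_t=1.0))


@pytest.fixture
def tiny_kernel(tiny_grid):
    return gaussian_passive_kernel(tiny_grid, sigma_T=0.5, sigma_dT=0.004)


@pytest.fixture
def default_grid():
    """Default assay mesh: 24 T-bins over 14-26 C x 15 dT-bins."""
    return build_grid(GridSpec(14.0, 26.0, 24, -0.02, 0.02, 15, delta_t=1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_stochastic_matrix(rng, n, sparsity=0.0):
    """Random row-stochastic matrix; optionally with structural zeros."""
    m = rng.random((n, n)) + 0.05
    if sparsity:
        mask = rng.random((n, n)) < sparsity
        mask[np.arange(n), np.arange(n)] = False  # keep rows nonempty
        m[mask] = 0.0
    return m / m.sum(axis=1, keepdims=True)


def random_transitions(rng, n_states, n_pairs, worm_id="w0"):
    pairs = rng.integers(0, n_states, size=(n_pairs, 2))
    return TransitionData(pairs, np.full(n_pairs, worm_id), n_states)
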
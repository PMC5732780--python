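import numpy as np
import pytest

from lpinrlmf import (
    Hyperparameters,
    InteractionMatrix,
    SimilarityMatrix,
    generate_planted_instance,
)


def random_similarity(q: int, rng) -> SimilarityMatrix:
    """A valid random similarity matrix: symmetric, [0,1], unit diagonal."""
    M = rng.random((q, q))
    S = (M + M.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(ids=[f"e{i}" for i in range(q)], values=S)


def random_interactions(m: int, n: int, density: float, rng) -> InteractionMatrix:
    Y = (rng.random((m, n)) < density).astype(float)
    if Y.sum() == 0:
        Y[0, 0] = 1.0
    return InteractionMatrix(
        lncrna_ids=[f"e{i}" for i in range(m)],
        protein_ids=[f"e{j}" for j in range(n)],
        Y=Y,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_instance():
    """Desk-scale planted instance shared by model-level tests."""
    return generate_planted_instance(
        m=30, n=8, r=3, density_target=0.2, sim_noise=0.05, seed=7
    )


@pytest.fixture
def small_hp():
    return Hyperparameters(r=3, c=5.0, K1=3, K2=3, max_iters=30, seed=0)
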
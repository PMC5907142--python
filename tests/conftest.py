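import numpy as np
import pytest

from chromnpls import ChromatinTensor, ExpressionVector, SimulationParams, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240911)


@pytest.fixture
def rank_one_data(rng):
    """Noise-free rank-one tensor: X_i = y_i * (a outer c), unit a and c."""
    n, J, K = 40, 4, 7
    a = rng.normal(size=J)
    a /= np.linalg.norm(a)
    c = rng.normal(size=K)
    c /= np.linalg.norm(c)
    y = rng.normal(size=n)
    values = y[:, None, None] * np.outer(a, c)[None]
    offsets = (np.arange(K) - K // 2).astype(float)
    X = ChromatinTensor(
        values=values,
        gene_ids=[f"g{i}" for i in range(n)],
        mark_names=[f"m{j}" for j in range(J)],
        bin_offsets=offsets,
    )
    yv = ExpressionVector(y=y, gene_ids=X.gene_ids)
    return X, yv, a, c


@pytest.fixture
def small_sim():
    """A small simulated dataset shared across tests (fast to generate)."""
    return simulate(SimulationParams(n_genes=400, n_bins=30, beta=2.0, seed=99))


def random_tensor(rng, n=30, J=4, K=6):
    """An unlabeled random 3-way dataset for algebraic checks."""
    values = rng.normal(size=(n, J, K))
    offsets = (np.arange(K) - (K - 1) / 2).astype(float)
    X = ChromatinTensor(
        values=values,
        gene_ids=[f"g{i}" for i in range(n)],
        mark_names=[f"m{j}" for j in range(J)],
        bin_offsets=offsets,
    )
    y = ExpressionVector(y=rng.normal(size=n), gene_ids=X.gene_ids)
    return X, y
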
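"""Generative simulation of binned chromatin profiles with a shared latent factor.

A per-gene latent variable Z ~ N(0, beta) drives both the expression response

    y = Z + eps_y,          eps_y ~ N(0, eps_y_var)

and, for each mark i with height h_i, the dispersion of that mark's signal
profile through a log-variance link

    log(sigma_i^2) = Z * h_i + eps_sigma_i,   eps_sigma_i ~ N(0, gamma_i).

The gene's profile for mark i is then the vector of N(0, sigma_i^2)
probability masses over an equal-width partition of [-R, R] into n_bins
intervals: genes with large |Z| have flatter, more dispersed profiles for
high-h marks, so the bin pattern carries information about expression. All
normal parameters are variances; the variance link uses the natural log.

Randomness comes from a single seeded generator with a fixed draw order
(Z vector, eps_y vector, then the eps_sigma matrix mark-major), so a dataset
is reproducible bit-for-bit from (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from chromnpls.tensor import ChromatinTensor, ExpressionVector

DEFAULT_HEIGHTS = (3.0, 2.0, 1.0, 0.5, 0.4)


@dataclass(frozen=True)
class SimulationParams:
    """All knobs of the generative design.

    Defaults follow the reference design: 10,000 genes, five marks with
    heights (3, 2, 1, 0.5, 0.4), 100 bins, expression noise variance 0.2,
    per-mark log-variance noise 0.1, density support [-10, 10].
    """

    n_genes: int = 10000
    n_bins: int = 100
    heights: tuple[float, ...] = DEFAULT_HEIGHTS
    beta: float = 2.0
    eps_y_var: float = 0.2
    gamma: tuple[float, ...] | float = 0.1
    density_range: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.beta <= 0 or self.eps_y_var <= 0:
            raise ValueError("beta and eps_y_var must be > 0")
        if self.density_range <= 0:
            raise ValueError("density_range must be > 0")
        if any(g <= 0 for g in self.gamma_per_mark):
            raise ValueError("all gamma must be > 0")

    @property
    def n_marks(self) -> int:
        return len(self.heights)

    @property
    def gamma_per_mark(self) -> tuple[float, ...]:
        if isinstance(self.gamma, (int, float)):
            return (float(self.gamma),) * self.n_marks
        if len(self.gamma) != self.n_marks:
            raise ValueError("gamma length must match number of marks")
        return tuple(float(g) for g in self.gamma)


@dataclass
class SimulatedDataset:
    """A simulated tensor/response pair with its latent state."""

    X: ChromatinTensor
    y: ExpressionVector
    Z: np.ndarray
    sigma2: np.ndarray  # (n_genes, n_marks)
    params: SimulationParams


def normal_interval_areas(
    sigma2: float | np.ndarray, n_bins: int, density_range: float
) -> np.ndarray:
    """N(0, sigma^2) probability masses over an equal partition of [-R, R].

    Entry j is the CDF difference across interval j. Accepts a scalar
    variance (returns shape ``(n_bins,)``) or an array of variances (returns
    ``sigma2.shape + (n_bins,)``). The entries sum to
    ``Phi(R/sigma) - Phi(-R/sigma)``, which is 1 up to truncation error.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 <= 0):
        raise ValueError("variance must be > 0")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if density_range <= 0:
        raise ValueError("density_range must be > 0")
    edges = np.linspace(-density_range, density_range, n_bins + 1)
    sigma = np.sqrt(sigma2)
    cdf = norm.cdf(edges / sigma[..., np.newaxis])
    return np.diff(cdf, axis=-1)


def simulate(params: SimulationParams) -> SimulatedDataset:
    """Draw one dataset from the latent-variable design."""
    rng = np.random.default_rng(params.seed)
    n, m, nb = params.n_genes, params.n_marks, params.n_bins
    Z = rng.normal(0.0, np.sqrt(params.beta), size=n)
    eps_y = rng.normal(0.0, np.sqrt(params.eps_y_var), size=n)
    gamma = np.array(params.gamma_per_mark)
    # mark-major: all genes for mark 1, then mark 2, ...
    eps_sigma = rng.normal(0.0, 1.0, size=(m, n)) * np.sqrt(gamma)[:, np.newaxis]

    y = Z + eps_y
    h = np.array(params.heights)
    log_sigma2 = Z[:, np.newaxis] * h[np.newaxis, :] + eps_sigma.T  # (n, m)
    sigma2 = np.exp(log_sigma2)
    X = normal_interval_areas(sigma2, nb, params.density_range)  # (n, m, nb)

    width = 2 * params.density_range / nb
    centers = -params.density_range + width * (np.arange(nb) + 0.5)
    tensor = ChromatinTensor(
        values=X,
        gene_ids=[f"gene_{i}" for i in range(n)],
        mark_names=[f"mark_{i + 1}" for i in range(m)],
        bin_offsets=centers,
    )
    expression = ExpressionVector(y=y, gene_ids=tensor.gene_ids, scale="raw")
    return SimulatedDataset(X=tensor, y=expression, Z=Z, sigma2=sigma2, params=params)


def simulate_grid(
    beta_values: list[float],
    params: SimulationParams = SimulationParams(),
    n_replicates: int = 10,
) -> list[SimulatedDataset]:
    """One dataset per (beta, replicate), with deterministic derived seeds.

    Seeds are spawned from (master seed, beta index, replicate index) via a
    seed sequence, so the full grid reproduces from ``params.seed`` alone.
    """
    if not beta_values:
        raise ValueError("beta_values must be non-empty")
    datasets = []
    for bi, beta in enumerate(beta_values):
        for rep in range(n_replicates):
            child = np.random.SeedSequence(
                entropy=params.seed, spawn_key=(bi, rep)
            )
            derived = int(child.generate_state(1)[0] % 2**31)
            run = SimulationParams(
                n_genes=params.n_genes,
                n_bins=params.n_bins,
                heights=params.heights,
                beta=float(beta),
                eps_y_var=params.eps_y_var,
                gamma=params.gamma,
                density_range=params.density_range,
                seed=derived,
            )
            datasets.append(simulate(run))
    return datasets
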
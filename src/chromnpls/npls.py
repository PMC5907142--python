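"""Three-way partial least squares regression (N-way PLS, N = 3).

Each component is a rank-one pair of unit-norm loading vectors — one over
marks, one over bins — together with a per-gene score vector

    t_i = p1' X_i p2

chosen so that cov(t, y)^2 is maximal over all unit (p1, p2). Because

    cov(t, y) ∝ p1' ( Σ_i y_i X_i ) p2,

the optimal pair is the leading singular pair of the y-weighted slice sum
Z = Σ_i y_i X_i (genes mean-centered on both sides). After each extraction
the tensor is deflated by the rank-one term t ⊗ p1 ⊗ p2, the regression
coefficients b are refit jointly on all scores so far, and the response
residual y - T b drives the next cross-covariance. Prediction projects new
(centered) gene slices through the same sequence of loading pairs and
deflations, then applies Ŷ = T_new b + ȳ.

For univariate responses the response loading is the fixed scalar 1, and
with a singleton bin mode the algorithm reduces exactly to univariate
two-way PLS1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from chromnpls.tensor import ChromatinTensor, ExpressionVector, align_genes

#: Frobenius norm below which the cross-covariance matrix is considered zero.
DEGENERATE_TOL = 1e-14


@dataclass
class ComponentResult:
    """One extracted component: unit loadings, gene scores, achieved cov^2."""

    p1: np.ndarray
    p2: np.ndarray
    t: np.ndarray
    achieved_cov2: float


@dataclass
class NPLSModel:
    """A fitted 3-way PLS model.

    ``P1`` (n_marks x f) and ``P2`` (n_bins x f) hold the unit-norm loading
    vectors per factor, ``T`` the training scores, ``b`` the regression
    coefficients of centered y on T. ``q`` is the response loading, fixed to
    1.0 for the univariate response. ``x_center`` (n_marks x n_bins) and
    ``y_center`` are the training means removed before extraction.
    """

    f: int
    P1: np.ndarray
    P2: np.ndarray
    T: np.ndarray
    b: np.ndarray
    x_center: np.ndarray
    y_center: float
    mark_names: list[str]
    bin_offsets: np.ndarray
    q: float = 1.0

    def __post_init__(self) -> None:
        self.P1 = np.asarray(self.P1, dtype=float)
        self.P2 = np.asarray(self.P2, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.x_center = np.asarray(self.x_center, dtype=float)
        self.bin_offsets = np.asarray(self.bin_offsets, dtype=float)
        if not (
            self.P1.shape[1] == self.P2.shape[1] == self.T.shape[1]
            == self.b.size == self.f
        ):
            raise ValueError("inconsistent factor counts across model fields")
        if self.x_center.shape != (self.P1.shape[0], self.P2.shape[0]):
            raise ValueError("x_center shape inconsistent with loadings")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "f": self.f,
            "P1": self.P1.tolist(),
            "P2": self.P2.tolist(),
            "T": self.T.tolist(),
            "b": self.b.tolist(),
            "q": self.q,
            "x_center": self.x_center.tolist(),
            "y_center": self.y_center,
            "mark_names": self.mark_names,
            "bin_offsets": self.bin_offsets.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "NPLSModel":
        p = json.loads(Path(path).read_text())
        return cls(
            f=p["f"],
            P1=np.array(p["P1"]),
            P2=np.array(p["P2"]),
            T=np.array(p["T"]),
            b=np.array(p["b"]),
            x_center=np.array(p["x_center"]),
            y_center=p["y_center"],
            mark_names=p["mark_names"],
            bin_offsets=np.array(p["bin_offsets"]),
            q=p.get("q", 1.0),
        )


def cross_cov_matrix(x_residual: np.ndarray, y_residual: np.ndarray) -> np.ndarray:
    """Response-weighted slice sum Z = Σ_i y_i X_i (n_marks x n_bins).

    Both arguments are assumed centered over genes; Z is linear in each.
    Up to a 1/(n-1) factor this is the matrix of covariances between y and
    each (mark, bin) cell, whose leading singular pair solves the
    covariance-maximization problem.
    """
    x_residual = np.asarray(x_residual, dtype=float)
    y_residual = np.asarray(y_residual, dtype=float)
    if x_residual.ndim != 3:
        raise ValueError("x_residual must be a 3-way array")
    if y_residual.shape != (x_residual.shape[0],):
        raise ValueError(
            f"gene counts differ: tensor has {x_residual.shape[0]}, "
            f"response has {y_residual.shape}"
        )
    return np.einsum("i,ijk->jk", y_residual, x_residual)


def extract_component(
    x_residual: np.ndarray, y_residual: np.ndarray
) -> ComponentResult:
    """Extract the covariance-maximizing rank-one component.

    Returns unit loadings (p1 over marks, p2 over bins) equal to the leading
    singular pair of :func:`cross_cov_matrix`, and scores t_i = p1' X_i p2.
    Signs are fixed deterministically: the largest-magnitude entry of p1 is
    positive, and p2 is flipped if needed so that cov(t, y) >= 0.
    """
    z = cross_cov_matrix(x_residual, y_residual)
    if np.linalg.norm(z) < DEGENERATE_TOL:
        raise ValueError(
            "response uncorrelated with tensor: cross-covariance is zero"
        )
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    p1, p2 = u[:, 0].copy(), vt[0].copy()
    # Deterministic sign: dominant entry of p1 positive.
    dom = np.argmax(np.abs(p1))
    if p1[dom] < 0:
        p1, p2 = -p1, -p2
    t = np.einsum("ijk,j,k->i", x_residual, p1, p2)
    cov_ty = float(t @ y_residual)
    if cov_ty < 0:
        p2 = -p2
        t = -t
        cov_ty = -cov_ty
    n = y_residual.size
    cov = cov_ty / (n - 1) if n > 1 else cov_ty
    return ComponentResult(p1=p1, p2=p2, t=t, achieved_cov2=cov**2)


def fit(X: ChromatinTensor, y: ExpressionVector, f: int) -> NPLSModel:
    """Fit a 3-way PLS model with ``f`` factors.

    Centers the tensor per (mark, bin) cell and the response over genes,
    then alternates component extraction, joint least-squares refit of b on
    all scores, and rank-one deflation of the tensor.
    """
    X, y = align_genes(X, y)
    n_genes, n_marks, n_bins = X.shape
    if not 1 <= f <= min(n_marks * n_bins, n_genes - 1):
        raise ValueError(
            f"f={f} outside valid range [1, {min(n_marks * n_bins, n_genes - 1)}]"
        )
    x_center = X.values.mean(axis=0)
    y_center = float(y.y.mean())
    x_res = X.values - x_center
    y_centered = y.y - y_center
    y_res = y_centered.copy()

    P1 = np.empty((n_marks, f))
    P2 = np.empty((n_bins, f))
    T = np.empty((n_genes, f))
    b = np.empty(0)
    for k in range(f):
        try:
            comp = extract_component(x_res, y_res)
        except ValueError as exc:
            raise ValueError(
                f"degenerate residual after {k} components (requested f={f}); "
                f"achievable rank is {k}"
            ) from exc
        P1[:, k], P2[:, k], T[:, k] = comp.p1, comp.p2, comp.t
        b, *_ = np.linalg.lstsq(T[:, : k + 1], y_centered, rcond=None)
        x_res = x_res - np.einsum("i,j,k->ijk", comp.t, comp.p1, comp.p2)
        y_res = y_centered - T[:, : k + 1] @ b
    return NPLSModel(
        f=f,
        P1=P1,
        P2=P2,
        T=T,
        b=b,
        x_center=x_center,
        y_center=y_center,
        mark_names=X.mark_names,
        bin_offsets=X.bin_offsets,
    )


def _scores(model: NPLSModel, values: np.ndarray) -> np.ndarray:
    """Project (uncentered) gene slices through the training deflation sequence."""
    x_res = values - model.x_center
    T = np.empty((values.shape[0], model.f))
    for k in range(model.f):
        p1, p2 = model.P1[:, k], model.P2[:, k]
        t = np.einsum("ijk,j,k->i", x_res, p1, p2)
        T[:, k] = t
        x_res = x_res - np.einsum("i,j,k->ijk", t, p1, p2)
    return T


def predict(model: NPLSModel, X_new: ChromatinTensor) -> ExpressionVector:
    """Predict expression for new genes: Ŷ = T_new b + ȳ."""
    if X_new.mark_names != model.mark_names:
        raise ValueError(
            f"mark axes differ: model {model.mark_names} vs tensor {X_new.mark_names}"
        )
    if not np.array_equal(X_new.bin_offsets, model.bin_offsets):
        raise ValueError("bin-offset axes differ between model and tensor")
    T = _scores(model, X_new.values)
    return ExpressionVector(
        y=T @ model.b + model.y_center,
        gene_ids=X_new.gene_ids,
        scale="log2",
    )


def select_factors(
    X: ChromatinTensor,
    y: ExpressionVector,
    f_max: int,
    k: int = 10,
    n_replicates: int = 1,
    seed: int = 0,
) -> tuple[int, "pd.DataFrame"]:
    """Pick a factor count by cross-validation.

    Evaluates f = 1..f_max on shared fold assignments and returns the
    smallest f whose mean CV R is within one standard error of the best
    mean R, along with the per-f curve (mean/sd of R and RMSE).
    """
    import pandas as pd

    from chromnpls.evaluation import factor_sweep

    if f_max < 1:
        raise ValueError("f_max must be >= 1")
    curve = factor_sweep(
        X, y, list(range(1, f_max + 1)), k=k, n_replicates=n_replicates, seed=seed
    )
    mean_r = curve["mean_R"].to_numpy()
    se = curve["sd_R"].to_numpy() / np.sqrt(k * n_replicates)
    best = int(np.argmax(mean_r))
    threshold = mean_r[best] - se[best]
    f_star = int(curve["f"].iloc[int(np.argmax(mean_r >= threshold))])
    return f_star, curve
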
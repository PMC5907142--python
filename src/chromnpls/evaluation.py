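"""Metrics, replicated k-fold cross-validation, and method benchmarking.

Performance is measured by the Pearson correlation R between observed and
predicted expression and by the root-mean-square error with denominator
equal to the number of evaluated genes. The protocol is k-fold
cross-validation repeated over independently re-randomized replicates; R and
RMSE are computed per held-out fold and averaged over all k * n_replicates
fold evaluations (a pooled-predictions variant is available).

Baselines operate on the gene x (marks*bins) unfolding of the tensor:
ordinary least squares (implemented directly), random forest (500 trees),
and RBF support vector regression with library defaults. All methods in a
benchmark see identical fold assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from chromnpls import npls
from chromnpls.tensor import ChromatinTensor, ExpressionVector, align_genes

#: Number of trees for the random-forest baseline.
RF_N_TREES = 500


def pearson_r(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Pearson correlation: centered cross-product over product of centered norms."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.ndim != 1:
        raise ValueError("inputs must be 1-d vectors of equal length")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    yc = y - y.mean()
    hc = y_hat - y_hat.mean()
    denom = np.sqrt((yc @ yc)) * np.sqrt((hc @ hc))
    if denom == 0:
        raise ValueError("correlation undefined for constant input")
    return float((yc @ hc) / denom)


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root-mean-square error with denominator n (not n-1)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.ndim != 1:
        raise ValueError("inputs must be 1-d vectors of equal length")
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


@dataclass
class CVResult:
    """Aggregated cross-validation outcome for one method."""

    method_name: str
    fold_assignments: list[np.ndarray]  # per replicate: gene -> fold label
    fold_r: list[float]
    fold_rmse: list[float]
    mean_R: float
    mean_RMSE: float
    sd_R: float
    sd_RMSE: float
    n_folds: int
    n_replicates: int
    seed: int


# ---------------------------------------------------------------------------
# Fitters: callable factories fit(X_train, y_train) -> predict(X_test) -> yhat
# ---------------------------------------------------------------------------

Fitter = Callable[
    [ChromatinTensor, ExpressionVector], Callable[[ChromatinTensor], np.ndarray]
]


def npls_fitter(factors: int = 5) -> Fitter:
    def fitfn(X: ChromatinTensor, y: ExpressionVector):
        model = npls.fit(X, y, factors)
        return lambda X_test: npls.predict(model, X_test).y

    return fitfn


def lr_fitter() -> Fitter:
    """Ordinary least squares on the unfolded tensor, with intercept.

    Near-collinear directions are truncated at a relative tolerance of 1e-7,
    mirroring the aliased-column handling of standard regression routines;
    binned profiles are highly rank-deficient and keeping noise-level
    singular directions produces unstable out-of-fold predictions.
    """

    def fitfn(X: ChromatinTensor, y: ExpressionVector):
        A = np.column_stack([np.ones(X.n_genes), X.unfold()])
        coef, *_ = np.linalg.lstsq(A, y.y, rcond=1e-7)
        return lambda X_test: np.column_stack(
            [np.ones(X_test.n_genes), X_test.unfold()]
        ) @ coef

    return fitfn


def rf_fitter(n_trees: int = RF_N_TREES, seed: int = 0) -> Fitter:
    def fitfn(X: ChromatinTensor, y: ExpressionVector):
        from sklearn.ensemble import RandomForestRegressor

        model = RandomForestRegressor(n_estimators=n_trees, random_state=seed)
        model.fit(X.unfold(), y.y)
        return lambda X_test: model.predict(X_test.unfold())

    return fitfn


def svr_fitter() -> Fitter:
    """RBF support vector regression with the library's default settings."""

    def fitfn(X: ChromatinTensor, y: ExpressionVector):
        from sklearn.svm import SVR

        model = SVR()
        model.fit(X.unfold(), y.y)
        return lambda X_test: model.predict(X_test.unfold())

    return fitfn


def make_fitter(name: str, factors: int = 5, seed: int = 0) -> Fitter:
    """Resolve a method name to a fitter factory."""
    if name == "npls":
        return npls_fitter(factors)
    if name == "lr":
        return lr_fitter()
    if name == "rf":
        return rf_fitter(seed=seed)
    if name == "svr":
        return svr_fitter()
    raise ValueError(f"unknown method {name!r}; choose from npls, lr, rf, svr")


def make_folds(
    n: int, k: int, n_replicates: int, seed: int
) -> list[np.ndarray]:
    """Balanced random fold labels per replicate (sizes differ by <= 1)."""
    if n < k:
        raise ValueError(f"cannot split {n} genes into {k} folds")
    rng = np.random.default_rng(seed)
    assignments = []
    for _ in range(n_replicates):
        labels = np.tile(np.arange(k), n // k + 1)[:n]
        assignments.append(rng.permutation(labels))
    return assignments


def kfold_cv(
    X: ChromatinTensor,
    y: ExpressionVector,
    fitter: Fitter | str,
    k: int = 10,
    n_replicates: int = 10,
    seed: int = 0,
    factors: int = 5,
    fold_assignments: list[np.ndarray] | None = None,
    pooled: bool = False,
    method_name: str | None = None,
) -> CVResult:
    """Replicated k-fold cross-validation of one method.

    Per replicate the genes are partitioned into k balanced random folds;
    each fold is predicted by a model trained on the other k-1. R and RMSE
    are computed per fold and averaged (``pooled=True`` instead concatenates
    all held-out predictions per replicate before computing the metrics).
    Deterministic given the seed.
    """
    X, y = align_genes(X, y)
    if isinstance(fitter, str):
        method_name = method_name or fitter
        fitter = make_fitter(fitter, factors=factors, seed=seed)
    method_name = method_name or "custom"
    if fold_assignments is None:
        fold_assignments = make_folds(X.n_genes, k, n_replicates, seed)

    fold_r: list[float] = []
    fold_rmse: list[float] = []
    for labels in fold_assignments:
        rep_true: list[np.ndarray] = []
        rep_pred: list[np.ndarray] = []
        for fold in range(k):
            test_idx = np.flatnonzero(labels == fold)
            train_idx = np.flatnonzero(labels != fold)
            predict_fn = fitter(X.subset_genes(train_idx), y.subset_genes(train_idx))
            y_hat = predict_fn(X.subset_genes(test_idx))
            y_true = y.y[test_idx]
            if pooled:
                rep_true.append(y_true)
                rep_pred.append(np.asarray(y_hat))
            else:
                fold_r.append(pearson_r(y_true, y_hat))
                fold_rmse.append(rmse(y_true, y_hat))
        if pooled:
            yt, yp = np.concatenate(rep_true), np.concatenate(rep_pred)
            fold_r.append(pearson_r(yt, yp))
            fold_rmse.append(rmse(yt, yp))

    return CVResult(
        method_name=method_name,
        fold_assignments=fold_assignments,
        fold_r=fold_r,
        fold_rmse=fold_rmse,
        mean_R=float(np.mean(fold_r)),
        mean_RMSE=float(np.mean(fold_rmse)),
        sd_R=float(np.std(fold_r, ddof=1)) if len(fold_r) > 1 else 0.0,
        sd_RMSE=float(np.std(fold_rmse, ddof=1)) if len(fold_rmse) > 1 else 0.0,
        n_folds=k,
        n_replicates=n_replicates,
        seed=seed,
    )


def benchmark(
    X: ChromatinTensor,
    y: ExpressionVector,
    methods: list[str] = ("npls", "lr", "rf", "svr"),
    k: int = 10,
    n_replicates: int = 10,
    seed: int = 0,
    factors: int = 5,
) -> pd.DataFrame:
    """Cross-validate several methods on identical fold assignments.

    Returns one row per method with mean/sd R and RMSE; ``format_table``
    renders the conventional "R(RMSE)" cell layout.
    """
    if not methods:
        raise ValueError("methods must be non-empty")
    X, y = align_genes(X, y)
    folds = make_folds(X.n_genes, k, n_replicates, seed)
    rows = []
    for name in methods:
        res = kfold_cv(
            X,
            y,
            name,
            k=k,
            n_replicates=n_replicates,
            seed=seed,
            factors=factors,
            fold_assignments=folds,
        )
        rows.append(
            {
                "method": name,
                "mean_R": res.mean_R,
                "sd_R": res.sd_R,
                "mean_RMSE": res.mean_RMSE,
                "sd_RMSE": res.sd_RMSE,
                "n_folds": k,
                "n_replicates": n_replicates,
                "factors": factors if name == "npls" else np.nan,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)


def format_table(result: pd.DataFrame) -> str:
    """Human-readable benchmark table with R(RMSE) cells."""
    cells = [
        f"{row['method']}: {row['mean_R']:.3f}({row['mean_RMSE']:.2f})"
        for _, row in result.iterrows()
    ]
    return "  ".join(cells)


def factor_sweep(
    X: ChromatinTensor,
    y: ExpressionVector,
    f_values: list[int],
    k: int = 10,
    n_replicates: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validate the tensor model at each factor count on shared folds."""
    if not f_values:
        raise ValueError("f_values must be non-empty")
    X, y = align_genes(X, y)
    folds = make_folds(X.n_genes, k, n_replicates, seed)
    rows = []
    for f in f_values:
        res = kfold_cv(
            X,
            y,
            "npls",
            k=k,
            n_replicates=n_replicates,
            seed=seed,
            factors=f,
            fold_assignments=folds,
        )
        rows.append(
            {
                "f": f,
                "mean_R": res.mean_R,
                "sd_R": res.sd_R,
                "mean_RMSE": res.mean_RMSE,
                "sd_RMSE": res.sd_RMSE,
            }
        )
    return pd.DataFrame(rows)
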
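"""Log-transform normalization with a pseudocount tuned on held-out genes.

Binned signal is stabilized with ``log2(x + theta)`` where theta is chosen
per (mark, bin) on a tuning third of the genes: the grid value maximizing the
absolute Pearson correlation between the transformed signal and the
(log-scaled) expression response. The tuning genes are then excluded from all
model fitting and evaluation so the pseudocount choice cannot leak into the
reported performance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from chromnpls.tensor import ChromatinTensor, ExpressionVector

#: log2-spaced default pseudocount grid: 2^-8 ... 2^8.
DEFAULT_THETA_GRID = tuple(float(2.0**k) for k in range(-8, 9))


@dataclass
class NormalizationParams:
    """Fitted pseudocounts: one theta per (mark, bin), plus tuning provenance."""

    theta: np.ndarray  # (n_marks, n_bins)
    mark_names: list[str]
    bin_offsets: np.ndarray
    theta_grid: tuple[float, ...]
    tuning_gene_ids: list[str]
    seed: int | None = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.bin_offsets = np.asarray(self.bin_offsets, dtype=float)
        if self.theta.shape != (len(self.mark_names), self.bin_offsets.size):
            raise ValueError("theta shape does not match mark/bin labels")
        if np.any(self.theta <= 0):
            raise ValueError("all theta must be > 0")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "theta_grid": list(self.theta_grid),
            "seed": self.seed,
            "tuning_gene_ids": self.tuning_gene_ids,
            "entries": [
                {
                    "mark": mark,
                    "bin_offset": float(off),
                    "theta": float(self.theta[mi, bi]),
                }
                for mi, mark in enumerate(self.mark_names)
                for bi, off in enumerate(self.bin_offsets)
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationParams":
        payload = json.loads(Path(path).read_text())
        marks: list[str] = []
        offsets: list[float] = []
        for e in payload["entries"]:
            if e["mark"] not in marks:
                marks.append(e["mark"])
            if e["bin_offset"] not in offsets:
                offsets.append(e["bin_offset"])
        theta = np.empty((len(marks), len(offsets)))
        for e in payload["entries"]:
            theta[marks.index(e["mark"]), offsets.index(e["bin_offset"])] = e["theta"]
        return cls(
            theta=theta,
            mark_names=marks,
            bin_offsets=np.array(offsets),
            theta_grid=tuple(payload["theta_grid"]),
            tuning_gene_ids=payload["tuning_gene_ids"],
            seed=payload["seed"],
        )


def split_thirds(gene_ids: list[str], seed: int) -> tuple[list[str], list[str]]:
    """Randomly split genes into a tuning third and a modelling two-thirds.

    The split is uniform, disjoint, exhaustive, and deterministic given the
    seed; the tuning set has ``round(n/3)`` genes.
    """
    n = len(gene_ids)
    if n < 3:
        raise ValueError(f"need at least 3 genes to split, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_tune = int(round(n / 3))
    tune_idx = set(perm[:n_tune].tolist())
    tuning = [g for i, g in enumerate(gene_ids) if i in tune_idx]
    modelling = [g for i, g in enumerate(gene_ids) if i not in tune_idx]
    return tuning, modelling


def _abs_pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return np.nan
    return abs(float(xc @ yc) / denom)


def fit_theta(
    tensor_tuning: ChromatinTensor,
    y_tuning: ExpressionVector,
    grid: tuple[float, ...] = DEFAULT_THETA_GRID,
    seed: int | None = None,
) -> NormalizationParams:
    """Choose theta per (mark, bin) on tuning genes by correlation screening.

    For each (mark, bin) column the selected theta maximizes
    ``|corr(log2(x + theta), y)]`` over the grid; ties break toward the
    smallest theta. Grid values for which ``x + theta <= 0`` anywhere in the
    column are infeasible. A column with undefined correlation for every
    feasible theta (constant signal) falls back to the grid midpoint with a
    warning.
    """
    if tensor_tuning.gene_ids != y_tuning.gene_ids:
        raise ValueError("tuning tensor and response must share gene order")
    if not grid:
        raise ValueError("theta grid is empty")
    grid = tuple(sorted(float(t) for t in grid))
    if grid[0] <= 0:
        raise ValueError("all grid theta must be positive")

    y = y_tuning.y
    n_marks, n_bins = tensor_tuning.n_marks, tensor_tuning.n_bins
    theta = np.empty((n_marks, n_bins))
    midpoint = grid[len(grid) // 2]
    for mi in range(n_marks):
        for bi in range(n_bins):
            x = tensor_tuning.values[:, mi, bi]
            best_obj, best_theta = -np.inf, None
            for t in grid:
                shifted = x + t
                if np.any(shifted <= 0):
                    continue
                obj = _abs_pearson(np.log2(shifted), y)
                if np.isnan(obj):
                    continue
                if obj > best_obj:  # strict: ties keep the smaller theta
                    best_obj, best_theta = obj, t
            if best_theta is None:
                warnings.warn(
                    f"constant signal in mark={tensor_tuning.mark_names[mi]!r} "
                    f"bin_offset={tensor_tuning.bin_offsets[bi]}: theta set to "
                    f"grid midpoint {midpoint}",
                    stacklevel=2,
                )
                best_theta = midpoint
            theta[mi, bi] = best_theta
    return NormalizationParams(
        theta=theta,
        mark_names=tensor_tuning.mark_names,
        bin_offsets=tensor_tuning.bin_offsets,
        theta_grid=grid,
        tuning_gene_ids=list(tensor_tuning.gene_ids),
        seed=seed,
    )


def apply_theta(
    tensor: ChromatinTensor, params: NormalizationParams
) -> ChromatinTensor:
    """Elementwise ``log2(x + theta[mark, bin])``; shape and labels preserved."""
    if tensor.mark_names != params.mark_names:
        raise ValueError("tensor and params disagree on marks")
    if not np.array_equal(tensor.bin_offsets, params.bin_offsets):
        raise ValueError("tensor and params disagree on bin offsets")
    shifted = tensor.values + params.theta[np.newaxis, :, :]
    if np.any(shifted <= 0):
        cells = np.argwhere(shifted <= 0)
        desc = [
            f"(gene={tensor.gene_ids[g]!r}, mark={tensor.mark_names[m]!r}, "
            f"bin_offset={tensor.bin_offsets[b]})"
            for g, m, b in cells[:5]
        ]
        raise ValueError(
            f"x + theta <= 0 in {len(cells)} cells, e.g. {'; '.join(desc)}"
        )
    return ChromatinTensor(
        values=np.log2(shifted),
        gene_ids=tensor.gene_ids,
        mark_names=tensor.mark_names,
        bin_offsets=tensor.bin_offsets,
    )


def scale_expression(
    rpkm: np.ndarray,
    gene_ids: list[str],
    pseudocount: float = 0.0,
) -> ExpressionVector:
    """Average RPKM over individuals, then log2-scale.

    ``rpkm`` is (n_genes,) or (n_genes, n_individuals); the mean over
    individuals is taken first, then ``log2(mean + pseudocount)``.
    """
    rpkm = np.asarray(rpkm, dtype=float)
    if np.any(rpkm < 0):
        raise ValueError("RPKM values must be >= 0")
    mean = rpkm if rpkm.ndim == 1 else rpkm.mean(axis=1)
    shifted = mean + pseudocount
    if np.any(shifted <= 0):
        bad = [gene_ids[i] for i in np.flatnonzero(shifted <= 0)[:5]]
        raise ValueError(
            f"mean RPKM + pseudocount <= 0 for genes {bad}; "
            "use a positive pseudocount or filter unexpressed genes"
        )
    return ExpressionVector(
        y=np.log2(shifted),
        gene_ids=gene_ids,
        scale="log2",
        pseudocount=pseudocount,
    )
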
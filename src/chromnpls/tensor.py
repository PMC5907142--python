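"""Core in-memory containers: the chromatin signal tensor and the expression vector."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ChromatinTensor:
    """A 3-way array of chromatin signal: genes x marks x bins.

    Parameters
    ----------
    values
        Array of shape ``(n_genes, n_marks, n_bins)``; all entries finite.
    gene_ids
        One identifier per gene (first axis).
    mark_names
        One name per histone mark / factor (second axis).
    bin_offsets
        Bin-center positions relative to the anchor (TSS, in bp, or the
        center of a density-support interval for simulated data), in
        transcription-sense order: strictly increasing and symmetric
        about 0.
    """

    values: np.ndarray
    gene_ids: list[str]
    mark_names: list[str]
    bin_offsets: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.bin_offsets = np.asarray(self.bin_offsets, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.mark_names = list(self.mark_names)
        if self.values.ndim != 3:
            raise ValueError(f"tensor must be 3-way, got {self.values.ndim} axes")
        n_genes, n_marks, n_bins = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} gene slices"
            )
        if len(self.mark_names) != n_marks:
            raise ValueError(
                f"{len(self.mark_names)} mark names for {n_marks} mark slices"
            )
        if self.bin_offsets.shape != (n_bins,):
            raise ValueError(
                f"{self.bin_offsets.size} bin offsets for {n_bins} bins"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tensor contains non-finite values")
        if n_bins > 1:
            if not np.all(np.diff(self.bin_offsets) > 0):
                raise ValueError("bin offsets must be strictly increasing")
            if not np.allclose(self.bin_offsets, -self.bin_offsets[::-1]):
                raise ValueError("bin offsets must be symmetric about 0")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene ids must be unique")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_marks(self) -> int:
        return self.values.shape[1]

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]

    def unfold(self) -> np.ndarray:
        """Matricize along the gene mode: ``(n_genes, n_marks * n_bins)``.

        Used by matrix-based baseline regressors that cannot consume a
        3-way array directly.
        """
        return self.values.reshape(self.n_genes, -1)

    def subset_genes(self, indices: np.ndarray) -> "ChromatinTensor":
        """Return a tensor restricted to the given gene positions (in order)."""
        indices = np.asarray(indices)
        return ChromatinTensor(
            values=self.values[indices],
            gene_ids=[self.gene_ids[i] for i in indices],
            mark_names=self.mark_names,
            bin_offsets=self.bin_offsets,
        )


@dataclass
class ExpressionVector:
    """Per-gene expression response, raw (RPKM) or log2-scaled."""

    y: np.ndarray
    gene_ids: list[str]
    scale: str = "raw"
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.gene_ids = list(self.gene_ids)
        if self.y.ndim != 1:
            raise ValueError("expression must be a 1-d vector")
        if len(self.gene_ids) != self.y.size:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {self.y.size} values"
            )
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    def subset_genes(self, indices: np.ndarray) -> "ExpressionVector":
        indices = np.asarray(indices)
        return ExpressionVector(
            y=self.y[indices],
            gene_ids=[self.gene_ids[i] for i in indices],
            scale=self.scale,
            pseudocount=self.pseudocount,
        )


def align_genes(
    tensor: ChromatinTensor, expression: ExpressionVector
) -> tuple[ChromatinTensor, ExpressionVector]:
    """Reorder the expression vector to the tensor's gene order.

    Raises if either side has genes the other lacks.
    """
    if tensor.gene_ids == expression.gene_ids:
        return tensor, expression
    pos = {g: i for i, g in enumerate(expression.gene_ids)}
    missing = [g for g in tensor.gene_ids if g not in pos]
    if missing:
        raise ValueError(f"expression lacks genes: {missing[:5]}...")
    extra = set(expression.gene_ids) - set(tensor.gene_ids)
    if extra:
        raise ValueError(f"expression has genes absent from tensor: {sorted(extra)[:5]}...")
    order = np.array([pos[g] for g in tensor.gene_ids])
    return tensor, expression.subset_genes(order)
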
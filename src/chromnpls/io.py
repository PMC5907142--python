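"""Readers, coverage normalization, tensor assembly, and serialization.

File formats
------------
* **Annotations**: BED6 (chrom, start, end, name, score, strand), 0-based
  half-open. The TSS is the interval start for + genes and the interval end
  for - genes; it is converted to the package's 1-based TSS convention.
* **Coverage**: tab-separated long format with a header line
  ``gene_id  mark  individual  bin_index  treatment_count  input_count``,
  one row per (gene, mark, individual, bin).
* **Expression**: tab-separated with header ``gene_id  individual  rpkm``.
* **Tensor container**: NumPy ``.npz`` holding the value array plus axis
  labels (lossless round-trip); :func:`export_tensor_long` writes a
  plain-text long-format view.

Library-size normalization follows the input-subtraction scheme: per bin,
``treatment/total_mapped - input/total_input``, where the totals are the
per-(mark, individual) library sizes. Totals can be supplied explicitly;
by default they are the column sums over the coverage table.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from chromnpls.binning import BinningConfig, GeneAnnotation
from chromnpls.tensor import ChromatinTensor, ExpressionVector

COVERAGE_COLUMNS = [
    "gene_id",
    "mark",
    "individual",
    "bin_index",
    "treatment_count",
    "input_count",
]


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read BED6 gene annotations; TSS = start for +, end for - (1-based out)."""
    annotations = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}"
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {name!r}")
            seen.add(name)
            # BED start is 0-based; the TSS base is `start` for + genes
            # (1-based start+1) and `end` for - genes (1-based end).
            tss = start + 1 if strand == "+" else end
            annotations.append(
                GeneAnnotation(gene_id=name, chrom=chrom, tss=tss, strand=strand)
            )
    return annotations


def read_coverage(path: str | Path) -> pd.DataFrame:
    """Read a long-format binned coverage table, validating types per line."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in COVERAGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing coverage columns {missing}")
    out = df[COVERAGE_COLUMNS].copy()
    for col in ("bin_index", "treatment_count", "input_count"):
        converted = pd.to_numeric(out[col], errors="coerce")
        bad = converted.isna() | (converted % 1 != 0)
        if bad.any():
            # +2: header line plus 1-based numbering
            lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(
                f"{path}:{lineno}: non-integer value {out[col].iloc[lineno - 2]!r} "
                f"in column {col!r}"
            )
        out[col] = converted.astype(int)
    if (out[["treatment_count", "input_count"]] < 0).any().any():
        raise ValueError(f"{path}: negative counts are not allowed")
    if (out["bin_index"] < 0).any():
        raise ValueError(f"{path}: negative bin_index")
    return out


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a per-individual expression table (gene_id, individual, rpkm)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "individual", "rpkm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing expression column {col!r}")
    if (df["rpkm"] < 0).any():
        raise ValueError(f"{path}: negative RPKM values")
    return df


def normalize_coverage(
    treatment_count, total_mapped, input_count, total_input
):
    """Input-subtracted, depth-normalized signal for one bin.

    ``treatment/total_mapped - input/total_input``; may be negative when the
    control is locally enriched. Accepts scalars or aligned arrays.
    """
    total_mapped = np.asarray(total_mapped, dtype=float)
    total_input = np.asarray(total_input, dtype=float)
    if np.any(total_mapped <= 0):
        raise ValueError("total mapped reads must be > 0")
    if np.any(total_input <= 0):
        raise ValueError("total input reads must be > 0")
    result = (
        np.asarray(treatment_count, dtype=float) / total_mapped
        - np.asarray(input_count, dtype=float) / total_input
    )
    return float(result) if result.ndim == 0 else result


def average_individuals(signals: dict[str, pd.Series]) -> pd.Series:
    """Average per-individual signal series over individuals.

    Each series is indexed by (gene_id, mark, bin_index); all individuals
    must cover exactly the same index set.
    """
    if not signals:
        raise ValueError("no individuals to average")
    individuals = sorted(signals)
    ref = signals[individuals[0]].index
    for ind in individuals[1:]:
        idx = signals[ind].index
        missing = ref.difference(idx)
        extra = idx.difference(ref)
        if len(missing) or len(extra):
            raise ValueError(
                f"individual {ind!r} index mismatch: "
                f"missing {list(missing[:5])}, extra {list(extra[:5])}"
            )
    stacked = pd.concat([signals[ind].loc[ref] for ind in individuals], axis=1)
    return stacked.mean(axis=1)


def build_tensor(
    records: pd.DataFrame,
    annotations: list[GeneAnnotation],
    config: BinningConfig,
    mark_names: list[str] | None = None,
    totals: pd.DataFrame | None = None,
) -> ChromatinTensor:
    """Assemble the genes x marks x bins tensor from long-format coverage.

    Counts are depth-normalized and input-subtracted per (mark, individual),
    then averaged across individuals. Genes follow the annotation order,
    marks the declared order (default: order of first appearance), bins the
    transcription-sense order. Any missing (gene, mark, bin) cell is an
    error — silent zero-fill would bias the downstream covariance step.

    Parameters
    ----------
    totals
        Optional per-library sizes with columns
        ``mark, individual, total_mapped, total_input``. When omitted, the
        totals are the sums of the respective count columns within
        ``records`` per (mark, individual).
    """
    n_bins = config.n_bins
    gene_ids = [a.gene_id for a in annotations]
    if mark_names is None:
        mark_names = list(pd.unique(records["mark"]))

    dup = records.duplicated(subset=["gene_id", "mark", "individual", "bin_index"])
    if dup.any():
        row = records[dup].iloc[0]
        raise ValueError(
            f"duplicate coverage record for gene={row['gene_id']!r} "
            f"mark={row['mark']!r} individual={row['individual']!r} "
            f"bin={row['bin_index']}"
        )
    if (records["bin_index"] >= n_bins).any():
        bad = records.loc[records["bin_index"] >= n_bins].iloc[0]
        raise ValueError(
            f"bin_index {bad['bin_index']} out of range for {n_bins} bins"
        )

    if totals is None:
        totals = (
            records.groupby(["mark", "individual"], sort=False)[
                ["treatment_count", "input_count"]
            ]
            .sum()
            .rename(
                columns={
                    "treatment_count": "total_mapped",
                    "input_count": "total_input",
                }
            )
            .reset_index()
        )
    tot = totals.set_index(["mark", "individual"])
    for (mark, ind), row in tot.iterrows():
        if row["total_mapped"] <= 0:
            raise ValueError(
                f"zero total mapped reads for mark={mark!r} individual={ind!r}"
            )
        if row["total_input"] <= 0:
            raise ValueError(
                f"zero total input reads for mark={mark!r} individual={ind!r}"
            )

    merged = records.merge(
        tot, left_on=["mark", "individual"], right_index=True, how="left"
    )
    if merged["total_mapped"].isna().any():
        row = merged[merged["total_mapped"].isna()].iloc[0]
        raise ValueError(
            f"no library totals for mark={row['mark']!r} "
            f"individual={row['individual']!r}"
        )
    merged["signal"] = normalize_coverage(
        merged["treatment_count"].to_numpy(),
        merged["total_mapped"].to_numpy(),
        merged["input_count"].to_numpy(),
        merged["total_input"].to_numpy(),
    )

    per_individual = {
        ind: grp.set_index(["gene_id", "mark", "bin_index"])["signal"]
        for ind, grp in merged.groupby("individual", sort=False)
    }
    mean_signal = average_individuals(per_individual)

    tensor = np.full((len(gene_ids), len(mark_names), n_bins), np.nan)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    mark_pos = {m: i for i, m in enumerate(mark_names)}
    idx = mean_signal.index
    gi = np.array([gene_pos.get(g, -1) for g in idx.get_level_values("gene_id")])
    mi = np.array([mark_pos.get(m, -1) for m in idx.get_level_values("mark")])
    bi = idx.get_level_values("bin_index").to_numpy()
    keep = (gi >= 0) & (mi >= 0)
    tensor[gi[keep], mi[keep], bi[keep]] = mean_signal.to_numpy()[keep]

    if np.isnan(tensor).any():
        g, m, b = np.argwhere(np.isnan(tensor))[0]
        raise ValueError(
            f"missing coverage for gene={gene_ids[g]!r} "
            f"mark={mark_names[m]!r} bin={b}"
        )
    return ChromatinTensor(
        values=tensor,
        gene_ids=gene_ids,
        mark_names=mark_names,
        bin_offsets=np.array(config.bin_offsets, dtype=float),
    )


def write_tensor(tensor: ChromatinTensor, path: str | Path) -> None:
    """Serialize a tensor losslessly to an ``.npz`` container."""
    np.savez(
        path,
        values=tensor.values,
        gene_ids=np.array(tensor.gene_ids, dtype=object),
        mark_names=np.array(tensor.mark_names, dtype=object),
        bin_offsets=tensor.bin_offsets,
    )


def read_tensor(path: str | Path) -> ChromatinTensor:
    """Read a tensor written by :func:`write_tensor` (values bit-equal)."""
    with np.load(path, allow_pickle=True) as data:
        return ChromatinTensor(
            values=data["values"],
            gene_ids=[str(g) for g in data["gene_ids"]],
            mark_names=[str(m) for m in data["mark_names"]],
            bin_offsets=data["bin_offsets"],
        )


def export_tensor_long(tensor: ChromatinTensor, path: str | Path) -> None:
    """Write a plain-text long-format view (gene_id, mark, bin_offset, value)."""
    n_genes, n_marks, n_bins = tensor.shape
    frame = pd.DataFrame(
        {
            "gene_id": np.repeat(tensor.gene_ids, n_marks * n_bins),
            "mark": np.tile(np.repeat(tensor.mark_names, n_bins), n_genes),
            "bin_offset": np.tile(tensor.bin_offsets, n_genes * n_marks),
            "value": tensor.values.ravel(),
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def write_expression(expression: ExpressionVector, path: str | Path) -> None:
    """Write a per-gene expression vector as TSV (gene_id, value, scale)."""
    pd.DataFrame(
        {
            "gene_id": expression.gene_ids,
            "value": expression.y,
            "scale": expression.scale,
        }
    ).to_csv(path, sep="\t", index=False)


def read_expression_vector(path: str | Path) -> ExpressionVector:
    """Read a per-gene expression vector written by :func:`write_expression`."""
    df = pd.read_csv(path, sep="\t")
    scale = str(df["scale"].iloc[0]) if "scale" in df.columns else "raw"
    return ExpressionVector(
        y=df["value"].to_numpy(float),
        gene_ids=[str(g) for g in df["gene_id"]],
        scale=scale,
    )
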
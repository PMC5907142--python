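"""TSS-centered genomic binning.

Each gene's signal window flanks its transcription start site by ``flank_bp``
on both sides. Bins are centered on offsets -flank, -flank+width, ..., +flank
from the TSS, so a window of 10 kb flank and 500 bp bins yields 41 bins (the
central bin straddles the TSS). Bins are reported in transcription-sense
order: bin 0 is the most upstream bin of the gene, so minus-strand genes are
flipped relative to genomic coordinates.

Coordinates are 0-based half-open internally (BED convention); the TSS field
of :class:`GeneAnnotation` is 1-based as in most annotation tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene anchor: identifier, chromosome, 1-based TSS coordinate, strand."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValueError(f"{self.gene_id}: tss must be >= 1, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )


@dataclass(frozen=True)
class BinningConfig:
    """Window geometry around the TSS.

    ``n_bins = 2 * flank_bp / bin_width_bp + 1``: one bin centered on every
    offset from -flank to +flank in steps of the bin width.
    """

    flank_bp: int = 10000
    bin_width_bp: int = 500

    def __post_init__(self) -> None:
        if self.bin_width_bp <= 0:
            raise ValueError(f"bin width must be positive, got {self.bin_width_bp}")
        if self.flank_bp <= 0:
            raise ValueError(f"flank must be positive, got {self.flank_bp}")
        if self.flank_bp % self.bin_width_bp != 0:
            raise ValueError(
                f"bin width {self.bin_width_bp} does not divide flank {self.flank_bp}"
            )

    @property
    def n_bins(self) -> int:
        return 2 * (self.flank_bp // self.bin_width_bp) + 1

    @property
    def bin_offsets(self) -> list[int]:
        """Transcription-sense bin-center offsets from the TSS, in bp."""
        w = self.bin_width_bp
        m = self.n_bins // 2
        return [(k - m) * w for k in range(self.n_bins)]


@dataclass(frozen=True)
class BinInterval:
    """One genomic bin of a gene's window.

    ``start``/``end`` are 0-based half-open genomic coordinates (clipped at
    the chromosome start). ``bin_index`` counts in transcription-sense order;
    ``offset_bp`` is the bin center's transcription-sense distance from the
    TSS (negative = upstream).
    """

    chrom: str
    start: int
    end: int
    bin_index: int
    offset_bp: int


def make_bins(annotation: GeneAnnotation, config: BinningConfig) -> list[BinInterval]:
    """Tile a gene's TSS window into transcription-sense-ordered bins.

    On the + strand bin ``k`` is centered at ``tss + (k - (n_bins-1)/2) * width``;
    on the - strand the genomic direction is mirrored so bin 0 is still the
    most upstream bin in the direction of transcription. The intervals are
    half-open, non-overlapping, and tile
    ``[tss - flank - width/2, tss + flank + width/2)``.

    Bins reaching past the chromosome start are clipped at coordinate 0; a
    gene whose entire window lies off the chromosome is rejected.
    """
    w = config.bin_width_bp
    half = w // 2
    tss0 = annotation.tss - 1  # 0-based position of the TSS base
    offsets = config.bin_offsets
    sign = 1 if annotation.strand == "+" else -1
    intervals = []
    for k, off in enumerate(offsets):
        center = tss0 + sign * off
        start = center - half
        end = start + w
        start_c = max(start, 0)
        end_c = max(end, 0)
        intervals.append(
            BinInterval(
                chrom=annotation.chrom,
                start=start_c,
                end=end_c,
                bin_index=k,
                offset_bp=off,
            )
        )
    if all(iv.end <= 0 or iv.end == iv.start for iv in intervals):
        raise ValueError(
            f"{annotation.gene_id}: window lies entirely before the chromosome start"
        )
    return intervals
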
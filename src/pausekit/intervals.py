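"""Genomic intervals, gene models and interval algebra.

All coordinates are 0-based, half-open ``[start, end)`` — the BED/bedGraph
convention.  Gene tables read from 1-based sources must be converted before
they enter the package; everything downstream assumes the single internal
convention.

Strand conventions
------------------
For a ``+`` gene the TSS is ``start`` and the TES is ``end - 1``; for a ``-``
gene the TSS is ``end - 1`` and the TES is ``start``.  Windows anchored at the
TSS or TES are expressed in transcription-oriented offsets (negative =
upstream of the anchor) and mirrored onto the reference strand for ``-``
genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from intervaltree import IntervalTree

Strand = Literal["+", "-"]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlaps(self, other: "GenomicInterval", min_overlap: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_overlap


@dataclass(frozen=True)
class GeneAnnotation:
    """Strand-aware gene model anchoring TSS/TES windows."""

    gene_id: str
    interval: GenomicInterval
    strand: Strand

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def width(self) -> int:
        return self.interval.width

    @property
    def tss(self) -> int:
        """Transcription start site (last base of the interval on '-')."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        """Transcription end site (the terminus opposite the TSS)."""
        return self.interval.end - 1 if self.strand == "+" else self.interval.start


@dataclass
class Peak:
    """One peak record: an interval plus optional BED name/score."""

    interval: GenomicInterval
    name: str | None = None
    score: float | None = None


@dataclass
class PeakSet:
    """Ordered peak collection, kept sorted by (chrom, start).

    Raw peaks may overlap each other; no merging is implied.
    """

    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(
            self.peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
        )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    @property
    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]


def strand_window(
    gene: GeneAnnotation,
    offset_5p: int,
    offset_3p: int,
    anchor: Literal["TSS", "TES"] = "TSS",
    chrom_length: int | None = None,
) -> tuple[GenomicInterval, bool]:
    """Transcription-oriented window around a gene anchor.

    Offsets are in the direction of transcription (negative = upstream).  For
    a ``+`` gene the window is ``[anchor + offset_5p, anchor + offset_3p)``;
    for a ``-`` gene it is the mirror image
    ``[anchor - offset_3p + 1, anchor - offset_5p + 1)``.

    Returns the window and a flag telling whether it was clipped to
    chromosome bounds.  An empty window (before or after clipping) raises.
    """
    if offset_3p <= offset_5p:
        raise ValueError(
            f"window is empty: offsets ({offset_5p}, {offset_3p}) on gene {gene.gene_id}"
        )
    pos = gene.tss if anchor == "TSS" else gene.tes
    if gene.strand == "+":
        start, end = pos + offset_5p, pos + offset_3p
    else:
        start, end = pos - offset_3p + 1, pos - offset_5p + 1
    clipped = False
    if start < 0:
        start, clipped = 0, True
    if chrom_length is not None and end > chrom_length:
        end, clipped = chrom_length, True
    if end <= start:
        raise ValueError(
            f"window empty after clipping for gene {gene.gene_id}: [{start}, {end})"
        )
    return GenomicInterval(gene.chrom, start, end), clipped


def overlap_pairs(
    set_a: Sequence[GenomicInterval],
    set_b: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> list[tuple[int, int]]:
    """All index pairs (i, j) with overlap(set_a[i], set_b[j]) >= min_overlap bp.

    Interval-tree backed; exhaustive over both (sorted) inputs.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for j, iv in enumerate(set_b):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, j)
    pairs: list[tuple[int, int]] = []
    for i, iv in enumerate(set_a):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            if min(iv.end, hit.end) - max(iv.start, hit.begin) >= min_overlap:
                pairs.append((i, hit.data))
    pairs.sort()
    return pairs


def tss_windows(
    genes: Iterable[GeneAnnotation], flank: int, chrom_lengths: dict[str, int] | None = None
) -> list[GenomicInterval]:
    """Unoriented ``TSS +- flank`` windows, ``[tss - flank, tss + flank + 1)``,
    clipped at zero (and at chromosome length when provided)."""
    out = []
    for g in genes:
        start = max(0, g.tss - flank)
        end = g.tss + flank + 1
        if chrom_lengths is not None and g.chrom in chrom_lengths:
            end = min(end, chrom_lengths[g.chrom])
        out.append(GenomicInterval(g.chrom, start, end))
    return out


def annotate_peaks(
    peaks: PeakSet,
    genes: Sequence[GeneAnnotation],
    promoter_flank: int = 1000,
) -> tuple[list[str], dict[str, float]]:
    """Assign each peak to promoter / gene_body / distal_intergenic.

    Precedence is promoter > gene_body > distal_intergenic: a peak touching
    any ``TSS +- promoter_flank`` window is a promoter peak regardless of what
    else it overlaps.  Returns per-peak categories (input order) and the
    proportion of peaks in each category.
    """
    if not genes:
        raise ValueError("annotate_peaks requires a non-empty gene set")
    promoters = tss_windows(genes, promoter_flank)
    bodies = [g.interval for g in genes]
    peak_ivs = peaks.intervals
    prom_hits = {i for i, _ in overlap_pairs(peak_ivs, promoters)}
    body_hits = {i for i, _ in overlap_pairs(peak_ivs, bodies)}
    categories = []
    for i in range(len(peak_ivs)):
        if i in prom_hits:
            categories.append("promoter")
        elif i in body_hits:
            categories.append("gene_body")
        else:
            categories.append("distal_intergenic")
    n = max(len(categories), 1)
    proportions = {
        cat: categories.count(cat) / n
        for cat in ("promoter", "gene_body", "distal_intergenic")
    }
    return categories, proportions
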
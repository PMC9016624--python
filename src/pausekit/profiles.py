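"""Anchor-centered signal matrices and metagene profiles.

A matrix row is the binned signal in a fixed window around one anchor
(typically a TSS).  Rows of minus-strand anchors are reversed when
``orient_by_strand`` is on, so downstream-of-TSS is always rightward; with
it off, gene bodies are artificially placed to the right regardless of
strand (the unoriented convention of published metagene plots).

The metagene profile is the per-bin mean with standard error over rows,
after removing outlier regions whose row-mean deviates from the grand mean
of row-means by more than ``outlier_sd`` standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .intervals import GeneAnnotation

OUTLIER_SD = 2.0


@dataclass
class AnchorMatrix:
    values: np.ndarray  # rows = anchors, columns = bins
    row_ids: list[str]
    bin_size: int
    flank: int
    oriented: bool
    clipped: np.ndarray = field(default=None)  # bool per row: touched a chromosome edge

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.row_ids):
            raise ValueError("values must be 2-D with one row per row_id")
        if self.clipped is None:
            self.clipped = np.zeros(self.values.shape[0], dtype=bool)

    @property
    def bin_centers(self) -> np.ndarray:
        n = self.values.shape[1]
        return (np.arange(n) - n / 2 + 0.5) * self.bin_size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"bin_{i}" for i in range(self.values.shape[1])])
        df.insert(0, "row_id", self.row_ids)
        return df


def build_matrix(
    track: CoverageTrack,
    anchors: Sequence[GeneAnnotation],
    flank: int = 2000,
    bin_size: int = 50,
    orient_by_strand: bool = True,
) -> AnchorMatrix:
    """Signal matrix over ``anchor TSS +- flank`` windows.

    Rows partially outside the chromosome are zero-padded and flagged, not
    dropped.  ``flank`` must be at least one bin and a multiple of bin_size.
    """
    if flank < bin_size:
        raise ValueError("flank must be at least one bin wide")
    if flank % bin_size != 0:
        raise ValueError("flank must be a multiple of bin_size")
    n_bins = 2 * flank // bin_size
    rows = np.zeros((len(anchors), n_bins))
    clipped = np.zeros(len(anchors), dtype=bool)
    from .intervals import GenomicInterval

    for r, gene in enumerate(anchors):
        chrom_len = track.chrom_lengths[gene.chrom]
        # oriented minus-strand windows are shifted by +1 bp so that, after
        # reversal, the TSS base occupies the same column as on plus strands
        mirror = orient_by_strand and gene.strand == "-"
        left = gene.tss - flank + (1 if mirror else 0)
        for j in range(n_bins):
            s, e = left + j * bin_size, left + (j + 1) * bin_size
            cs, ce = max(s, 0), min(e, chrom_len)
            if ce <= cs:
                clipped[r] = True
                continue  # fully off-chromosome: zero-padded
            if (cs, ce) != (s, e):
                clipped[r] = True
            sig = track.region_signal(GenomicInterval(gene.chrom, cs, ce))
            rows[r, j] = sig * (ce - cs) / bin_size  # pad missing bases with zero
        if mirror:
            rows[r] = rows[r, ::-1]
    return AnchorMatrix(rows, [g.gene_id for g in anchors], bin_size, flank, orient_by_strand, clipped)


def metagene(
    matrix: AnchorMatrix, outlier_sd: float = OUTLIER_SD
) -> pd.DataFrame:
    """Per-bin mean and s.e.m. over retained rows, plus n_used.

    A row is an outlier when its row-mean deviates from the grand mean of
    row-means by strictly more than ``outlier_sd`` standard deviations (of
    the row-means).  All rows removed is an error.
    """
    v = matrix.values
    row_means = v.mean(axis=1)
    sd = row_means.std(ddof=1) if len(row_means) > 1 else 0.0
    if sd == 0.0:
        keep = np.ones(len(row_means), dtype=bool)
    else:
        keep = np.abs(row_means - row_means.mean()) <= outlier_sd * sd
    if not keep.any():
        raise ValueError("outlier filter removed every row")
    kept = v[keep]
    n = kept.shape[0]
    mean = kept.mean(axis=0)
    sem = kept.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(v.shape[1])
    return pd.DataFrame(
        {
            "bin_center": matrix.bin_centers,
            "mean": mean,
            "sem": sem,
            "n_used": n,
        }
    )


def rank_matrix(matrix: AnchorMatrix, key: Sequence[float]) -> AnchorMatrix:
    """Stable descending sort of rows by ``key`` (ties broken by row id)."""
    if len(key) != matrix.values.shape[0]:
        raise ValueError("key must have one value per row")
    order = sorted(
        range(len(key)), key=lambda i: (-float(key[i]), matrix.row_ids[i])
    )
    return AnchorMatrix(
        matrix.values[order],
        [matrix.row_ids[i] for i in order],
        matrix.bin_size,
        matrix.flank,
        matrix.oriented,
        matrix.clipped[order],
    )
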
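"""Plain-text readers and writers.

Formats
-------
* gene table: TSV, header ``chrom  start  end  strand  gene_id``, 0-based
  half-open coordinates;
* coverage: bedGraph (``chrom  start  end  value``), records aligned to a
  fixed bin grid, absent bins read as zero;
* peaks: BED3/BED6;
* chromosome sizes: two-column TSV (``chrom  length``), no header;
* interactions: TSV with header ``bait_chrom bait_start bait_end bait_id
  oe_chrom oe_start oe_end count_rep1 count_rep2``;
* generic tables (counts, DE statistics, summaries): TSV with header, tab
  separated, UTF-8, ``.`` for missing values.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .intervals import GeneAnnotation, GenomicInterval, Peak, PeakSet

GENE_TABLE_COLUMNS = ["chrom", "start", "end", "strand", "gene_id"]
INTERACTION_COLUMNS = [
    "bait_chrom", "bait_start", "bait_end", "bait_id",
    "oe_chrom", "oe_start", "oe_end", "count_rep1", "count_rep2",
]


class TableFormatError(ValueError):
    """Malformed input table; message carries the offending line number."""


def read_gene_table(path: str | Path) -> list[GeneAnnotation]:
    """Read a gene annotation TSV, validating every record.

    Raises :class:`TableFormatError` naming the first offending line for a
    malformed strand, non-positive width or duplicate gene_id.
    """
    genes: list[GeneAnnotation] = []
    seen: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != GENE_TABLE_COLUMNS:
            raise TableFormatError(
                f"{path}: line 1: expected header {GENE_TABLE_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise TableFormatError(f"{path}: line {lineno}: expected 5 fields")
            chrom, start_s, end_s, strand, gene_id = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise TableFormatError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            if strand not in ("+", "-"):
                raise TableFormatError(
                    f"{path}: line {lineno}: malformed strand {strand!r}"
                )
            if end <= start or start < 0:
                raise TableFormatError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            if gene_id in seen:
                raise TableFormatError(
                    f"{path}: line {lineno}: duplicate gene_id {gene_id!r} "
                    f"(first seen line {seen[gene_id]})"
                )
            seen[gene_id] = lineno
            genes.append(
                GeneAnnotation(gene_id, GenomicInterval(chrom, start, end), strand)
            )
    return genes


def write_gene_table(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.interval.start}\t{g.interval.end}\t{g.strand}\t{g.gene_id}\n"
            )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise TableFormatError(f"{path}: line {lineno}: expected 2 fields")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise TableFormatError(
                    f"{path}: line {lineno}: non-integer length"
                ) from exc
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_bedgraph(
    path: str | Path, bin_size: int, chrom_sizes: dict[str, int]
) -> CoverageTrack:
    """Read a grid-aligned bedGraph into a :class:`CoverageTrack`.

    Every record must start on the bin grid and cover whole bins (the final
    record of a chromosome may be truncated by the chromosome end); bins not
    covered by any record are zero.
    """
    track = CoverageTrack(bin_size=bin_size, chrom_lengths=dict(chrom_sizes))
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise TableFormatError(f"{path}: line {lineno}: expected 4 fields")
            chrom, start_s, end_s, value_s = fields
            if chrom not in chrom_sizes:
                raise TableFormatError(
                    f"{path}: line {lineno}: unknown chromosome {chrom!r}"
                )
            try:
                start, end = int(start_s), int(end_s)
                value = float(value_s)
            except ValueError as exc:
                raise TableFormatError(
                    f"{path}: line {lineno}: non-numeric field"
                ) from exc
            if not math.isfinite(value):
                raise TableFormatError(f"{path}: line {lineno}: non-finite value")
            chrom_end = chrom_sizes[chrom]
            aligned_end = end % bin_size == 0 or end == chrom_end
            if start % bin_size != 0 or not aligned_end or end <= start:
                raise TableFormatError(
                    f"{path}: line {lineno}: interval [{start}, {end}) not aligned "
                    f"to {bin_size}-bp grid"
                )
            if end > chrom_end:
                raise TableFormatError(
                    f"{path}: line {lineno}: interval exceeds {chrom} length {chrom_end}"
                )
            track.values[chrom][start // bin_size : math.ceil(end / bin_size)] = value
    return track


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write non-zero bins as bedGraph records, merging equal-value runs."""
    with open(path, "w", encoding="utf-8") as fh:
        for chrom in track.chroms:
            v = track.values[chrom]
            length = track.chrom_lengths[chrom]
            if v.size == 0:
                continue
            # boundaries of equal-value runs
            change = np.flatnonzero(v[1:] != v[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [v.size]))
            for s, e in zip(starts, ends):
                val = v[s]
                if val == 0.0:
                    continue
                bp_end = min(int(e) * track.bin_size, length)
                fh.write(
                    f"{chrom}\t{int(s) * track.bin_size}\t{bp_end}\t{float(val)!r}\n"
                )


def read_bed(path: str | Path) -> PeakSet:
    """Read BED3/BED6 peaks (name and score optional)."""
    peaks: list[Peak] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TableFormatError(f"{path}: line {lineno}: expected >= 3 fields")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise TableFormatError(f"{path}: line {lineno}: {exc}") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = (
                float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
            )
            peaks.append(Peak(iv, name=name, score=score))
    return PeakSet(peaks)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in peaks:
            iv = p.interval
            if p.name is None and p.score is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = p.name if p.name is not None else "."
                score = f"{p.score!r}" if p.score is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\n")


def read_table(path: str | Path, required: Iterable[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["."], keep_default_na=True)
    if required is not None:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise TableFormatError(f"{path}: missing required columns {missing}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=".", lineterminator="\n")


def read_interactions(path: str | Path) -> pd.DataFrame:
    return read_table(path, required=INTERACTION_COLUMNS)
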
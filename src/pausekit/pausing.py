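"""Pol II pausing index (PI).

The PI of a gene is the ratio of mean per-bp Pol II density in the
promoter-proximal window, (-30, +300) bp around the TSS oriented along
transcription, to the density over the transcribed region (TSS + 300 bp to
the TES).  Genes shorter than 1 kb are excluded, as are genes whose
promoter-proximal density falls below 1.2 (no appreciable Pol II binding)
and genes with non-positive body density (undefined ratio).  A gene is
called paused when PI > 2 and not paused when PI < 2; a PI of exactly 2 is
conservatively called not paused.

Tracks are expected to be clamped (negative input-subtracted bins zeroed)
before densities are measured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .intervals import GeneAnnotation, strand_window

logger = logging.getLogger(__name__)

Status = Literal["ok", "excluded_width", "excluded_low_promoter", "excluded_zero_body"]

PROMOTER_WINDOW = (-30, 300)
MIN_GENE_WIDTH = 1000
MIN_PROMOTER_DENSITY = 1.2
PAUSED_THRESHOLD = 2.0


@dataclass
class PausingRecord:
    gene_id: str
    d_prom: float | None
    d_body: float | None
    pi: float | None
    status: Status

    def __post_init__(self) -> None:
        if (self.status == "ok") != (self.pi is not None):
            raise ValueError("PI must be defined exactly when status is 'ok'")


def compute_pi(
    track: CoverageTrack,
    gene: GeneAnnotation,
    promoter_window: tuple[int, int] = PROMOTER_WINDOW,
    min_width: int = MIN_GENE_WIDTH,
    min_promoter_density: float = MIN_PROMOTER_DENSITY,
) -> PausingRecord:
    """PI of one gene from a clamped Pol II track.

    Exclusion order: gene width, then promoter density, then body density.
    """
    if gene.chrom not in track.values:
        raise KeyError(f"gene {gene.gene_id}: chromosome {gene.chrom!r} not in track")
    if gene.width < min_width:
        return PausingRecord(gene.gene_id, None, None, None, "excluded_width")
    chrom_len = track.chrom_lengths[gene.chrom]
    prom_iv, _ = strand_window(
        gene, promoter_window[0], promoter_window[1], "TSS", chrom_len
    )
    body_iv, _ = strand_window(gene, promoter_window[1], gene.width, "TSS", chrom_len)
    d_prom = track.region_signal(prom_iv)
    d_body = track.region_signal(body_iv)
    if d_prom < min_promoter_density:
        return PausingRecord(gene.gene_id, d_prom, d_body, None, "excluded_low_promoter")
    if d_body <= 0:
        return PausingRecord(gene.gene_id, d_prom, d_body, None, "excluded_zero_body")
    return PausingRecord(gene.gene_id, d_prom, d_body, d_prom / d_body, "ok")


def pi_table(
    track: CoverageTrack,
    genes: Sequence[GeneAnnotation],
    **kwargs,
) -> list[PausingRecord]:
    """One :func:`compute_pi` record per gene, in input order."""
    records = [compute_pi(track, g, **kwargs) for g in genes]
    counts = pd.Series([r.status for r in records]).value_counts().to_dict()
    logger.info("pi_table: %d genes, status counts %s", len(records), counts)
    return records


def classify_paused(
    record: PausingRecord, threshold: float = PAUSED_THRESHOLD
) -> Literal["paused", "not_paused", "unclassified"]:
    """Paused iff PI > threshold; PI == threshold is called not paused;
    excluded records are unclassified."""
    if record.status != "ok":
        return "unclassified"
    return "paused" if record.pi > threshold else "not_paused"


def pi_quantile_bins(records: Sequence[PausingRecord], k: int = 5) -> dict[str, int]:
    """Rank genes by PI into k near-equal bins (0 = lowest PI).

    Only records with status 'ok' are binned; ties are broken by gene_id so
    the assignment is stable.  Bin sizes differ by at most one.
    """
    ok = [r for r in records if r.status == "ok"]
    if len(ok) < k:
        raise ValueError(f"need at least {k} scored records, got {len(ok)}")
    order = sorted(ok, key=lambda r: (r.pi, r.gene_id))
    labels: dict[str, int] = {}
    for b, chunk in enumerate(np.array_split(np.arange(len(order)), k)):
        for i in chunk:
            labels[order[int(i)].gene_id] = b
    return labels


def records_to_frame(records: Sequence[PausingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "d_prom": [r.d_prom for r in records],
            "d_body": [r.d_body for r in records],
            "PI": [r.pi for r in records],
            "status": [r.status for r in records],
            "class": [classify_paused(r) for r in records],
        }
    )
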
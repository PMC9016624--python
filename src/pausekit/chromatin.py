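"""Heterochromatin-type scoring and enhancer / super-enhancer geometry.

Heterochromatin domains are scored by the difference D = mean(H3K27me3) -
mean(H3K9me3) over the domain: D > 0 marks facultative-like (Polycomb)
heterochromatin, D <= 0 constitutive-like.  Both tracks are assumed to be
input-normalized on a common scale.

Enhancer calling follows the ROSE recipe: H3K27ac peaks overlapping any
TSS +- exclusion window are discarded as promoter signal, the survivors are
stitched when their gaps are at most 12.5 kb, and stitched regions are
ranked by total H3K27ac signal.  Super-enhancers are the regions above the
point where, after scaling ranks and signals to the unit square, the
signal-vs-rank curve has slope one (the tangent/elbow cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .intervals import (
    GeneAnnotation,
    GenomicInterval,
    Peak,
    PeakSet,
    overlap_pairs,
    tss_windows,
)

STITCH_DISTANCE = 12_500
TSS_EXCLUSION_ENHANCER = 2_000
TSS_EXCLUSION_SE = 2_500


@dataclass
class DomainScore:
    domain: GenomicInterval
    k27_mean: float
    k9_mean: float

    @property
    def difference(self) -> float:
        return self.k27_mean - self.k9_mean

    @property
    def het_class(self) -> str:
        return "facultative_like" if self.difference > 0 else "constitutive_like"


@dataclass
class StitchedEnhancer:
    interval: GenomicInterval
    n_constituents: int
    total_signal: float
    rank: int | None = None
    is_super: bool = False


def score_domains(
    k27_track: CoverageTrack,
    k9_track: CoverageTrack,
    domains: Sequence[GenomicInterval],
) -> list[DomainScore]:
    return [
        DomainScore(d, k27_track.region_signal(d), k9_track.region_signal(d))
        for d in domains
    ]


def domain_scores_frame(scores: Sequence[DomainScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.domain.chrom for s in scores],
            "start": [s.domain.start for s in scores],
            "end": [s.domain.end for s in scores],
            "k27_mean": [s.k27_mean for s in scores],
            "k9_mean": [s.k9_mean for s in scores],
            "difference": [s.difference for s in scores],
            "class": [s.het_class for s in scores],
        }
    )


def call_enhancer_seeds(
    h3k27ac_peaks: PeakSet,
    genes: Sequence[GeneAnnotation],
    tss_exclusion: int = TSS_EXCLUSION_ENHANCER,
) -> PeakSet:
    """Drop peaks overlapping any TSS +- tss_exclusion window; keep the rest
    sorted.  With no genes, all peaks are kept."""
    if not genes:
        return PeakSet(list(h3k27ac_peaks))
    windows = tss_windows(genes, tss_exclusion)
    hit = {i for i, _ in overlap_pairs(h3k27ac_peaks.intervals, windows)}
    return PeakSet([p for i, p in enumerate(h3k27ac_peaks) if i not in hit])


def stitch(seeds: PeakSet, stitch_distance: int = STITCH_DISTANCE) -> list[StitchedEnhancer]:
    """Transitively merge seeds whose half-open gap is <= stitch_distance.

    The total signal of a stitched region is the sum of its constituents'
    scores (unscored seeds contribute their width).  Output regions on the
    same chromosome are pairwise separated by more than stitch_distance.
    """
    out: list[StitchedEnhancer] = []
    current: list[Peak] = []

    def flush() -> None:
        if not current:
            return
        iv = GenomicInterval(
            current[0].interval.chrom,
            current[0].interval.start,
            max(p.interval.end for p in current),
        )
        signal = sum(
            p.score if p.score is not None else float(p.interval.width) for p in current
        )
        out.append(StitchedEnhancer(iv, len(current), float(signal)))

    for peak in seeds:  # PeakSet is sorted by (chrom, start)
        if current and (
            peak.interval.chrom != current[0].interval.chrom
            or peak.interval.start - max(p.interval.end for p in current) > stitch_distance
        ):
            flush()
            current = []
        current.append(peak)
    flush()
    return out


def rose_cutoff(signals: np.ndarray) -> tuple[float, int]:
    """ROSE elbow on a signal vector: scale ascending ranks and signals to
    [0, 1] and take the point minimizing y - x (where the unit-slope line is
    tangent to the curve from below).

    Returns (cutoff signal value, tangent index into the ascending sort).
    Degenerate all-equal vectors return the maximum (nothing exceeds it).
    """
    s = np.sort(np.asarray(signals, dtype=float))
    n = s.size
    if n < 3:
        raise ValueError("super-enhancer cutoff undefined for fewer than 3 regions")
    lo, hi = s[0], s[-1]
    if hi == lo:
        return float(hi), n - 1
    x = np.arange(1, n + 1) / n
    y = (s - lo) / (hi - lo)
    idx = int(np.argmin(y - x))
    return float(s[idx]), idx


def call_super_enhancers(stitched: Sequence[StitchedEnhancer]) -> list[StitchedEnhancer]:
    """Rank stitched enhancers by total signal and flag those above the ROSE
    tangent cutoff as super-enhancers.  Returns new records sorted by
    descending signal with ``rank`` (1 = strongest) and ``is_super`` set."""
    if len(stitched) < 3:
        raise ValueError("super-enhancer cutoff undefined for fewer than 3 regions")
    signals = np.array([e.total_signal for e in stitched])
    cutoff, _ = rose_cutoff(signals)
    order = sorted(
        range(len(stitched)),
        key=lambda i: (-signals[i], stitched[i].interval.chrom, stitched[i].interval.start),
    )
    out = []
    for rank, i in enumerate(order, start=1):
        e = stitched[i]
        out.append(
            StitchedEnhancer(
                e.interval, e.n_constituents, e.total_signal, rank, bool(signals[i] > cutoff)
            )
        )
    return out


def stitched_frame(stitched: Sequence[StitchedEnhancer]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [e.interval.chrom for e in stitched],
            "start": [e.interval.start for e in stitched],
            "end": [e.interval.end for e in stitched],
            "n_constituents": [e.n_constituents for e in stitched],
            "total_signal": [e.total_signal for e in stitched],
            "rank": [e.rank for e in stitched],
            "is_super": [e.is_super for e in stitched],
        }
    )
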
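"""Fisher-exact enrichment machinery.

Each enrichment question is a 2x2 contingency table over a finite universe
of genes (or peaks): a = |A and B|, b = |A minus B|, c = |B minus A|,
d = |universe minus (A union B)|.  The association score is the log2 odds
ratio LOR = log2(ad / bc); significance is the two-sided Fisher exact
p-value, annotated with star bands (* <=0.05, ** <=0.01, *** <=0.001,
**** <=0.0001).  Raw p-values are reported without a multiplicity layer,
matching the star-band convention of enrichment heatmaps.

Zero-cell tables get a Haldane-Anscombe display correction (+0.5 to every
cell) for the odds ratio only; the exact p-value is untouched and the
correction is flagged on the cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import fisher_exact

STAR_BANDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def p_to_stars(p: float) -> str:
    for cut, stars in STAR_BANDS:
        if p <= cut:
            return stars
    return "ns"


@dataclass
class EnrichmentCell:
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    log2_odds_ratio: float
    p_value: float
    haldane_corrected: bool = False

    @property
    def stars(self) -> str:
        return p_to_stars(self.p_value)


def fisher_cell(a: int, b: int, c: int, d: int) -> EnrichmentCell:
    """Exact test of one 2x2 table (two-sided), with closed-form OR = ad/bc."""
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("empty universe")
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = 0 in (a, b, c, d)
    if corrected:
        orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return EnrichmentCell(a, b, c, d, orr, math.log2(orr), float(p), corrected)


def fisher_enrichment(
    set_a: Iterable[Hashable],
    set_b: Iterable[Hashable],
    universe: Iterable[Hashable],
) -> EnrichmentCell:
    """Enrichment of set_a against set_b within a universe.

    Both sets must be subsets of the universe.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    sa, sb = set(set_a), set(set_b)
    if not sa <= uni or not sb <= uni:
        raise ValueError("set_a and set_b must be subsets of the universe")
    a = len(sa & sb)
    b = len(sa - sb)
    c = len(sb - sa)
    d = len(uni) - a - b - c
    return fisher_cell(a, b, c, d)


def enrichment_heatmap(
    gene_groups: Mapping[str, Iterable[Hashable]],
    bin_assignment: Mapping[Hashable, Hashable],
) -> pd.DataFrame:
    """One Fisher test per (group, bin) over the binned universe.

    ``bin_assignment`` maps every universe member to exactly one bin (e.g. a
    PI quintile); each group must be a subset of the binned universe.
    Returns a long-format table with counts, OR, LOR, p and stars.
    """
    universe = set(bin_assignment)
    bins = sorted(set(bin_assignment.values()), key=str)
    rows = []
    for group_name, members in gene_groups.items():
        members = set(members)
        if not members <= universe:
            raise ValueError(
                f"group {group_name!r} contains genes outside the binned universe"
            )
        for b in bins:
            in_bin = {g for g, lab in bin_assignment.items() if lab == b}
            cell = fisher_enrichment(members, in_bin, universe)
            rows.append(
                {
                    "group": group_name,
                    "bin": b,
                    "a": cell.a,
                    "b": cell.b,
                    "c": cell.c,
                    "d": cell.d,
                    "odds_ratio": cell.odds_ratio,
                    "LOR": cell.log2_odds_ratio,
                    "p_value": cell.p_value,
                    "stars": cell.stars,
                }
            )
    return pd.DataFrame(rows)


def overlap_percentage(
    overlap_counts: Sequence[int], total: int
) -> tuple[list[float], float, int]:
    """Combined overlap percentage from per-set overlap counts.

    Returns (per-set unrounded percentages, combined unrounded percentage,
    combined percentage rounded to the nearest integer).  E.g. overlaps of
    64 and 18 target genes out of 945 give 8.68% unrounded, 9% rounded.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    per_set = [100.0 * c / total for c in overlap_counts]
    combined = 100.0 * sum(overlap_counts) / total
    return per_set, combined, round(combined)


def overlap_percentage_sets(
    target_sets: Mapping[str, Iterable[Hashable]],
    annotation_set: Iterable[Hashable],
    total: int,
) -> tuple[dict[str, float], float, int]:
    """Set-based variant: overlap of each target set with an annotation set."""
    ann = set(annotation_set)
    counts = {name: len(set(s) & ann) for name, s in target_sets.items()}
    per_set, combined, rounded = overlap_percentage(list(counts.values()), total)
    return dict(zip(counts, per_set)), combined, rounded
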
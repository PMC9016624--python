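"""FPKM, rank-based expression tiers and differential-expression filtering.

FPKM follows the standard per-gene normalization

    FPKM_g = RC_g * 1e6 / (RC_p * L_g)

with RC_g the reads mapped to gene g, RC_p the total reads mapped over the
provided (protein-coding) gene set, and L_g the gene length in bp.

Genes are split by FPKM rank into four (near-)equal tiers, silent -> low ->
medium -> high, mirroring the quartile categorization used for expression-
stratified analyses.

Differential-expression fitting itself is consumed, not performed: the
filter takes a statistics table (fold change + adjusted p) and applies the
strict cutoffs |FC| > 1.5 and Padj < 0.1.  Fold changes are interpreted on
the linear ratio scale by default (down = ratio < 1/1.5); a log2 dialect is
available via ``log2=True``.  Genes down upon knockdown form the activated
set (AG: the factor promoted their expression), genes up form the repressed
set (RG).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TIER_NAMES = ("silent", "low", "medium", "high")
FC_CUTOFF = 1.5
PADJ_CUTOFF = 0.1


def compute_fpkm(counts: pd.DataFrame) -> pd.DataFrame:
    """Add an ``fpkm`` column to a table with gene_id / count / length.

    Raises on zero total counts or non-positive lengths.
    """
    for col in ("gene_id", "count", "length"):
        if col not in counts.columns:
            raise ValueError(f"counts table missing column {col!r}")
    total = float(counts["count"].sum())
    if total <= 0:
        raise ValueError("total read count over provided genes is zero")
    if (counts["length"] <= 0).any():
        raise ValueError("gene lengths must be positive")
    out = counts.copy()
    out["fpkm"] = counts["count"] * 1e6 / (total * counts["length"])
    return out


def expression_tiers(fpkm_table: pd.DataFrame, k: int = 4) -> pd.Series:
    """Rank-based k-tile tier per gene, sizes differing by at most 1.

    Ties in FPKM are broken by gene_id, so the split is deterministic even
    when many genes are exactly silent.  Returns a Series of tier labels
    indexed by gene_id (k=4 uses silent/low/medium/high).
    """
    if "fpkm" not in fpkm_table.columns:
        raise ValueError("table missing 'fpkm' column (run compute_fpkm first)")
    if len(fpkm_table) < k:
        raise ValueError(f"need at least {k} genes for {k} tiers")
    ordered = fpkm_table.sort_values(
        ["fpkm", "gene_id"], kind="mergesort"
    )["gene_id"].to_numpy()
    names = TIER_NAMES if k == 4 else tuple(f"tier_{i}" for i in range(k))
    labels = np.empty(len(ordered), dtype=object)
    for b, chunk in enumerate(np.array_split(np.arange(len(ordered)), k)):
        labels[chunk] = names[b]
    return pd.Series(labels, index=pd.Index(ordered, name="gene_id"), name="tier")


def filter_de(
    de_table: pd.DataFrame,
    fc_cut: float = FC_CUTOFF,
    padj_cut: float = PADJ_CUTOFF,
    log2: bool = False,
) -> tuple[set[str], set[str]]:
    """Split a DE statistics table into (activated, repressed) gene sets.

    Kept iff |FC| > fc_cut AND padj < padj_cut, both strict.  ``log2=True``
    reads ``fold_change`` as log2 ratios.  Activated genes (AG) are the ones
    DOWN in the knockdown; repressed genes (RG) are UP.
    """
    for col in ("gene_id", "fold_change", "adjusted_p"):
        if col not in de_table.columns:
            raise ValueError(f"DE table missing column {col!r}")
    fc = de_table["fold_change"].astype(float)
    if log2:
        magnitude = np.exp2(np.abs(fc))
        down = fc < 0
    else:
        if (fc <= 0).any():
            raise ValueError("ratio-scale fold changes must be positive")
        magnitude = np.maximum(fc, 1.0 / fc)
        down = fc < 1.0
    keep = (magnitude > fc_cut) & (de_table["adjusted_p"].astype(float) < padj_cut)
    activated = set(de_table.loc[keep & down, "gene_id"])
    repressed = set(de_table.loc[keep & ~down, "gene_id"])
    return activated, repressed
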
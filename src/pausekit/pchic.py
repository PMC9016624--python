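"""Promoter-capture Hi-C post-processing.

Takes called bait / other-end interaction tables with raw read counts for
two biological replicates and applies the downstream steps: keep
interactions with more than 5 reads in each replicate and bait-to-other-end
distance (midpoint to midpoint) below 1.5 Mb, quantile-normalize the
replicate count columns, average replicates into one intensity per
interaction, and summarize per bait gene (number of interactions and mean
intensity).  Condition comparisons use paired Wilcoxon signed-rank tests on
matched baits across conditions and unpaired Mann-Whitney tests between
gene categories within a condition.

When two conditions are compared, normalization is applied jointly across
all four replicate columns so the conditions share one scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata, wilcoxon

MIN_READS = 5
MAX_DISTANCE = 1_500_000


def interaction_distance(df: pd.DataFrame) -> pd.Series:
    """Midpoint-to-midpoint bait / other-end distance in bp."""
    bait_mid = 0.5 * (df["bait_start"] + df["bait_end"])
    oe_mid = 0.5 * (df["oe_start"] + df["oe_end"])
    return (bait_mid - oe_mid).abs()


def filter_interactions(
    records: pd.DataFrame,
    min_reads: int = MIN_READS,
    max_distance: float = MAX_DISTANCE,
) -> pd.DataFrame:
    """Keep records with count > min_reads in BOTH replicates and distance
    < max_distance, all strict."""
    dist = interaction_distance(records)
    keep = (
        (records["count_rep1"] > min_reads)
        & (records["count_rep2"] > min_reads)
        & (dist < max_distance)
    )
    out = records.loc[keep].copy()
    out["distance"] = dist[keep]
    return out.reset_index(drop=True)


def quantile_normalize(columns: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Quantile normalization of equal-length columns (limma
    normalizeBetweenArrays style).

    Each column's sorted values are replaced by the across-column mean of
    sorted values; tied entries within a column receive the average of the
    reference values at their tied ranks.  Afterwards all columns share one
    distribution (exactly so in the absence of ties).
    """
    x = np.asarray(columns, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D array of columns")
    n, m = x.shape
    if m < 2:
        raise ValueError("need at least 2 columns to normalize")
    if n == 0:
        return x.copy()
    reference = np.sort(x, axis=0).mean(axis=1)
    ref_cumsum = np.concatenate(([0.0], np.cumsum(reference)))
    out = np.empty_like(x)
    for j in range(m):
        # a tie spanning ranks [rmin, rmax] receives the mean of the
        # reference values over that whole span
        rmin = rankdata(x[:, j], method="min").astype(int)
        rmax = rankdata(x[:, j], method="max").astype(int)
        out[:, j] = (ref_cumsum[rmax] - ref_cumsum[rmin - 1]) / (rmax - rmin + 1)
    return out


def add_intensity(
    records: pd.DataFrame, extra_count_columns: tuple[str, ...] = ()
) -> pd.DataFrame:
    """Quantile-normalize the replicate count columns and add per-record
    ``intensity`` = mean of the two normalized replicates.

    ``extra_count_columns`` lets a second condition's replicates join the
    normalization so both conditions end up on a common scale; intensity is
    always the mean of count_rep1/count_rep2 after normalization.
    """
    cols = ("count_rep1", "count_rep2", *extra_count_columns)
    normed = quantile_normalize(records[list(cols)].to_numpy())
    out = records.copy()
    for j, c in enumerate(cols):
        out[f"norm_{c}"] = normed[:, j]
    out["intensity"] = 0.5 * (out["norm_count_rep1"] + out["norm_count_rep2"])
    return out


@dataclass
class GeneInteractionSummary:
    gene_id: str
    n_interactions: int
    mean_intensity: float | None
    condition: str = ""


def summarize_per_gene(
    records: pd.DataFrame,
    all_baits: list[str] | None = None,
    condition: str = "",
) -> pd.DataFrame:
    """Per-bait interaction count and mean intensity.

    Requires an ``intensity`` column (see :func:`add_intensity`).  Baits in
    ``all_baits`` with no surviving interaction get n_interactions = 0 and a
    missing intensity.
    """
    if "intensity" not in records.columns:
        raise ValueError("records lack 'intensity'; run add_intensity first")
    grouped = records.groupby("bait_id", sort=True).agg(
        n_interactions=("intensity", "size"), mean_intensity=("intensity", "mean")
    )
    if all_baits is not None:
        grouped = grouped.reindex(sorted(all_baits))
        grouped["n_interactions"] = grouped["n_interactions"].fillna(0).astype(int)
    out = grouped.reset_index().rename(columns={"index": "bait_id"})
    out["condition"] = condition
    return out


def _paired_p(x: np.ndarray, y: np.ndarray) -> float:
    diff = x - y
    if np.all(diff == 0):
        return 1.0  # no signed ranks: identical paired samples
    return float(wilcoxon(x, y).pvalue)


def compare_conditions(
    summary_ctrl: pd.DataFrame,
    summary_kd: pd.DataFrame,
    group_labels: dict[str, str],
) -> pd.DataFrame:
    """Paired (across conditions) and unpaired (between groups) rank tests.

    For each gene group: a paired Wilcoxon test on matched baits compares
    control vs knockdown for interaction count and intensity; Mann-Whitney
    tests compare this group against every other group within the control
    condition.  Groups with fewer than 2 matched baits are refused.

    Returns a long table of comparisons with medians, means and p-values.
    """
    merged = summary_ctrl.merge(
        summary_kd, on="bait_id", suffixes=("_ctrl", "_kd"), how="inner"
    )
    if merged.empty:
        raise ValueError("no matched baits between conditions for the paired test")
    merged["group"] = merged["bait_id"].map(group_labels)
    merged = merged.dropna(subset=["group"])
    groups = sorted(merged["group"].unique())
    rows = []
    for g in groups:
        sub = merged[merged["group"] == g]
        for metric in ("n_interactions", "mean_intensity"):
            x = sub[f"{metric}_ctrl"].dropna().to_numpy(dtype=float)
            pair = sub[[f"{metric}_ctrl", f"{metric}_kd"]].dropna()
            if len(pair) < 2:
                raise ValueError(
                    f"group {g!r}: need >= 2 matched baits for the paired test, "
                    f"got {len(pair)}"
                )
            p_paired = _paired_p(
                pair[f"{metric}_ctrl"].to_numpy(dtype=float),
                pair[f"{metric}_kd"].to_numpy(dtype=float),
            )
            rows.append(
                {
                    "group": g,
                    "metric": metric,
                    "comparison": "ctrl_vs_kd",
                    "other": "",
                    "median": float(np.median(x)),
                    "mean": float(np.mean(x)),
                    "p_value": p_paired,
                }
            )
        for other in groups:
            if other <= g:
                continue
            for metric in ("n_interactions", "mean_intensity"):
                x = merged.loc[merged["group"] == g, f"{metric}_ctrl"].dropna()
                y = merged.loc[merged["group"] == other, f"{metric}_ctrl"].dropna()
                if len(x) < 2 or len(y) < 2:
                    raise ValueError(
                        f"unpaired test {g!r} vs {other!r} refused: a group has "
                        "fewer than 2 baits"
                    )
                p = float(mannwhitneyu(x, y, alternative="two-sided").pvalue)
                rows.append(
                    {
                        "group": g,
                        "metric": metric,
                        "comparison": "between_groups",
                        "other": other,
                        "median": float(x.median()),
                        "mean": float(x.mean()),
                        "p_value": p,
                    }
                )
    return pd.DataFrame(rows)
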
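"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most literal route available
(per-bp expansion, all-pairs scans, exhaustive enumeration) and is kept
free of the implementation code paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def per_bp_signal(values: np.ndarray, bin_size: int, start: int, end: int) -> float:
    """Mean per-bp signal by expanding bins to base-pair resolution."""
    per_bp = np.repeat(values, bin_size)
    return float(per_bp[start:end].mean())


def per_bp_pi(
    values: np.ndarray,
    bin_size: int,
    start: int,
    end: int,
    strand: str,
) -> float:
    """Pausing index via literal per-bp densities on a clamped track.

    Promoter = oriented (-30, +300) around the TSS; body = +300 bp to the
    TES.  Mirrors the half-open window arithmetic by explicit base lists.
    Only the gene's neighbourhood is expanded to base pairs.
    """
    pad_bins = 400 // bin_size + 1
    first = max(start // bin_size - pad_bins, 0)
    last = (end - 1) // bin_size + pad_bins + 1
    offset = first * bin_size
    per_bp_local = np.repeat(np.maximum(values[first:last], 0.0), bin_size)

    class _Shifted:
        def __getitem__(self, sl):
            return per_bp_local[sl.start - offset : sl.stop - offset]

    per_bp = _Shifted()
    if strand == "+":
        tss = start
        prom = per_bp[tss - 30 : tss + 300]
        body = per_bp[tss + 300 : end]
    else:
        tss = end - 1
        prom = per_bp[tss - 300 + 1 : tss + 30 + 1]
        body = per_bp[start : tss - 300 + 1]
    return float(prom.mean() / body.mean())


def quadratic_overlap_pairs(set_a, set_b, min_overlap: int = 1):
    """All-pairs O(n*m) overlap scan over (chrom, start, end) triples."""
    pairs = []
    for i, (ca, sa, ea) in enumerate(set_a):
        for j, (cb, sb, eb) in enumerate(set_b):
            if ca == cb and min(ea, eb) - max(sa, sb) >= min_overlap:
                pairs.append((i, j))
    return sorted(pairs)


def fisher_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exhaustive fixed-margin enumeration.

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed table's
    (standard two-sided convention, with the customary 1 + 1e-7 relative
    slack on the tie comparison).
    """
    n = a + b + c + d
    row = a + b
    col = a + c

    def log_p(x: int) -> float:
        # P(X = x) for X ~ Hypergeom(n, col, row)
        return (
            math.lgamma(col + 1) - math.lgamma(x + 1) - math.lgamma(col - x + 1)
            + math.lgamma(n - col + 1) - math.lgamma(row - x + 1)
            - math.lgamma(n - col - row + x + 1)
            - (math.lgamma(n + 1) - math.lgamma(row + 1) - math.lgamma(n - row + 1))
        )

    lo, hi = max(0, row + col - n), min(row, col)
    p_obs = math.exp(log_p(a))
    total = 0.0
    for x in range(lo, hi + 1):
        px = math.exp(log_p(x))
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)


def rank_average_quantile_norm(columns: np.ndarray) -> np.ndarray:
    """Reference quantile normalization via explicit tie-group averaging."""
    x = np.asarray(columns, dtype=float)
    n, m = x.shape
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(m):
        order = np.argsort(x[:, j], kind="mergesort")
        col = x[order, j]
        assigned = np.empty(n)
        i = 0
        while i < n:
            k = i
            while k + 1 < n and col[k + 1] == col[i]:
                k += 1
            assigned[i : k + 1] = reference[i : k + 1].mean()
            i = k + 1
        out[order, j] = assigned
    return out


def rose_tangent_flags(signals: np.ndarray) -> np.ndarray:
    """Super-enhancer flags by exhaustive tangent scan on the unit square.

    For every candidate point of the ascending rank curve, consider the
    unit-slope line through it; the tangent-from-below line is the one no
    point falls under.  Signals strictly above the tangent point's signal
    are flagged.  All-equal vectors flag nothing.
    """
    s = np.sort(np.asarray(signals, dtype=float))
    n = s.size
    if s[0] == s[-1]:
        return np.zeros_like(np.asarray(signals), dtype=bool)
    x = np.arange(1, n + 1) / n
    y = (s - s[0]) / (s[-1] - s[0])
    best = None
    for i in range(n):
        b = y[i] - x[i]
        if np.all(y - x >= b - 1e-12):  # no point below the line through i
            if best is None or b < y[best] - x[best] or (
                b == y[best] - x[best] and i < best
            ):
                best = i
    cutoff = s[best]
    return np.asarray(signals, dtype=float) > cutoff
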
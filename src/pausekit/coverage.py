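"""Fixed-bin coverage tracks: the in-memory surrogate of a binned bigWig.

A :class:`CoverageTrack` stores one real-valued vector per chromosome, with a
single bin size (50 bp by default, matching input-subtracted RPKM tracks
binned at 50 bp).  Bin ``i`` covers base pairs ``[i * bin_size,
(i + 1) * bin_size)``; the last bin of a chromosome may be truncated by the
chromosome end, and its value still refers to mean-per-bp signal over the
bases it covers.

Signal over an arbitrary interval is the overlap-weighted mean per base pair:
partial bins contribute proportionally to the number of bases overlapped.
Input-subtracted tracks can be negative; :meth:`CoverageTrack.clamp_negative`
zeroes negative bins before ratio statistics such as the pausing index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval


@dataclass
class CoverageTrack:
    bin_size: int
    chrom_lengths: dict[str, int]
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, length in self.chrom_lengths.items():
            n_bins = math.ceil(length / self.bin_size)
            if chrom not in self.values:
                self.values[chrom] = np.zeros(n_bins, dtype=float)
            else:
                v = np.asarray(self.values[chrom], dtype=float)
                if v.shape != (n_bins,):
                    raise ValueError(
                        f"{chrom}: expected {n_bins} bins for length "
                        f"{length} at bin_size {self.bin_size}, got {v.shape}"
                    )
                if not np.all(np.isfinite(v)):
                    raise ValueError(f"{chrom}: track values must be finite")
                self.values[chrom] = v

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    def region_signal(self, interval: GenomicInterval) -> float:
        """Mean per-bp signal over ``interval``.

        Computed as ``sum(bin value * overlapped bp) / interval width`` so
        that partial bins are pro-rated by the bases they contribute.
        """
        chrom = interval.chrom
        if chrom not in self.values:
            raise KeyError(f"chromosome {chrom!r} not in track")
        if interval.end > self.chrom_lengths[chrom]:
            raise ValueError(
                f"interval [{interval.start}, {interval.end}) exceeds "
                f"{chrom} length {self.chrom_lengths[chrom]}"
            )
        bs = self.bin_size
        v = self.values[chrom]
        first = interval.start // bs
        last = (interval.end - 1) // bs
        idx = np.arange(first, last + 1)
        bin_starts = idx * bs
        bin_ends = bin_starts + bs
        overlap = np.minimum(bin_ends, interval.end) - np.maximum(bin_starts, interval.start)
        return float(np.dot(v[first : last + 1], overlap) / interval.width)

    def clamp_negative(self) -> "CoverageTrack":
        """Bin-wise ``max(value, 0)``; shape unchanged, input untouched."""
        return CoverageTrack(
            bin_size=self.bin_size,
            chrom_lengths=dict(self.chrom_lengths),
            values={c: np.maximum(v, 0.0) for c, v in self.values.items()},
        )

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            bin_size=self.bin_size,
            chrom_lengths=dict(self.chrom_lengths),
            values={c: v * factor for c, v in self.values.items()},
        )

    def copy(self) -> "CoverageTrack":
        return self.scaled(1.0)
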
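"""Seeded synthetic data with the statistical structure the pipeline assumes.

The generator emits a toy single-chromosome genome together with coverage
tracks, expression counts, H3K27ac enhancer peaks and two-replicate
promoter-capture interaction tables.  It encodes the contrasts the analysis
is designed to detect:

* Pol II tracks with a controllable promoter-proximal / gene-body density
  ratio (``pause_ratio_paused`` vs ``pause_ratio_elongating``);
* histone-variant occupancy that is TSS-confined for activated genes and
  covers promoter plus gene body for repressed genes;
* anti-correlated H3K27me3 / H3K9me3 domain mixtures (facultative-like vs
  constitutive-like heterochromatin);
* H3K27ac peak clusters in intergenic space, some of which stitch into
  super-enhancer-sized domains;
* negative-binomial expression counts in four abundance tiers;
* distance-decaying two-replicate contact counts in which activated-gene
  baits receive more but weaker interactions than repressed-gene baits.

Determinism: one integer seed expands via ``numpy.random.SeedSequence`` into
independent substreams (0 = genome, 1 = tracks, 2 = expression, 3 =
contacts; each track kind and each PCHiC condition has its own child), so
regenerating one component never perturbs another.  Within a stream, draws
happen in the documented order of the code.  Gene coordinates sit on the bin
grid so that, at zero noise, promoter/body density ratios are exact by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .intervals import GeneAnnotation, GenomicInterval, Peak, PeakSet

TRACK_KINDS = ("PolII", "mH2A1.1", "H3K27ac", "H3K27me3", "H3K9me3")
_TRACK_INDEX = {k: i for i, k in enumerate(TRACK_KINDS)}
_CONDITION_INDEX = {"ctrl": 0, "kd": 1}


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome.

    Defaults mirror the contrasts the analysis targets: about two thirds of
    transcribed genes paused (promoter/body density ratio 5 vs 1), a
    deregulated-gene compartment split ~56:44 between activated (AG) and
    repressed (RG) genes, four expression tiers spanning silent to high, and
    AG baits with twice as many but half as intense contacts as RG baits.
    """

    n_genes: int = 1000
    chrom_name: str = "chrSim"
    chrom_length: int = 20_000_000
    bin_size: int = 50

    fraction_paused: float = 0.68
    pause_ratio_paused: float = 5.0
    pause_ratio_elongating: float = 1.0
    polii_body_mean: float = 2.0
    noise_frac: float = 0.2  # Gaussian bin noise, s.d. as fraction of base signal

    fraction_ag: float = 0.15
    fraction_rg: float = 0.12
    binding_mode_ag: Literal["tss_confined", "promoter_plus_body"] = "tss_confined"
    binding_mode_rg: Literal["tss_confined", "promoter_plus_body"] = "promoter_plus_body"
    mh2a_amplitude: float = 3.0
    mh2a_bump_sd: float = 200.0  # bp

    het_mean_high: float = 3.0
    het_mean_low: float = 0.5

    enhancer_gap_prob: float = 0.35
    h3k27ac_lognorm_mu: float = 0.5
    h3k27ac_lognorm_sigma: float = 1.0

    tier_means: tuple[float, float, float, float] = (0.0, 2.0, 20.0, 200.0)
    nb_dispersion: float = 0.1

    contact_decay: float = 0.3
    contact_mean_ag: float = 8.0
    contact_mean_rg: float = 4.0
    contact_mean_neutral: float = 5.0
    contact_intensity_ag: float = 15.0
    contact_intensity_rg: float = 30.0
    contact_intensity_neutral: float = 22.0
    contact_dispersion: float = 0.1
    contact_min_distance: int = 20_000
    contact_max_distance: int = 2_000_000

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.chrom_length <= 0 or self.bin_size <= 0:
            raise ValueError("n_genes, chrom_length and bin_size must be positive")
        if not 0.0 <= self.fraction_paused <= 1.0:
            raise ValueError("fraction_paused must lie in [0, 1]")
        if self.fraction_ag < 0 or self.fraction_rg < 0 or (
            self.fraction_ag + self.fraction_rg > 1.0
        ):
            raise ValueError("fraction_ag/fraction_rg must be a sub-probability pair")
        if min(self.pause_ratio_paused, self.pause_ratio_elongating) <= 0:
            raise ValueError("pause ratios must be positive")
        if list(self.tier_means) != sorted(self.tier_means) or len(
            set(self.tier_means)
        ) != 4:
            raise ValueError("tier_means must be 4 strictly increasing values")
        if self.noise_frac < 0 or self.nb_dispersion < 0 or self.contact_dispersion < 0:
            raise ValueError("noise and dispersion parameters must be non-negative")
        if not 0 < self.contact_min_distance < self.contact_max_distance:
            raise ValueError("contact distance range must be increasing and positive")

    # -- substreams ---------------------------------------------------------
    def _root(self) -> np.random.SeedSequence:
        return np.random.SeedSequence(self.seed)

    def rng_genome(self) -> np.random.Generator:
        return np.random.default_rng(self._root().spawn(4)[0])

    def rng_track(self, kind: str) -> np.random.Generator:
        children = self._root().spawn(4)[1].spawn(len(TRACK_KINDS))
        return np.random.default_rng(children[_TRACK_INDEX[kind]])

    def rng_expression(self) -> np.random.Generator:
        return np.random.default_rng(self._root().spawn(4)[2])

    def rng_contacts(self, condition: str) -> np.random.Generator:
        children = self._root().spawn(4)[3].spawn(len(_CONDITION_INDEX))
        return np.random.default_rng(children[_CONDITION_INDEX[condition]])


@dataclass
class SimTruth:
    """Ground truth for parameter-recovery tests.

    ``genes``: one row per gene (gene_id, paused flag, regulation class in
    {AG, RG, neutral}, expression tier index).  ``domains``: the
    heterochromatin domain partition with its facultative/constitutive type.
    ``enhancers``: planted H3K27ac peaks with cluster ids and amplitudes.
    """

    genes: pd.DataFrame
    domains: pd.DataFrame = field(default_factory=pd.DataFrame)
    enhancers: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_genome(config: SimConfig) -> tuple[list[GeneAnnotation], SimTruth]:
    """Place non-overlapping, alternating-strand genes on the toy chromosome.

    Widths are 2-10 kb and intergenic gaps 2-8 kb, both multiples of the bin
    size so promoter/body windows align to the coverage grid.  Raises if the
    genes cannot fit the chromosome.
    """
    rng = config.rng_genome()
    n = config.n_genes
    bs = config.bin_size
    widths = rng.integers(2000 // bs, 10000 // bs + 1, size=n) * bs
    gaps = rng.integers(2000 // bs, 8000 // bs + 1, size=n + 1) * bs
    total = int(widths.sum() + gaps.sum())
    if total > config.chrom_length:
        raise ValueError(
            f"{n} genes need {total} bp but chromosome is {config.chrom_length} bp"
        )
    starts = np.cumsum(gaps[:-1]) + np.concatenate(([0], np.cumsum(widths[:-1])))
    strands = np.where(np.arange(n) % 2 == 0, "+", "-")

    paused = rng.random(n) < config.fraction_paused
    u = rng.random(n)
    reg_class = np.where(
        u < config.fraction_ag,
        "AG",
        np.where(u < config.fraction_ag + config.fraction_rg, "RG", "neutral"),
    )
    tier = rng.integers(0, 4, size=n)

    genes = [
        GeneAnnotation(
            f"gene{i:05d}",
            GenomicInterval(config.chrom_name, int(s), int(s + w)),
            str(strands[i]),
        )
        for i, (s, w) in enumerate(zip(starts, widths))
    ]
    genes_df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": config.chrom_name,
            "start": starts.astype(int),
            "end": (starts + widths).astype(int),
            "strand": strands,
            "paused": paused,
            "reg_class": reg_class,
            "tier": tier,
        }
    )

    # heterochromatin domain partition: 20-100 kb blocks, alternating type
    edges = [0]
    while edges[-1] < config.chrom_length:
        edges.append(
            edges[-1] + int(rng.integers(20_000 // bs, 100_000 // bs + 1)) * bs
        )
    edges[-1] = config.chrom_length
    dom_type = ["facultative" if i % 2 == 0 else "constitutive" for i in range(len(edges) - 1)]
    domains_df = pd.DataFrame(
        {
            "chrom": config.chrom_name,
            "start": edges[:-1],
            "end": edges[1:],
            "type": dom_type,
        }
    )

    # enhancer clusters planted in the middle of a subset of intergenic gaps
    enh_rows = []
    cluster_id = 0
    gap_starts = np.concatenate(([0], (starts + widths)))
    gap_ends = np.concatenate((starts, [total]))
    for gs, ge in zip(gap_starts, gap_ends):
        if ge - gs < 4000 or rng.random() >= config.enhancer_gap_prob:
            continue
        n_peaks = int(rng.integers(1, 5))
        amp = float(rng.lognormal(config.h3k27ac_lognorm_mu, config.h3k27ac_lognorm_sigma))
        lo, hi = gs + 1000, ge - 1000
        for _ in range(n_peaks):
            w = int(rng.integers(500 // bs, 1500 // bs + 1)) * bs
            if hi - lo <= w // bs:
                continue
            s = int(rng.integers(lo // bs, (hi - w) // bs + 1)) * bs
            enh_rows.append(
                {
                    "chrom": config.chrom_name,
                    "start": s,
                    "end": s + w,
                    "cluster_id": cluster_id,
                    "amplitude": amp,
                }
            )
        cluster_id += 1
    enhancers_df = pd.DataFrame(
        enh_rows, columns=["chrom", "start", "end", "cluster_id", "amplitude"]
    )
    return genes, SimTruth(genes=genes_df, domains=domains_df, enhancers=enhancers_df)


def _empty_track(config: SimConfig) -> CoverageTrack:
    return CoverageTrack(
        bin_size=config.bin_size,
        chrom_lengths={config.chrom_name: config.chrom_length},
    )


def _promoter_body_regions(row: pd.Series) -> tuple[tuple[int, int], tuple[int, int]]:
    """Signal regions (bp) enclosing the oriented (-30, +300) promoter window
    and the +300..TES body, padded to the 50-bp grid."""
    if row.strand == "+":
        prom = (row.start - 50, row.start + 300)
        body = (row.start + 300, row.end)
    else:
        prom = (row.end - 300, row.end + 50)
        body = (row.start, row.end - 300)
    return prom, body


def simulate_track(
    genes: list[GeneAnnotation],
    truth: SimTruth,
    config: SimConfig,
    kind: str,
) -> CoverageTrack:
    """Synthesize one input-normalized coverage track.

    Gaussian i.i.d. noise is added per bin; like input-subtracted real
    tracks, values may go negative (downstream ratio statistics are expected
    to clamp first).
    """
    if kind not in TRACK_KINDS:
        raise ValueError(f"unknown track kind {kind!r}; expected one of {TRACK_KINDS}")
    rng = config.rng_track(kind)
    track = _empty_track(config)
    v = track.values[config.chrom_name]
    bs = config.bin_size
    centers = (np.arange(v.size) + 0.5) * bs

    def fill(lo: int, hi: int, value: float) -> None:
        v[max(lo, 0) // bs : min(hi, config.chrom_length) // bs] = value

    base_amp = {
        "PolII": config.polii_body_mean,
        "mH2A1.1": config.mh2a_amplitude,
        "H3K27ac": 1.0,
        "H3K27me3": config.het_mean_high,
        "H3K9me3": config.het_mean_high,
    }[kind]

    if kind == "PolII":
        m = config.polii_body_mean
        for row in truth.genes.itertuples():
            ratio = (
                config.pause_ratio_paused if row.paused else config.pause_ratio_elongating
            )
            prom, body = _promoter_body_regions(row)
            fill(*body, m)
            fill(*prom, ratio * m)
    elif kind == "mH2A1.1":
        for row in truth.genes.itertuples():
            tss = row.start if row.strand == "+" else row.end - 1
            mode = {
                "AG": config.binding_mode_ag,
                "RG": config.binding_mode_rg,
                "neutral": "tss_confined",
            }[row.reg_class]
            amp = config.mh2a_amplitude * (0.2 if row.reg_class == "neutral" else 1.0)
            if mode == "tss_confined":
                sel = np.abs(centers - tss) < 4 * config.mh2a_bump_sd
                v[sel] += amp * np.exp(
                    -0.5 * ((centers[sel] - tss) / config.mh2a_bump_sd) ** 2
                )
            else:  # promoter_plus_body plateau
                lo = row.start - 500 if row.strand == "+" else row.start
                hi = row.end if row.strand == "+" else row.end + 500
                sel = slice(max(lo, 0) // bs, min(hi, config.chrom_length) // bs)
                v[sel] += 0.7 * amp
    elif kind in ("H3K27me3", "H3K9me3"):
        high_type = "facultative" if kind == "H3K27me3" else "constitutive"
        for row in truth.domains.itertuples():
            mean = config.het_mean_high if row.type == high_type else config.het_mean_low
            fill(row.start, row.end, mean)
    elif kind == "H3K27ac":
        for row in truth.enhancers.itertuples():
            fill(row.start, row.end, row.amplitude)

    if config.noise_frac > 0:
        v += rng.normal(0.0, config.noise_frac * base_amp, size=v.size)
    return track


def enhancer_peaks(truth: SimTruth) -> PeakSet:
    """Planted H3K27ac peaks as a scored PeakSet (score = amplitude x width)."""
    peaks = [
        Peak(
            GenomicInterval(row.chrom, int(row.start), int(row.end)),
            name=f"enh{idx:05d}",
            score=float(row.amplitude * (row.end - row.start)),
        )
        for idx, row in enumerate(truth.enhancers.itertuples())
    ]
    return PeakSet(peaks)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) with var = mean + dispersion * mean^2; Poisson
    when dispersion is (near) zero."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion < 1e-12:
        out[pos] = rng.poisson(mean[pos])
    else:
        size_param = 1.0 / dispersion
        p = size_param / (size_param + mean[pos])
        out[pos] = rng.negative_binomial(size_param, p)
    return out


def simulate_expression(
    genes: list[GeneAnnotation], truth: SimTruth, config: SimConfig
) -> pd.DataFrame:
    """Per-gene NB counts: mean = tier rate x gene length in kb.

    Tier 0 (silent) has rate 0 and therefore zero counts.
    """
    rng = config.rng_expression()
    tiers = truth.genes["tier"].to_numpy()
    lengths = (truth.genes["end"] - truth.genes["start"]).to_numpy()
    rates = np.asarray(config.tier_means)[tiers]
    mean = rates * lengths / 1000.0
    counts = _nb_draw(rng, mean, config.nb_dispersion)
    return pd.DataFrame(
        {"gene_id": truth.genes["gene_id"], "count": counts, "length": lengths}
    )


def simulate_pchic(
    genes: list[GeneAnnotation],
    truth: SimTruth,
    config: SimConfig,
    condition: str = "ctrl",
) -> pd.DataFrame:
    """Two-replicate interaction table for one condition.

    Per bait, the number of contacts is Poisson with a class-specific mean
    (AG baits twice the RG mean by default) and per-replicate read counts are
    NB around ``class intensity x (distance / 500 kb)^-decay`` (AG intensity
    half the RG intensity by default).  Other ends are drawn up to 2 Mb away
    so the 1.5-Mb filter is exercised.
    """
    if condition not in _CONDITION_INDEX:
        raise ValueError(f"condition must be one of {list(_CONDITION_INDEX)}")
    rng = config.rng_contacts(condition)
    n_mean = {
        "AG": config.contact_mean_ag,
        "RG": config.contact_mean_rg,
        "neutral": config.contact_mean_neutral,
    }
    intensity = {
        "AG": config.contact_intensity_ag,
        "RG": config.contact_intensity_rg,
        "neutral": config.contact_intensity_neutral,
    }
    oe_width = 4000
    rows: list[dict] = []
    for row in truth.genes.itertuples():
        k = int(rng.poisson(n_mean[row.reg_class]))
        if k == 0:
            continue
        tss = row.start if row.strand == "+" else row.end - 1
        bait_start = max(0, tss - 2000)
        bait_end = min(config.chrom_length, tss + 2000)
        bait_mid = 0.5 * (bait_start + bait_end)
        dists = rng.integers(
            config.contact_min_distance, config.contact_max_distance + 1, size=k
        )
        signs = np.where(rng.random(k) < 0.5, -1, 1)
        mu = intensity[row.reg_class] * (dists / 5e5) ** (-config.contact_decay)
        c1 = _nb_draw(rng, mu, config.contact_dispersion)
        c2 = _nb_draw(rng, mu, config.contact_dispersion)
        for d, s, r1, r2 in zip(dists, signs, c1, c2):
            oe_mid = bait_mid + s * int(d)
            oe_start = int(round(oe_mid - oe_width / 2))
            oe_start = min(max(oe_start, 0), config.chrom_length - oe_width)
            rows.append(
                {
                    "bait_chrom": row.chrom,
                    "bait_start": bait_start,
                    "bait_end": bait_end,
                    "bait_id": row.gene_id,
                    "oe_chrom": row.chrom,
                    "oe_start": oe_start,
                    "oe_end": oe_start + oe_width,
                    "count_rep1": int(r1),
                    "count_rep2": int(r2),
                }
            )
    from .io import INTERACTION_COLUMNS

    return pd.DataFrame(rows, columns=INTERACTION_COLUMNS)
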
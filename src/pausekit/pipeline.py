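"""End-to-end orchestration: simulate -> pi -> expr -> enhancers -> enrich ->
metagene -> pchic, driven by one YAML config and one seed.

Every stage writes plain-text outputs into the run directory; a manifest
lists each file with its SHA-256 checksum, so two runs with the same config
and seed can be compared checksum-for-checksum.  All thresholds are
surfaced in the config with the analysis defaults (PI > 2; |FC| > 1.5 and
Padj < 0.1; 12.5 kb stitching; TSS exclusions of 2 kb / 2.5 kb; 5 PI bins;
4 expression tiers); deviations are validated and logged as warnings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import chromatin, enrichment, expression, io, pausing, pchic, profiles
from .simulate import SimConfig, TRACK_KINDS, enhancer_peaks, simulate_expression, simulate_genome, simulate_pchic, simulate_track

logger = logging.getLogger("pausekit.pipeline")

STAGES = ("simulate", "pi", "expr", "enhancers", "enrich", "metagene", "pchic")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All pipeline thresholds, defaulting to the analysis' printed values."""

    pi_threshold: float = 2.0
    pi_promoter_window: tuple[int, int] = (-30, 300)
    pi_min_width: int = 1000
    pi_min_promoter_density: float = 1.2
    fc_cut: float = 1.5
    padj_cut: float = 0.1
    stitch_distance: int = 12_500
    tss_exclusion_enhancer: int = 2_000
    tss_exclusion_se: int = 2_500
    pi_bins: int = 5
    expression_tiers: int = 4
    metagene_flank: int = 2_000
    metagene_outlier_sd: float = 2.0
    pchic_min_reads: int = 5
    pchic_max_distance: int = 1_500_000
    seed: int = 0
    sim: dict = field(default_factory=dict)

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)


_DEFAULTS = PipelineConfig()


def validate_config(raw: dict | None) -> tuple[PipelineConfig, list[str]]:
    """Normalize a raw config mapping: inject defaults, reject out-of-range
    values, and warn about deviations from the analysis defaults."""
    raw = dict(raw or {})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "pi_promoter_window" in raw:
        raw["pi_promoter_window"] = tuple(raw["pi_promoter_window"])
    cfg = PipelineConfig(**raw)
    if cfg.pi_threshold <= 0:
        raise ValueError(f"pi_threshold must be positive, got {cfg.pi_threshold}")
    if cfg.fc_cut < 1:
        raise ValueError("fc_cut is a linear ratio cutoff and must be >= 1")
    if not 0 < cfg.padj_cut <= 1:
        raise ValueError("padj_cut must lie in (0, 1]")
    for name in ("stitch_distance", "tss_exclusion_enhancer", "tss_exclusion_se",
                 "pi_min_width", "metagene_flank", "pchic_max_distance"):
        if getattr(cfg, name) <= 0:
            raise ValueError(f"{name} must be positive")
    if cfg.pi_bins < 2 or cfg.expression_tiers < 2:
        raise ValueError("pi_bins and expression_tiers must be >= 2")
    warnings = []
    for f in dataclasses.fields(PipelineConfig):
        if f.name in ("seed", "sim"):
            continue
        if getattr(cfg, f.name) != getattr(_DEFAULTS, f.name):
            warnings.append(
                f"{f.name}={getattr(cfg, f.name)} deviates from the default "
                f"{getattr(_DEFAULTS, f.name)}"
            )
    for w in warnings:
        logger.warning(w)
    return cfg, warnings


def load_config(path: str | Path | None) -> tuple[PipelineConfig, list[str]]:
    raw = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _truth_de_table(truth_genes: pd.DataFrame) -> pd.DataFrame:
    """Deterministic DE statistics table derived from simulation truth:
    AGs fall to half on knockdown, RGs double, neutral genes are untouched."""
    fc = truth_genes["reg_class"].map({"AG": 0.5, "RG": 2.0, "neutral": 1.0})
    padj = truth_genes["reg_class"].map({"AG": 0.01, "RG": 0.01, "neutral": 1.0})
    return pd.DataFrame(
        {"gene_id": truth_genes["gene_id"], "fold_change": fc, "adjusted_p": padj}
    )


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage on a synthetic dataset; returns the manifest dict.

    Any stage failure aborts with :class:`PipelineError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, list[str]] = {}

    def emit(stage: str, name: str) -> Path:
        outputs.setdefault(stage, []).append(name)
        return out / name

    stage = "simulate"
    try:
        sim = config.sim_config()
        genes, truth = simulate_genome(sim)
        io.write_gene_table(genes, emit(stage, "genes.tsv"))
        io.write_chrom_sizes(
            {sim.chrom_name: sim.chrom_length}, emit(stage, "chrom.sizes")
        )
        tracks = {}
        for kind in TRACK_KINDS:
            tracks[kind] = simulate_track(genes, truth, sim, kind)
            safe = kind.replace(".", "_")
            io.write_bedgraph(tracks[kind], emit(stage, f"track_{safe}.bedgraph"))
        counts = simulate_expression(genes, truth, sim)
        io.write_table(counts, emit(stage, "counts.tsv"))
        io.write_table(truth.genes, emit(stage, "truth_genes.tsv"))
        peaks = enhancer_peaks(truth)
        io.write_bed(peaks, emit(stage, "h3k27ac_peaks.bed"))
        pchic_tables = {
            cond: simulate_pchic(genes, truth, sim, condition=cond)
            for cond in ("ctrl", "kd")
        }
        for cond, tbl in pchic_tables.items():
            io.write_table(tbl, emit(stage, f"pchic_{cond}.tsv"))
        logger.info("simulate: %d genes, %d enhancer peaks", len(genes), len(peaks))
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineError(stage, str(exc)) from exc

    stage = "pi"
    try:
        clamped = tracks["PolII"].clamp_negative()
        records = pausing.pi_table(
            clamped,
            genes,
            promoter_window=config.pi_promoter_window,
            min_width=config.pi_min_width,
            min_promoter_density=config.pi_min_promoter_density,
        )
        pi_df = pausing.records_to_frame(records)
        io.write_table(pi_df, emit(stage, "pausing.tsv"))
        logger.info("pi: %d records", len(records))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "expr"
    try:
        fpkm = expression.compute_fpkm(counts)
        tiers = expression.expression_tiers(fpkm, k=config.expression_tiers)
        fpkm = fpkm.merge(tiers.reset_index(), on="gene_id")
        io.write_table(fpkm, emit(stage, "expression.tsv"))
        de_table = _truth_de_table(truth.genes)
        io.write_table(de_table, emit(stage, "de_stats.tsv"))
        ag, rg = expression.filter_de(de_table, config.fc_cut, config.padj_cut)
        logger.info("expr: %d AG, %d RG", len(ag), len(rg))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "enhancers"
    try:
        seeds = chromatin.call_enhancer_seeds(peaks, genes, config.tss_exclusion_se)
        stitched = chromatin.stitch(seeds, config.stitch_distance)
        ranked = chromatin.call_super_enhancers(stitched)
        io.write_table(chromatin.stitched_frame(ranked), emit(stage, "enhancers.tsv"))
        dom_scores = chromatin.score_domains(
            tracks["H3K27me3"],
            tracks["H3K9me3"],
            [
                chromatin.GenomicInterval(r.chrom, r.start, r.end)
                for r in truth.domains.itertuples()
            ],
        )
        io.write_table(
            chromatin.domain_scores_frame(dom_scores), emit(stage, "domains.tsv")
        )
        logger.info(
            "enhancers: %d seeds -> %d stitched, %d super",
            len(seeds), len(ranked), sum(e.is_super for e in ranked),
        )
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "enrich"
    try:
        bins = pausing.pi_quantile_bins(records, k=config.pi_bins)
        heat = enrichment.enrichment_heatmap(
            {"AG": ag & set(bins), "RG": rg & set(bins)}, bins
        )
        io.write_table(heat, emit(stage, "enrichment_heatmap.tsv"))
        logger.info("enrich: %d cells", len(heat))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "metagene"
    try:
        matrix = profiles.build_matrix(
            clamped, genes, flank=config.metagene_flank, bin_size=sim.bin_size,
            orient_by_strand=True,
        )
        prof = profiles.metagene(matrix, outlier_sd=config.metagene_outlier_sd)
        io.write_table(prof, emit(stage, "metagene_polii.tsv"))
        logger.info("metagene: n_used=%d", int(prof["n_used"].iloc[0]))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "pchic"
    try:
        group_labels = dict(zip(truth.genes["gene_id"], truth.genes["reg_class"]))
        summaries = {}
        for cond, tbl in pchic_tables.items():
            kept = pchic.filter_interactions(
                tbl, config.pchic_min_reads, config.pchic_max_distance
            )
            kept = pchic.add_intensity(kept)
            summaries[cond] = pchic.summarize_per_gene(kept, condition=cond)
            io.write_table(summaries[cond], emit(stage, f"pchic_summary_{cond}.tsv"))
        comparison = pchic.compare_conditions(
            summaries["ctrl"], summaries["kd"], group_labels
        )
        io.write_table(comparison, emit(stage, "pchic_comparison.tsv"))
        logger.info("pchic: %d comparisons", len(comparison))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    manifest = {
        "seed": config.seed,
        "stages": {
            s: {name: _sha256(out / name) for name in names}
            for s, names in outputs.items()
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
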
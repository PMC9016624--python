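import numpy as np
import pandas as pd
import pytest

from pausekit import io
from pausekit.intervals import GenomicInterval, strand_window
from pausekit.simulate import (
    SimConfig,
    TRACK_KINDS,
    enhancer_peaks,
    simulate_expression,
    simulate_genome,
    simulate_pchic,
    simulate_track,
)


def small_cfg(**kw):
    base = dict(n_genes=60, chrom_length=2_000_000, seed=5)
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"fraction_paused": 1.5},
            {"fraction_ag": 0.7, "fraction_rg": 0.5},
            {"tier_means": (0.0, 5.0, 5.0, 50.0)},
            {"tier_means": (10.0, 5.0, 50.0, 500.0)},
            {"pause_ratio_paused": 0.0},
            {"noise_frac": -0.1},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            small_cfg(**kw)


class TestSimulateGenome:
    def test_requested_gene_and_truth_counts(self):
        genes, truth = simulate_genome(small_cfg(n_genes=10))
        assert len(genes) == 10
        assert len(truth.genes) == 10

    def test_same_seed_identical_output(self, tmp_path):
        cfg = small_cfg()
        g1, t1 = simulate_genome(cfg)
        g2, t2 = simulate_genome(cfg)
        assert g1 == g2
        pd.testing.assert_frame_equal(t1.genes, t2.genes)
        pd.testing.assert_frame_equal(t1.enhancers, t2.enhancers)
        # file-level determinism
        io.write_gene_table(g1, tmp_path / "a.tsv")
        io.write_gene_table(g2, tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_fraction_paused_zero(self):
        _, truth = simulate_genome(small_cfg(fraction_paused=0.0))
        assert not truth.genes["paused"].any()

    def test_genes_sorted_disjoint_alternating(self):
        genes, _ = simulate_genome(small_cfg())
        for a, b in zip(genes, genes[1:]):
            assert a.interval.end < b.interval.start
            assert a.strand != b.strand
        assert all(g.width >= 2000 for g in genes)

    def test_overflowing_chromosome_rejected(self):
        with pytest.raises(ValueError, match="chromosome"):
            simulate_genome(small_cfg(n_genes=500, chrom_length=100_000))


class TestSimulateTrack:
    def test_unknown_kind_rejected(self, small_sim):
        cfg, genes, truth = small_sim
        with pytest.raises(ValueError, match="kind"):
            simulate_track(genes, truth, cfg, "H3K9ac")

    def test_noise_free_pause_ratio_exact(self):
        cfg = small_cfg(noise_frac=0.0, pause_ratio_paused=5.0)
        genes, truth = simulate_genome(cfg)
        track = simulate_track(genes, truth, cfg, "PolII")
        for gene, paused in zip(genes, truth.genes["paused"]):
            prom, _ = strand_window(gene, -30, 300, "TSS", cfg.chrom_length)
            body, _ = strand_window(gene, 300, gene.width, "TSS", cfg.chrom_length)
            ratio = track.region_signal(prom) / track.region_signal(body)
            assert ratio == pytest.approx(5.0 if paused else 1.0, abs=1e-6)

    def test_noise_free_body_is_flat(self):
        cfg = small_cfg(noise_frac=0.0)
        genes, truth = simulate_genome(cfg)
        track = simulate_track(genes, truth, cfg, "PolII")
        g = genes[0]
        body, _ = strand_window(g, 300, g.width, "TSS", cfg.chrom_length)
        bins = track.values[cfg.chrom_name][body.start // 50 : body.end // 50]
        assert np.ptp(bins) == 0.0

    def test_mh2a_tss_confined_vs_body_binding(self):
        """AG genes carry a TSS bump only; RG genes carry body signal too."""
        cfg = small_cfg(n_genes=200, chrom_length=6_000_000, noise_frac=0.0)
        genes, truth = simulate_genome(cfg)
        track = simulate_track(genes, truth, cfg, "mH2A1.1")
        sig = {"AG": [], "RG": []}
        for gene, cls in zip(genes, truth.genes["reg_class"]):
            if cls == "neutral":
                continue
            body, _ = strand_window(gene, 1500, gene.width, "TSS", cfg.chrom_length)
            sig[cls].append(track.region_signal(body))
        assert np.mean(sig["RG"]) > 10 * max(np.mean(sig["AG"]), 1e-9)

    def test_het_domain_tracks_anticorrelated(self, small_sim):
        cfg, genes, truth = small_sim
        k27 = simulate_track(genes, truth, cfg, "H3K27me3")
        k9 = simulate_track(genes, truth, cfg, "H3K9me3")
        r = np.corrcoef(k27.values[cfg.chrom_name], k9.values[cfg.chrom_name])[0, 1]
        assert r < -0.5

    def test_promoter_body_ratio_distribution_near_config(self):
        """Monte-Carlo: empirical mean ratios within 5% of configured."""
        cfg = SimConfig(n_genes=1000, seed=1)
        genes, truth = simulate_genome(cfg)
        track = simulate_track(genes, truth, cfg, "PolII").clamp_negative()
        ratios = {True: [], False: []}
        for gene, paused in zip(genes, truth.genes["paused"]):
            prom, _ = strand_window(gene, -30, 300, "TSS", cfg.chrom_length)
            body, _ = strand_window(gene, 300, gene.width, "TSS", cfg.chrom_length)
            ratios[bool(paused)].append(
                track.region_signal(prom) / track.region_signal(body)
            )
        assert np.mean(ratios[True]) == pytest.approx(cfg.pause_ratio_paused, rel=0.05)
        assert np.mean(ratios[False]) == pytest.approx(
            cfg.pause_ratio_elongating, rel=0.05
        )

    def test_generated_files_parse_through_readers(self, small_sim, tmp_path):
        cfg, genes, truth = small_sim
        for kind in TRACK_KINDS:
            track = simulate_track(genes, truth, cfg, kind)
            p = tmp_path / "t.bedgraph"
            io.write_bedgraph(track, p)
            back = io.read_bedgraph(p, cfg.bin_size, track.chrom_lengths)
            np.testing.assert_array_equal(
                back.values[cfg.chrom_name], track.values[cfg.chrom_name]
            )


class TestSimulateExpression:
    def test_deterministic(self, small_sim):
        cfg, genes, truth = small_sim
        a = simulate_expression(genes, truth, cfg)
        b = simulate_expression(genes, truth, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_silent_tier_zero_counts(self, small_sim):
        cfg, genes, truth = small_sim
        counts = simulate_expression(genes, truth, cfg)
        silent = truth.genes["tier"] == 0
        assert (counts.loc[silent.to_numpy(), "count"] == 0).all()

    def test_tier_rates_recovered_within_10pct(self):
        cfg = SimConfig(n_genes=1000, seed=1)
        genes, truth = simulate_genome(cfg)
        counts = simulate_expression(genes, truth, cfg)
        rate = counts["count"] / (counts["length"] / 1000.0)
        for tier in (1, 2, 3):
            sel = (truth.genes["tier"] == tier).to_numpy()
            assert rate[sel].mean() == pytest.approx(
                cfg.tier_means[tier], rel=0.10
            )


class TestSimulatePchic:
    def test_deterministic_and_condition_independent_streams(self, small_sim):
        cfg, genes, truth = small_sim
        a = simulate_pchic(genes, truth, cfg, "ctrl")
        b = simulate_pchic(genes, truth, cfg, "ctrl")
        pd.testing.assert_frame_equal(a, b)
        kd = simulate_pchic(genes, truth, cfg, "kd")
        assert not a.equals(kd)

    def test_zero_contact_config_empty_table(self, small_sim):
        cfg, genes, truth = small_sim
        import dataclasses

        quiet = dataclasses.replace(
            cfg, contact_mean_ag=0.0, contact_mean_rg=0.0, contact_mean_neutral=0.0
        )
        assert simulate_pchic(genes, truth, quiet).empty

    def test_ag_rg_count_ratio_near_config(self):
        cfg = SimConfig(
            n_genes=1000, fraction_ag=0.5, fraction_rg=0.5, seed=1,
            chrom_length=25_000_000,
        )
        genes, truth = simulate_genome(cfg)
        tbl = simulate_pchic(genes, truth, cfg)
        counts = tbl.groupby("bait_id").size()
        cls = truth.genes.set_index("gene_id")["reg_class"]
        per_class = counts.groupby(cls).mean()
        # zero-contact baits are absent from the table; compare raw sums per gene
        n_ag = (cls == "AG").sum()
        n_rg = (cls == "RG").sum()
        mean_ag = counts.reindex(cls.index[cls == "AG"]).fillna(0).mean()
        mean_rg = counts.reindex(cls.index[cls == "RG"]).fillna(0).mean()
        assert mean_ag / mean_rg == pytest.approx(
            cfg.contact_mean_ag / cfg.contact_mean_rg, rel=0.10
        )
        assert n_ag > 0 and n_rg > 0 and len(per_class) == 2

    def test_distances_exercise_filter_range(self, small_sim):
        cfg, genes, truth = small_sim
        tbl = simulate_pchic(genes, truth, cfg)
        from pausekit.pchic import interaction_distance

        d = interaction_distance(tbl)
        assert (d > 1_500_000).any() and (d < 1_500_000).any()


class TestEnhancerPeaks:
    def test_scored_and_sorted(self, small_sim):
        _, _, truth = small_sim
        peaks = enhancer_peaks(truth)
        assert len(peaks) == len(truth.enhancers)
        starts = [p.interval.start for p in peaks]
        assert starts == sorted(starts)
        assert all(p.score > 0 for p in peaks)
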
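import numpy as np
import pandas as pd
import pytest

from pausekit.pchic import (
    add_intensity,
    compare_conditions,
    filter_interactions,
    interaction_distance,
    quantile_normalize,
    summarize_per_gene,
)

from oracles import rank_average_quantile_norm


def interactions(rows):
    """rows: (bait_id, distance, count_rep1, count_rep2)."""
    out = []
    for bait_id, dist, c1, c2 in rows:
        out.append(
            {
                "bait_chrom": "chr1", "bait_start": 1_000_000,
                "bait_end": 1_004_000, "bait_id": bait_id,
                "oe_chrom": "chr1",
                "oe_start": 1_002_000 + dist - 2000,
                "oe_end": 1_002_000 + dist + 2000,
                "count_rep1": c1, "count_rep2": c2,
            }
        )
    return pd.DataFrame(out)


class TestFilterInteractions:
    def test_passing_record_kept(self):
        kept = filter_interactions(interactions([("g", 1_000_000, 6, 7)]))
        assert len(kept) == 1
        assert kept.loc[0, "distance"] == 1_000_000

    def test_min_reads_strict_in_each_replicate(self):
        kept = filter_interactions(interactions([("g", 1_000_000, 5, 8)]))
        assert kept.empty

    def test_distance_cutoff_strict(self):
        df = interactions(
            [("g", 2_000_000, 9, 9), ("g", 1_500_000, 9, 9), ("g", 1_499_999, 9, 9)]
        )
        kept = filter_interactions(df)
        assert kept["distance"].tolist() == [1_499_999]

    def test_monotone_in_min_reads(self):
        rng = np.random.default_rng(7)
        df = interactions(
            [(f"g{i}", int(rng.integers(10_000, 2_000_000)),
              int(rng.integers(0, 20)), int(rng.integers(0, 20)))
             for i in range(200)]
        )
        sizes = [len(filter_interactions(df, min_reads=m)) for m in range(0, 15)]
        assert sizes == sorted(sizes, reverse=True)

    def test_midpoint_distance(self):
        df = interactions([("g", 123_456, 9, 9)])
        assert interaction_distance(df).iloc[0] == 123_456


class TestQuantileNormalize:
    def test_toy_example(self):
        cols = np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])
        out = quantile_normalize(cols)
        np.testing.assert_allclose(out[:, 0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out[:, 1], [2.5, 3.5, 4.5])

    def test_identical_columns_fixed_point(self):
        col = np.array([3.0, 1.0, 7.0, 2.0])
        out = quantile_normalize(np.column_stack([col, col]))
        np.testing.assert_allclose(out[:, 0], col)
        np.testing.assert_allclose(out[:, 1], col)

    def test_sorted_columns_identical_after_normalization(self):
        rng = np.random.default_rng(23)
        cols = rng.normal(size=(500, 3)) * [1.0, 5.0, 0.2] + [0, 10, -3]
        out = quantile_normalize(cols)
        for j in range(1, 3):
            np.testing.assert_array_equal(
                np.sort(out[:, 0]), np.sort(out[:, j])
            )

    def test_ties_match_rank_average_oracle(self):
        rng = np.random.default_rng(24)
        cols = rng.integers(0, 6, size=(40, 3)).astype(float)  # heavy ties
        np.testing.assert_allclose(
            quantile_normalize(cols), rank_average_quantile_norm(cols), atol=1e-12
        )

    def test_shape_errors(self):
        with pytest.raises(ValueError):
            quantile_normalize(np.ones((5, 1)))
        with pytest.raises(ValueError):
            quantile_normalize(np.ones(5))


class TestSummarizePerGene:
    @staticmethod
    def normalized(rows):
        return add_intensity(filter_interactions(interactions(rows)))

    def test_counts_per_bait(self):
        kept = self.normalized(
            [("a", 100_000, 9, 9), ("a", 200_000, 10, 11), ("a", 300_000, 8, 9),
             ("b", 100_000, 12, 13)]
        )
        summary = summarize_per_gene(kept)
        assert summary.set_index("bait_id").loc["a", "n_interactions"] == 3

    def test_bait_without_interactions_reported_zero(self):
        kept = self.normalized([("a", 100_000, 9, 9)])
        summary = summarize_per_gene(kept, all_baits=["a", "b"])
        row_b = summary.set_index("bait_id").loc["b"]
        assert row_b["n_interactions"] == 0
        assert pd.isna(row_b["mean_intensity"])

    def test_intensity_is_mean_of_normalized_replicates(self):
        kept = self.normalized([("a", 100_000, 9, 9), ("b", 200_000, 30, 31)])
        expected = 0.5 * (kept["norm_count_rep1"] + kept["norm_count_rep2"])
        np.testing.assert_allclose(kept["intensity"], expected)

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(25)
        rows = [
            (f"g{rng.integers(0, 8)}", int(rng.integers(50_000, 1_400_000)),
             int(rng.integers(6, 40)), int(rng.integers(6, 40)))
            for _ in range(100)
        ]
        kept = self.normalized(rows)
        summary = summarize_per_gene(kept).set_index("bait_id")
        for bait, sub in kept.groupby("bait_id"):
            assert summary.loc[bait, "n_interactions"] == len(sub)
            assert summary.loc[bait, "mean_intensity"] == pytest.approx(
                sub["intensity"].mean()
            )

    def test_requires_intensity(self):
        with pytest.raises(ValueError, match="intensity"):
            summarize_per_gene(interactions([("a", 1000, 9, 9)]))


class TestCompareConditions:
    @staticmethod
    def summary(rows, condition):
        return pd.DataFrame(
            rows, columns=["bait_id", "n_interactions", "mean_intensity"]
        ).assign(condition=condition)

    def test_identical_summaries_paired_p_one(self):
        rows = [(f"g{i}", 3 + i % 4, 10.0 + i) for i in range(10)]
        ctrl = self.summary(rows, "ctrl")
        kd = self.summary(rows, "kd")
        labels = {f"g{i}": "AG" for i in range(10)}
        out = compare_conditions(ctrl, kd, labels)
        paired = out[out["comparison"] == "ctrl_vs_kd"]
        assert (paired["p_value"] == 1.0).all()

    def test_designed_group_difference_detected(self):
        rng = np.random.default_rng(26)
        rows_ag = [(f"a{i}", int(rng.poisson(8)) + 1, float(rng.normal(15, 2)))
                   for i in range(60)]
        rows_rg = [(f"r{i}", int(rng.poisson(4)) + 1, float(rng.normal(30, 2)))
                   for i in range(60)]
        ctrl = self.summary(rows_ag + rows_rg, "ctrl")
        kd = self.summary(rows_ag + rows_rg, "kd")
        labels = {**{f"a{i}": "AG" for i in range(60)},
                  **{f"r{i}": "RG" for i in range(60)}}
        out = compare_conditions(ctrl, kd, labels)
        between = out[out["comparison"] == "between_groups"].set_index("metric")
        assert between.loc["n_interactions", "p_value"] < 0.01
        assert between.loc["mean_intensity", "p_value"] < 0.01

    def test_single_gene_group_refused(self):
        ctrl = self.summary([("a", 3, 10.0), ("b", 4, 11.0), ("c", 5, 12.0)], "ctrl")
        kd = self.summary([("a", 3, 10.0), ("b", 4, 11.0), ("c", 5, 12.0)], "kd")
        labels = {"a": "AG", "b": "AG", "c": "RG"}
        with pytest.raises(ValueError, match="fewer than 2|>= 2"):
            compare_conditions(ctrl, kd, labels)

    def test_no_matched_baits_rejected(self):
        ctrl = self.summary([("a", 3, 10.0)], "ctrl")
        kd = self.summary([("z", 3, 10.0)], "kd")
        with pytest.raises(ValueError, match="matched"):
            compare_conditions(ctrl, kd, {"a": "AG", "z": "AG"})
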
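"""Window tiling, SNP-count binning, outlier calling and the framework's
set/sort operations against direct oracles."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

import andescan as a
from andescan.containers import DataError


def snp_table(positions, scores, chrom="1"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": list(positions),
            "snp_id": [f"s{i}" for i in range(len(positions))],
            "score": list(scores),
        }
    )


def window_table(scores, width=100_000, chrom="1", snp_count=5):
    n = len(scores)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * width,
            "end": (np.arange(n) + 1) * width,
            "snp_count": snp_count,
            "score": scores,
            "max_snp_score": scores,
            "max_snp_id": [f"s{i}" for i in range(n)],
            "max_snp_pos": np.arange(n) * width + 1,
        }
    )


class TestMakeWindows:
    def test_ten_windows_over_950kb(self):
        pos = np.arange(1, 950_001, 10_000)
        w = a.make_windows(snp_table(pos, np.zeros(len(pos))), 100_000)
        assert len(w) == 10
        assert w["start"].iloc[0] == 0 and w["end"].iloc[-1] == 1_000_000

    def test_one_based_to_zero_based_convention(self):
        # 1-based position 100,000 is 0-based 99,999 -> window [0, 100000)
        w = a.make_windows(snp_table([100_000], [0.0]), 100_000)
        assert (w["start"].iloc[0], w["end"].iloc[0]) == (0, 100_000)
        w2 = a.make_windows(snp_table([100_001], [0.0]), 100_000)
        assert w2["start"].iloc[0] == 100_000

    def test_empty_windows_dropped(self):
        w = a.make_windows(snp_table([50, 950_000], [0.0, 0.0]), 100_000)
        assert len(w) == 2  # windows 1..8 have no SNPs and are absent

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(np.arange(1, 2_000_000), size=300, replace=False))
        w = a.make_windows(snp_table(pos, np.zeros(300)), 100_000)
        assert w["snp_count"].sum() == 300  # every SNP in exactly one window


class TestWindowScores:
    def test_max_kind(self):
        snp = snp_table([10, 20, 150_000], [0.1, 0.7, 0.3])
        w = a.window_scores(snp, 100_000, "score", "max")
        assert w["score"].tolist() == [0.7, 0.3]
        assert w["max_snp_id"].iloc[0] == "s1"

    def test_prop_extreme_kind(self):
        snp = snp_table([10, 20, 30, 40], [2.5, -3.0, 0.5, 1.0])
        w = a.window_scores(snp, 100_000, "score", "prop_extreme", abs_threshold=2.0)
        assert w["score"].iloc[0] == pytest.approx(0.5)
        assert w["max_snp_score"].iloc[0] == pytest.approx(3.0)

    def test_nan_scores_not_counted(self):
        snp = snp_table([10, 20], [np.nan, 0.4])
        w = a.window_scores(snp, 100_000, "score", "max")
        assert w["snp_count"].iloc[0] == 1


class TestBinning:
    def test_uniform_counts_single_bin(self):
        w = window_table(np.linspace(0, 1, 60))
        binned = a.bin_by_snp_count(w)
        assert (binned["bin_id"] == 0).all()

    def test_merge_up_to_floor(self):
        counts = np.repeat([1, 2, 3, 4, 5, 6], 20)  # 20 windows per count
        w = window_table(np.linspace(0, 1, 120), snp_count=1)
        w["snp_count"] = counts
        binned = a.bin_by_snp_count(w, bin_floor=50)
        sizes = binned.groupby("bin_id").size()
        # merge-up: counts {1,2,3} -> 60, {4,5,6} -> 60
        assert sizes.tolist() == [60, 60]

    def test_deficient_tail_folds_into_previous(self):
        counts = np.concatenate([np.repeat(1, 60), np.repeat(9, 10)])
        w = window_table(np.linspace(0, 1, 70))
        w["snp_count"] = counts
        binned = a.bin_by_snp_count(w, bin_floor=50)
        assert binned["bin_id"].nunique() == 1

    def test_fewer_than_floor_windows_single_bin(self):
        w = window_table(np.linspace(0, 1, 10))
        w["snp_count"] = np.arange(10)
        binned = a.bin_by_snp_count(w, bin_floor=50)
        assert (binned["bin_id"] == 0).all()


class TestOutliers:
    def test_two_hundred_windows_top1_flags_two(self):
        w = a.bin_by_snp_count(window_table(np.arange(200, dtype=float)))
        out = a.call_outliers(w)
        assert out["top1"].sum() == 2
        assert set(out.loc[out["top1"], "score"]) == {198.0, 199.0}

    def test_ceiling_rule_per_bin(self):
        rng = np.random.default_rng(1)
        w = window_table(rng.normal(size=1000))
        w["snp_count"] = np.repeat(np.arange(10), 100)
        out = a.call_outliers(a.bin_by_snp_count(w, bin_floor=100))
        per_bin = out.groupby("bin_id")["top1"].sum()
        for b, flagged in per_bin.items():
            n = (out["bin_id"] == b).sum()
            assert flagged == math.ceil(0.01 * n)

    def test_tie_break_deterministic(self):
        w = window_table([1.0, 1.0, 0.0, 0.0])
        w.loc[0, "max_snp_score"] = 0.5
        w.loc[1, "max_snp_score"] = 0.9  # wins the tie
        out = a.call_outliers(a.bin_by_snp_count(w))
        assert out.loc[out["rank"] == 1, "start"].iloc[0] == 100_000

    def test_rank_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.random(100)
        w1 = a.call_outliers(a.bin_by_snp_count(window_table(scores)))
        w2 = a.call_outliers(a.bin_by_snp_count(window_table(np.exp(5 * scores))))
        np.testing.assert_array_equal(w1["rank"], w2["rank"])
        np.testing.assert_array_equal(w1["top1"], w2["top1"])

    def test_top1_implies_top5(self):
        rng = np.random.default_rng(3)
        out = a.call_outliers(a.bin_by_snp_count(window_table(rng.random(300))))
        assert (out["top1"] <= out["top5"]).all()


class TestExclusionFilter:
    def _flagged(self, scores, seed_offset=0):
        return a.call_outliers(a.bin_by_snp_count(window_table(scores)))

    def test_disjoint_sets_all_retained(self):
        focal = self._flagged(np.arange(100, dtype=float))
        control = self._flagged(np.arange(100, dtype=float)[::-1])
        kept = a.exclusion_filter(focal, control)
        assert len(kept) == focal["top1"].sum()

    def test_shared_window_removed(self):
        scores = np.arange(100, dtype=float)
        focal = self._flagged(scores)
        control = self._flagged(scores)  # same ranking: top window shared
        kept = a.exclusion_filter(focal, control)
        assert len(kept) == 0

    def test_control_percentile_one_removes_everything(self):
        focal = self._flagged(np.arange(100, dtype=float))
        control = a.call_outliers(
            a.bin_by_snp_count(window_table(np.arange(100, dtype=float))),
            top1=0.01,
            top5=1.0,
        )
        kept = a.exclusion_filter(focal, control)
        assert len(kept) == 0

    def test_mismatched_tiling_rejected(self):
        focal = self._flagged(np.arange(100, dtype=float))
        control = a.call_outliers(
            a.bin_by_snp_count(window_table(np.arange(100, dtype=float), width=200_000))
        )
        with pytest.raises(DataError, match="tiling"):
            a.exclusion_filter(focal, control)


class TestOverlapAndCounts:
    def test_disjoint_gene_sets_empty_summary(self):
        df = a.cross_test_overlap({"ihs": {"A"}, "pbs": {"B"}})
        assert (df["n_tests"] >= 2).sum() == 0

    def test_three_test_gene_reported(self):
        df = a.cross_test_overlap(
            {"ihs": {"G"}, "xpehh": {"G"}, "pbs": {"G", "H"}}
        )
        assert df.set_index("gene").loc["G", "n_tests"] == 3

    def test_matches_set_intersection_oracle(self):
        rng = np.random.default_rng(4)
        genes = [f"G{i}" for i in range(50)]
        sets = {
            t: set(rng.choice(genes, size=20, replace=False))
            for t in ("ihs", "xpehh", "fst", "pbs")
        }
        df = a.cross_test_overlap(sets).set_index("gene")
        for g in genes:
            expected = sum(g in s for s in sets.values())
            if expected:
                assert df.loc[g, "n_tests"] == expected
            else:
                assert g not in df.index

    def test_fst_cutoff_strict_inequality(self):
        w = window_table([0.59, 0.60, 0.61])
        assert a.fst_cutoff_count(w, 0.6) == 1
        assert a.fst_cutoff_count(window_table([0.1, 0.2]), 0.6) == 0


class TestBranchLengthComparison:
    def _pair(self, s1, s2):
        f1 = a.call_outliers(a.bin_by_snp_count(window_table(s1)))
        f2 = a.call_outliers(a.bin_by_snp_count(window_table(s2)))
        return f1, f2

    def test_identical_scores_share_zero(self):
        s = np.arange(100, dtype=float)
        share, n = a.branch_length_comparison(*self._pair(s, s))
        assert n > 0 and share == 0.0  # strict > never fires on ties

    def test_epsilon_dominance_share_one(self):
        s = np.arange(100, dtype=float)
        share, n = a.branch_length_comparison(*self._pair(s + 1e-9, s))
        assert share == 1.0

    def test_empty_overlap_not_available(self):
        s = np.arange(100, dtype=float)
        share, n = a.branch_length_comparison(*self._pair(s, s[::-1]))
        assert share is None and n == 0

    def test_random_scores_near_half(self):
        # 1000 jointly-flagged windows with independent scores
        rng = np.random.default_rng(5)
        f1 = window_table(rng.random(1000))
        f2 = window_table(rng.random(1000))
        f1["top1"] = True
        f2["top1"] = True
        share, n = a.branch_length_comparison(f1, f2)
        assert n == 1000
        assert abs(share - 0.5) < 0.05
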
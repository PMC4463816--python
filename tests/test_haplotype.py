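"""EHH / iHH / iHS / XP-EHH against brute-force pair counting."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import andescan as a
from andescan.containers import DataError
from andescan.haplotype import EhhCurve, standardize_binned

from conftest import toy_haps, toy_variants
from oracles import ehh_pair_counting, trapezoid_to_crossing


def positions(n, spacing=1000):
    return np.arange(1, n + 1) * spacing


class TestEhh:
    def test_identical_carriers_stay_at_one(self):
        block = np.zeros((4, 10), dtype=np.uint8)
        block[:, 5] = 1  # everyone carries the derived core allele
        curve = a.ehh(block, positions(10), core=5, allele=1, direction="right", floor=0.0)
        np.testing.assert_array_equal(curve.ehh, np.ones(5))

    def test_three_one_split_gives_half(self):
        # 4 carriers; extended haplotypes split {3, 1}: EHH = 3/C(4,2) = 0.5
        block = np.zeros((4, 3), dtype=np.uint8)
        block[:, 0] = 1  # core
        block[3, 1] = 1  # one haplotype deviates at the next marker
        curve = a.ehh(block, positions(3), core=0, allele=1, direction="right", floor=0.0)
        assert curve.ehh[1] == pytest.approx(0.5)

    def test_all_distinct_gives_zero(self):
        block = np.array(
            [[1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1]], dtype=np.uint8
        )
        curve = a.ehh(block, positions(3), core=0, allele=1, direction="right", floor=0.0)
        assert curve.ehh[2] == 0.0

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(0)
        block = rng.integers(0, 2, size=(12, 30)).astype(np.uint8)
        block[:, 15] = 1
        for direction in ("left", "right"):
            curve = a.ehh(block, positions(30), 15, 1, direction, floor=0.0)
            assert np.all(np.diff(curve.ehh) <= 1e-12)

    def test_gap_stops_walk(self):
        pos = np.array([1000, 2000, 500_000])
        block = np.ones((4, 3), dtype=np.uint8)
        curve = a.ehh(block, pos, 0, 1, "right", floor=0.0, gap_max=200_000)
        assert curve.stop_reason == "gap"
        assert len(curve.distances) == 2  # core + one marker before the gap

    def test_single_carrier_rejected(self):
        block = np.zeros((4, 3), dtype=np.uint8)
        block[0, 1] = 1
        with pytest.raises(DataError, match=">= 2"):
            a.ehh(block, positions(3), 1, 1, "right")

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        H = int(rng.integers(4, 13))
        M = int(rng.integers(5, 31))
        block = rng.integers(0, 2, size=(H, M)).astype(np.uint8)
        core = int(rng.integers(0, M))
        pos = positions(M)
        for allele in (0, 1):
            subset = np.flatnonzero(block[:, core] == allele)
            if subset.size < 2:
                continue
            for direction in ("left", "right"):
                curve = a.ehh(block, pos, core, allele, direction, floor=0.0)
                step = 1 if direction == "right" else -1
                for i, d in enumerate(curve.distances[1:], start=1):
                    target = core + step * i
                    expected = ehh_pair_counting(block, core, target, subset, False)
                    assert curve.ehh[i] == pytest.approx(float(expected), abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_pooled_matches_pair_counting_with_core(self, seed):
        rng = np.random.default_rng(seed)
        block = rng.integers(0, 2, size=(8, 15)).astype(np.uint8)
        core = 7
        pos = positions(15)
        curve = a.ehh(block, pos, core, "pooled", "right", floor=0.0)
        subset = range(8)
        for i in range(1, len(curve.distances)):
            expected = ehh_pair_counting(block, core, core + i, subset, True)
            assert curve.ehh[i] == pytest.approx(float(expected), abs=1e-12)


class TestIhh:
    def curve(self, dists, vals, reason="floor", direction="right"):
        return EhhCurve(0, 1, direction, np.asarray(dists, float), np.asarray(vals, float), reason)

    def test_rectangle(self):
        # EHH = 1 out to 10 kb each side, then an immediate cut to below floor
        left = self.curve([0, 10_000, 10_001], [1.0, 1.0, 0.0], direction="left")
        right = self.curve([0, 10_000, 10_001], [1.0, 1.0, 0.0])
        area, flag = a.ihh(left, right)
        # crossing interpolated within the 1 bp step
        assert area == pytest.approx(20_000, rel=1e-3)
        assert flag == "ok"

    def test_single_step_matches_piecewise_oracle(self):
        dists, vals = [0, 1000], [1.0, 0.04]
        side = self.curve(dists, vals)
        area, flag = a.ihh(side, side)
        expected = 2 * trapezoid_to_crossing(dists, vals, 0.05)
        assert area == pytest.approx(expected, abs=1e-9)
        assert flag == "ok"

    def test_symmetric_curves_contribute_equally(self):
        left = self.curve([0, 500, 1500], [1.0, 0.4, 0.01], direction="left")
        right = self.curve([0, 500, 1500], [1.0, 0.4, 0.01])
        area, _ = a.ihh(left, right)
        one_sided = trapezoid_to_crossing([0, 500, 1500], [1.0, 0.4, 0.01], 0.05)
        assert area == pytest.approx(2 * one_sided, abs=1e-9)

    def test_additive_over_subdivided_intervals(self):
        coarse = self.curve([0, 1000], [1.0, 0.5], reason="end")
        fine = self.curve([0, 500, 1000], [1.0, 0.75, 0.5], reason="end")
        a1, _ = a.ihh(coarse, coarse)
        a2, _ = a.ihh(fine, fine)
        assert a1 == pytest.approx(a2)

    def test_gap_flag_propagates(self):
        side = self.curve([0, 1000], [1.0, 0.9], reason="gap")
        ok = self.curve([0, 1000, 2000], [1.0, 0.5, 0.01])
        _, flag = a.ihh(side, ok)
        assert flag == "gap"

    def test_zero_area_flagged(self):
        side = self.curve([0], [1.0], reason="floor")
        area, flag = a.ihh(side, side)
        assert flag == "zero_area"


class TestStandardization:
    def test_bins_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(1)
        n = 2000
        freqs = rng.uniform(0.05, 0.95, n)
        vals = rng.normal(freqs, 1.0)  # frequency-dependent mean, like iHS
        std, bins = standardize_binned(vals, freqs, np.ones(n, bool))
        for b in np.unique(bins[bins >= 0]):
            m = bins == b
            assert np.abs(std[m].mean()) < 1e-9
            assert np.abs(std[m].std() - 1.0) < 1e-9

    def test_small_bins_merged(self):
        freqs = np.concatenate([np.full(100, 0.5), np.full(3, 0.93)])
        vals = np.arange(103, dtype=float)
        std, bins = standardize_binned(vals, freqs, np.ones(103, bool), min_bin=20)
        assert len(np.unique(bins)) == 1  # deficient high bin folded in

    def test_invalid_entries_get_nan(self):
        vals = np.array([1.0, 2.0, 3.0])
        valid = np.array([True, False, True])
        std, bins = standardize_binned(vals, np.full(3, 0.5), valid)
        assert np.isnan(std[1]) and bins[1] == -1


class TestIhsScan:
    def _scan(self, haps, variants, pops=("X",)):
        panel = a.PopulationPanel(
            {s: pops[0] for s in haps.sample_ids}
        )
        return a.ihs_scan(haps, variants, panel, pops[0])

    def test_mirror_symmetry_gives_zero(self):
        # ancestral and derived carriers with mirror-image structure
        rng = np.random.default_rng(2)
        M = 21
        half = rng.integers(0, 2, size=(6, M)).astype(np.uint8)
        block = np.vstack([half, half.copy()])
        core = 10
        block[:6, core] = 0
        block[6:, core] = 1
        block[6:, :core] = half[:, :core]
        block[6:, core + 1:] = half[:, core + 1:]
        variants = toy_variants(positions(M))
        haps = a.HaplotypeMatrix(block, [f"S{i}" for i in range(6)])
        df = self._scan(haps, variants)
        row = df[df["pos"] == positions(M)[core]].iloc[0]
        assert row["ihs_unstd"] == pytest.approx(0.0, abs=1e-12)

    def test_frequency_bounds_flagged(self, small_scenario):
        _, variants, haps, panel = small_scenario
        df = a.ihs_scan(haps, variants, panel, "CAL")
        out_of_bounds = (df["dfreq"] < 0.05) | (df["dfreq"] > 0.95)
        assert (df.loc[out_of_bounds, "flag"].isin(["low_freq", "n_core"])).all()
        assert df.loc[out_of_bounds, "ihs_std"].isna().all()

    def test_standardized_bins_zero_mean_unit_sd(self, small_scenario):
        _, variants, haps, panel = small_scenario
        df = a.ihs_scan(haps, variants, panel, "CAL")
        ok = df[df["valid"]]
        for b, sub in ok.groupby("freq_bin"):
            assert abs(sub["ihs_std"].mean()) < 1e-9
            assert abs(sub["ihs_std"].std(ddof=0) - 1.0) < 1e-9


class TestXpehhScan:
    def test_identical_populations_give_zero_unstd(self):
        rng = np.random.default_rng(3)
        block = rng.integers(0, 2, size=(8, 40)).astype(np.uint8)
        values = np.vstack([block, block])  # popB is a copy of popA
        variants = toy_variants(positions(40))
        haps = a.HaplotypeMatrix(values, [f"S{i}" for i in range(8)])
        panel = a.PopulationPanel(
            {f"S{i}": ("A" if i < 4 else "B") for i in range(8)}
        )
        df = a.xpehh_scan(haps, variants, panel, "A", "B")
        ok = df[df["flag"].isin(["ok", "edge"])]
        np.testing.assert_allclose(ok["xpehh_unstd"], 0.0, atol=1e-12)

    def test_swap_negates_unstandardized(self, small_scenario):
        _, variants, haps, panel = small_scenario
        ab = a.xpehh_scan(haps, variants, panel, "CAL", "WIC")
        ba = a.xpehh_scan(haps, variants, panel, "WIC", "CAL")
        m = ab["xpehh_unstd"].notna() & ba["xpehh_unstd"].notna()
        np.testing.assert_allclose(
            ab.loc[m, "xpehh_unstd"], -ba.loc[m, "xpehh_unstd"], atol=1e-12
        )

    def test_genomewide_standardization(self, small_scenario):
        _, variants, haps, panel = small_scenario
        df = a.xpehh_scan(haps, variants, panel, "CAL", "WIC")
        ok = df[df["valid"]]
        assert abs(ok["xpehh_std"].mean()) < 1e-9
        assert abs(ok["xpehh_std"].std(ddof=0) - 1.0) < 1e-9
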
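"""Spike-in protocol, synthetic profile generator, and call evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cnahier.bins import GenomeBins
from cnahier.reference import estimate_cn_reference
from cnahier.simulate import (TruthRegion, TruthSet, evaluate_calls,
                              plan_benchmark_chromosome, plan_fa_regions,
                              plan_lcvs, profile_from_cn, select_fa_regions,
                              spike_plan_delta, spike_reads, spike_truth,
                              synth_profile, uniform_reads)


class TestPlanLCVs:
    def test_single_segment_whole_chromosome(self, rng):
        plan = plan_lcvs(50_000_000, 1, rng)
        assert plan[0][:2] == (0, 50_000_000)

    def test_partition_conserves_length(self, rng):
        plan = plan_lcvs(100_000_000, 4, rng)
        assert plan[0][0] == 0 and plan[-1][1] == 100_000_000
        assert all(a[1] == b[0] for a, b in zip(plan[:-1], plan[1:]))

    def test_minimum_segment_respected_over_many_draws(self):
        r = np.random.default_rng(0)
        for _ in range(200):
            plan = plan_lcvs(30_000_000, 5, r)
            assert min(e - s for s, e, _ in plan) >= 1_000_000

    def test_infeasible_raises(self, rng):
        with pytest.raises(ValueError):
            plan_lcvs(3_000_000, 4, rng)


class TestPlanFARegions:
    def test_constraints_hold(self, rng):
        plan = plan_benchmark_chromosome(20_000_000, 2, rng)
        fas = plan_fa_regions(plan, 40, rng)
        assert len(fas) == 40
        lcvs = [(s, e, c) for s, e, c in plan if c != 2]
        for s, e, pc, tc in fas:
            assert 50_000 <= e - s <= 100_000
            assert tc != pc and 0 <= tc <= 6
            assert any(ls < s and e < le for ls, le, lc in lcvs)
        ordered = sorted(fas)
        assert all(a[1] <= b[0] for a, b in zip(ordered[:-1], ordered[1:]))

    def test_mask_avoidance(self, rng):
        plan = [(0, 20_000_000, 3)]
        masks = [("chr1", 5_000_000, 9_000_000)]
        fas = plan_fa_regions(plan, 20, rng, mask_intervals=masks,
                              only_in_lcvs=False)
        for s, e, _, _ in fas:
            assert e <= 5_000_000 or s >= 9_000_000


class TestSpikeReads:
    def test_delta_formula_examples(self):
        assert spike_plan_delta(1000, 2, 3) == 500
        assert spike_plan_delta(1000, 2, 2) == 0
        assert spike_plan_delta(1000, 2, 1) == -500
        assert spike_plan_delta(7, 2, 3) == 4  # round(3.5) half away

    @given(x=st.integers(0, 100_000), c1=st.integers(1, 6),
           c2=st.integers(0, 8))
    @settings(max_examples=200, deadline=None)
    def test_delta_formula_property(self, x, c1, c2):
        v = x * (c2 / c1 - 1.0)
        expected = int(np.sign(v) * np.floor(abs(v) + 0.5))
        assert spike_plan_delta(x, c1, c2) == expected

    def test_addition_and_conservation_outside_region(self, rng):
        reads = uniform_reads(2_000_000, 2.0, 100, rng)
        region = (500_000, 700_000)
        before_out = reads.n_reads - reads.in_region(*region).size
        x = reads.in_region(*region).size
        out = spike_reads(reads, region, 2, 3, rng)
        assert out.in_region(*region).size == x + round(x * 0.5)
        assert out.n_reads - out.in_region(*region).size == before_out
        # added reads stay inside the region
        assert np.all((out.starts >= 0))

    def test_removal_exact_count_and_cn_zero(self, rng):
        reads = uniform_reads(2_000_000, 2.0, 100, rng)
        region = (100_000, 300_000)
        x = reads.in_region(*region).size
        halved = spike_reads(reads, region, 2, 1, rng)
        assert halved.in_region(*region).size == x - round(x * 0.5)
        wiped = spike_reads(reads, region, 2, 0, rng)
        assert wiped.in_region(*region).size == 0

    def test_identity_when_cn_unchanged(self, rng):
        reads = uniform_reads(1_000_000, 1.0, 100, rng)
        out = spike_reads(reads, (0, 500_000), 3, 3, rng)
        np.testing.assert_array_equal(out.starts, reads.starts)

    def test_rd_ratio_matches_target(self, rng):
        reads = uniform_reads(5_000_000, 2.0, 100, rng)
        region = (1_000_000, 3_000_000)
        out = spike_reads(reads, region, 2, 5, rng)
        gb = GenomeBins("chr1", 5_000_000, 1000)
        rd0 = reads.to_rd(gb).rd[1000:3000].mean()
        rd1 = out.to_rd(gb).rd[1000:3000].mean()
        assert rd1 / rd0 == pytest.approx(2.5, rel=0.02)

    def test_bad_copy_numbers_raise(self):
        with pytest.raises(ValueError):
            spike_plan_delta(10, 0, 2)
        with pytest.raises(ValueError):
            spike_plan_delta(10, 2, -1)


class TestSelectFARegions:
    def test_read_count_cutoff_enforced(self, rng):
        reads = uniform_reads(20_000_000, 1.0, 100, rng)
        plan = [(0, 20_000_000, 3)]
        regions = select_fa_regions(reads, plan, 10, rng,
                                    size_range=(50_000, 60_000))
        assert len(regions) == 10
        # audit: every accepted region satisfies the 5% similarity rule
        width = 50_000
        starts = np.arange(0, 20_000_000 - width, width // 2)
        med = np.median([reads.in_region(int(s), int(s + width)).size
                         for s in starts])
        for s, e, _, _ in regions:
            rc = reads.in_region(s, e).size * (width / (e - s))
            assert abs(med - rc) / med <= 0.05 + 0.01


class TestSynthProfile:
    def test_diploid_histogram_unimodal_at_coverage(self):
        profile, truth, cn = synth_profile(chrom_length=5_000_000,
                                           coverage=4.0, n_lcv=0, n_fa=0,
                                           rng=np.random.default_rng(1))
        assert truth.regions == []
        assert np.nanmean(profile.values) == pytest.approx(4.0, rel=0.02)

    def test_mode_spacing_reflects_planted_states(self):
        # thirds at CN 1 / 2 / 3 -> histogram modes with spacing 1:2:3
        cn = np.concatenate([np.full(10_000, 1.0), np.full(10_000, 2.0),
                             np.full(10_000, 3.0)])
        profile = profile_from_cn(cn, 8.0, np.random.default_rng(2))
        v = profile.values
        hist, edges = np.histogram(v[np.isfinite(v)], bins=200)
        centers = 0.5 * (edges[:-1] + edges[1:])
        modes = []
        for lo, hi in ((2, 6), (6, 10), (10, 14)):
            sel = (centers >= lo) & (centers < hi)
            modes.append(centers[sel][np.argmax(hist[sel])])
        assert modes[1] / modes[0] == pytest.approx(2.0, rel=0.05)
        assert modes[2] / modes[0] == pytest.approx(3.0, rel=0.05)

    def test_same_seed_reproducible(self):
        a = synth_profile(chrom_length=12_000_000,
                          rng=np.random.default_rng(9), n_fa=5)
        b = synth_profile(chrom_length=12_000_000,
                          rng=np.random.default_rng(9), n_fa=5)
        np.testing.assert_array_equal(a[0].rd, b[0].rd)
        assert a[1].regions == b[1].regions

    def test_wave_and_gc_bias_applied(self):
        p_wave, _, _ = synth_profile(chrom_length=5_000_000, coverage=10.0,
                                     n_lcv=0, n_fa=0,
                                     wave={"amplitude": 0.2, "period": 500},
                                     rng=np.random.default_rng(3))
        v = p_wave.values
        phase = np.sin(2 * np.pi * np.arange(v.size) / 500)
        assert np.corrcoef(v, phase)[0, 1] > 0.5


class TestSpikeRobustness:
    def test_reference_stable_under_lcv_spiking(self):
        """Spiking LCVs moves the global median by percents while the
        multimodal 2N estimate stays within 1%."""
        rng = np.random.default_rng(42)
        reads = uniform_reads(30_000_000, 8.0, 50, rng, "chr1")
        gb = GenomeBins("chr1", 30_000_000, 1000)
        base = reads.to_rd(gb)
        ref0 = estimate_cn_reference(base, "diploid")
        plan = [(0, 18_000_000, 2), (18_000_000, 26_000_000, 3),
                (26_000_000, 30_000_000, 4)]
        spiked_reads, truth = spike_truth(reads, plan, [], rng)
        spiked = spiked_reads.to_rd(GenomeBins("chr1", 30_000_000, 1000))
        ref1 = estimate_cn_reference(spiked, "diploid")
        med_shift = abs(np.nanmedian(spiked.values)
                        - np.nanmedian(base.values)) / np.nanmedian(base.values)
        assert med_shift > 0.02
        assert abs(ref1.rd_2n - ref0.rd_2n) / ref0.rd_2n < 0.01


class TestEvaluateCalls:
    def _truth(self):
        return TruthSet([
            TruthRegion("chr1", 1_000_000, 1_080_000, "FA", 2, 4),
            TruthRegion("chr1", 3_000_000, 3_060_000, "FA", 2, 1),
            TruthRegion("chr1", 5_000_000, 9_000_000, "LCV", 2, 3)])

    def test_perfect_calls_score_one(self):
        truth = self._truth()
        fa = pd.DataFrame([
            {"chromosome": "chr1", "start": 1_000_000, "end": 1_080_000,
             "mean_cn": 4.0, "direction": "amplification"},
            {"chromosome": "chr1", "start": 3_000_000, "end": 3_060_000,
             "mean_cn": 1.0, "direction": "deletion"}])
        lcv = pd.DataFrame([
            {"chromosome": "chr1", "start": 5_000_000, "end": 9_000_000,
             "mean_cn": 3.0, "cn_state": 3}])
        m = evaluate_calls(fa, lcv, truth)
        assert m["FA"]["recall"] == 1.0 and m["FA"]["precision"] == 1.0
        assert m["LCV"]["recall"] == 1.0
        assert m["FA"]["mean_abs_cn_error"] == 0.0

    def test_seventy_percent_overlap_unmatched(self):
        truth = self._truth()
        fa = pd.DataFrame([
            {"chromosome": "chr1", "start": 1_000_000, "end": 1_056_000,
             "mean_cn": 4.0, "direction": "amplification"}])  # 70% of truth
        m = evaluate_calls(fa, None, truth)
        assert m["FA"]["n_matched"] == 0

    def test_lcv_state_mismatch_not_matched(self):
        truth = self._truth()
        lcv = pd.DataFrame([
            {"chromosome": "chr1", "start": 5_000_000, "end": 9_000_000,
             "mean_cn": 4.0, "cn_state": 4}])
        m = evaluate_calls(None, lcv, truth)
        assert m["LCV"]["n_matched"] == 0

    def test_no_calls_convention(self):
        m = evaluate_calls(pd.DataFrame(), None, self._truth())
        assert m["FA"]["recall"] == 0.0
        assert m["FA"]["precision"] == 1.0
        assert m["FA"]["no_calls"] is True
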
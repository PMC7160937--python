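"""RD computation from alignments, GC correction, mappability masking."""

import numpy as np
import pysam
import pytest

from cnahier.bins import GenomeBins
from cnahier.rd import (RDProfile, apply_mappability_mask, compute_rd,
                        gc_correct, load_binned, write_bedgraph)

from conftest import make_profile


def write_sam(path, reads, chrom="chr1", length=1_000_000):
    """reads: list of (start, cigar_len, mapq, flag)."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": length}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, (start, rlen, mapq, flag) in enumerate(sorted(reads)):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"r{i}"
            a.reference_id = 0
            a.reference_start = start
            a.cigarstring = f"{rlen}M"
            a.mapping_quality = mapq
            a.flag = flag
            a.query_sequence = "A" * rlen
            out.write(a)


class TestComputeRD:
    def test_read_fully_inside_bin_contributes_fraction(self, tmp_path):
        sam = tmp_path / "a.sam"
        write_sam(sam, [(100, 100, 60, 0)])
        profile = compute_rd(str(sam), GenomeBins("chr1", 1_000_000, 1000))
        assert profile.rd[0] == pytest.approx(0.1)
        assert profile.rd[1:].sum() == 0

    def test_straddling_read_splits_proportionally(self, tmp_path):
        sam = tmp_path / "a.sam"
        write_sam(sam, [(940, 100, 60, 0)])  # 60 bp in bin 0, 40 in bin 1
        profile = compute_rd(str(sam), GenomeBins("chr1", 1_000_000, 1000))
        assert profile.rd[0] == pytest.approx(0.06)
        assert profile.rd[1] == pytest.approx(0.04)

    def test_filters_exclude_duplicates_secondary_low_mapq(self, tmp_path):
        sam = tmp_path / "a.sam"
        write_sam(sam, [(100, 100, 60, 0),
                        (100, 100, 60, 1024),   # duplicate
                        (100, 100, 60, 256),    # secondary
                        (100, 100, 0, 0)])      # mapq below threshold
        profile = compute_rd(str(sam), GenomeBins("chr1", 1_000_000, 1000),
                             min_mapq=1)
        assert profile.rd[0] == pytest.approx(0.1)

    def test_uniform_coverage_and_base_conservation(self, tmp_path, rng):
        # 10,000 reads of 100 bp uniform over 1 Mb -> ~1x coverage
        starts = rng.integers(0, 1_000_000 - 100, size=10_000)
        sam = tmp_path / "u.sam"
        write_sam(sam, [(int(s), 100, 60, 0) for s in starts])
        profile = compute_rd(str(sam), GenomeBins("chr1", 1_000_000, 1000))
        assert profile.coverage == pytest.approx(1.0, abs=0.05)
        # exact conservation: summed rd * bin_size == total aligned bases
        assert profile.rd.sum() * 1000 == pytest.approx(10_000 * 100)

    def test_chromosome_mismatch_raises(self, tmp_path):
        sam = tmp_path / "a.sam"
        write_sam(sam, [(100, 100, 60, 0)])
        with pytest.raises(KeyError, match="chrX"):
            compute_rd(str(sam), GenomeBins("chrX", 1_000_000, 1000))

    def test_unsorted_input_raises(self, tmp_path):
        sam = tmp_path / "a.sam"
        header = {"HD": {"VN": "1.6", "SO": "queryname"},
                  "SQ": [{"SN": "chr1", "LN": 1000}]}
        with pysam.AlignmentFile(str(sam), "w", header=header):
            pass
        with pytest.raises(ValueError, match="sorted"):
            compute_rd(str(sam), GenomeBins("chr1", 1000, 1000))


class TestGCCorrect:
    def _with_gc(self, rd, gc):
        p = make_profile(rd)
        p.bins.gc_fraction = np.asarray(gc, dtype=float)
        return p

    def test_uniform_gc_is_identity(self):
        p = self._with_gc(np.full(1000, 2.0), np.full(1000, 0.4))
        out = gc_correct(p)
        np.testing.assert_allclose(out.rd, p.rd)

    def test_two_strata_rescaled_to_common_median(self):
        rd = np.concatenate([np.full(500, 0.8), np.full(500, 1.2)])
        gc = np.concatenate([np.full(500, 0.3), np.full(500, 0.6)])
        out = gc_correct(self._with_gc(rd, gc), n_strata=2)
        assert np.median(out.rd[:500]) == pytest.approx(np.median(out.rd[500:]))
        # global median preserved within 1%
        assert np.median(out.rd) == pytest.approx(np.median(rd), rel=0.01)

    def test_linear_gc_bias_removed(self, rng):
        n = 20_000
        gc = np.repeat(rng.uniform(0.3, 0.7, n // 100), 100)
        rd = rng.poisson(2000 * (1 + 0.8 * (gc - 0.5)), n) / 1000
        out = gc_correct(self._with_gc(rd, gc))
        r_before = np.corrcoef(rd, gc)[0, 1]
        r_after = np.corrcoef(out.rd, gc)[0, 1]
        assert abs(r_before) > 0.5
        assert abs(r_after) < 0.1

    def test_scale_equivariance(self, rng):
        n = 5000
        gc = np.repeat(rng.uniform(0.3, 0.7, n // 100), 100)
        rd = rng.poisson(2000 * (1 + 0.5 * (gc - 0.5)), n) / 1000
        out1 = gc_correct(self._with_gc(rd, gc))
        out3 = gc_correct(self._with_gc(3.0 * rd, gc))
        np.testing.assert_allclose(out3.rd, 3.0 * out1.rd, rtol=1e-9)

    def test_small_stratum_left_uncorrected(self):
        rd = np.concatenate([np.full(500, 1.0), np.full(10, 37.0)])
        gc = np.concatenate([np.full(500, 0.4), np.full(10, 0.9)])
        out = gc_correct(self._with_gc(rd, gc), n_strata=2,
                         min_stratum_bins=20)
        np.testing.assert_allclose(out.rd[-10:], 37.0)


class TestMappabilityMask:
    def test_threshold_extremes(self, flat_profile):
        n = flat_profile.bins.n_bins
        track = np.linspace(0.01, 0.99, n)
        out0 = apply_mappability_mask(flat_profile.masked_copy(), 0.0,
                                      track=track)
        assert np.isfinite(out0.rd).sum() == np.isfinite(flat_profile.rd).sum()
        p = flat_profile.masked_copy()
        p.bins.masks["low_mappability"][:] = False
        out1 = apply_mappability_mask(p, 1.0, track=track)
        assert (~np.isfinite(out1.rd)).sum() == n  # every bin < 1

    def test_exact_low_mappability_set_masked(self, rng):
        p = make_profile(np.full(2000, 1.0))
        track = np.ones(2000)
        low = rng.choice(2000, size=100, replace=False)
        track[low] = 0.2
        out = apply_mappability_mask(p, 0.5, track=track)
        assert set(np.nonzero(~np.isfinite(out.rd))[0]) == set(low)

    def test_bad_threshold_raises(self, flat_profile):
        with pytest.raises(ValueError):
            apply_mappability_mask(flat_profile, 1.5)

    def test_masks_only_grow(self, flat_profile):
        p = flat_profile.masked_copy()
        track = np.linspace(0, 1, p.bins.n_bins)
        before = p.bins.combined_mask().copy()
        out = apply_mappability_mask(p, 0.3, track=track)
        after = out.bins.combined_mask()
        assert np.all(after[before])  # nothing unmasked


def test_bedgraph_round_trip(tmp_path, flat_profile):
    path = tmp_path / "p.bedgraph"
    flat_profile.rd[5] = np.nan
    write_bedgraph(flat_profile, str(path))
    back = load_binned(str(path))
    assert back.chromosome == flat_profile.chromosome
    obs = np.isfinite(flat_profile.values)
    np.testing.assert_allclose(back.rd[obs], flat_profile.rd[obs], rtol=1e-5)
    assert not np.isfinite(back.rd[5])
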
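"""Binned SV/CNV correlation: binning, signals, Pearson, reason codes."""

from __future__ import annotations

import numpy as np
import pytest

from fusiontriage import (
    FusionCandidate,
    GenomicInterval,
    bin_regions,
    cnv_signal,
    driver_correlation,
    sv_signal,
)
from fusiontriage.records import CNVSegment, SVCall
from fusiontriage.triage import SVHit

from _oracles import pearson_direct


def _fusion():
    return FusionCandidate(gene5="A", gene3="B")


def _hit(chrom, pos):
    call = SVCall("S", chrom, pos, "+", "99", 1, "-", "translocation")
    return SVHit(call, 5, 1)


def _bins_with_counts(counts, bin_size=10, chrom="1"):
    """Region tiled into len(counts) bins plus hits realizing the counts."""
    region = GenomicInterval(chrom, 1, bin_size * len(counts))
    bins = bin_regions(region, None, bin_size)
    hits = []
    for i, k in enumerate(counts):
        for j in range(k):
            hits.append(_hit(chrom, i * bin_size + 1 + j))
    return region, bins, hits


class TestBinning:
    def test_truncated_last_bin(self):
        region = GenomicInterval("1", 1, 25_000)
        bins = bin_regions(region, None, 10_000)
        assert [(b.start, b.end) for b in bins] == [
            (1, 10_000), (10_001, 20_000), (20_001, 25_000)
        ]

    def test_region_narrower_than_bin(self):
        bins = bin_regions(GenomicInterval("1", 100, 150), None, 10_000)
        assert len(bins) == 1 and (bins[0].start, bins[0].end) == (100, 150)

    def test_total_coverage_equals_region_widths(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            s5 = int(rng.integers(1, 10_000))
            s3 = int(rng.integers(1, 10_000))
            r5 = GenomicInterval("1", s5, s5 + int(rng.integers(0, 50_000)))
            r3 = GenomicInterval("2", s3, s3 + int(rng.integers(0, 50_000)))
            bins = bin_regions(r5, r3, int(rng.integers(100, 9_999)))
            assert sum(b.length for b in bins) == r5.length + r3.length

    def test_overlapping_regions_not_merged(self):
        r = GenomicInterval("1", 1, 1_000)
        bins = bin_regions(r, r, 100)
        assert len(bins) == 20  # both copies tiled independently


class TestSignals:
    def test_sv_counts_match_brute_recount(self):
        rng = np.random.default_rng(23)
        region = GenomicInterval("1", 1, 5_000)
        bins = bin_regions(region, None, 137)
        hits = [_hit("1", int(rng.integers(1, 5_001))) for _ in range(60)]
        x = sv_signal(bins, hits)
        for i, b in enumerate(bins):
            want = sum(1 for h in hits if b.start <= h.call.pos1 <= b.end)
            assert x[i] == want

    def test_duplicate_hit_entries_count_once(self):
        bins = bin_regions(GenomicInterval("1", 1, 100), None, 100)
        call = SVCall("S", "1", 50, "+", "99", 1, "-", "translocation")
        hits = [SVHit(call, 5, 1), SVHit(call, 3, 1)]  # same breakend, both windows
        assert sv_signal(bins, hits).tolist() == [1.0]

    def test_cnv_weighted_mean(self):
        bins = bin_regions(GenomicInterval("1", 1, 10_000), None, 10_000)
        segs = [
            CNVSegment("S", "1", 1, 5_000, "1", 1.0),
            CNVSegment("S", "1", 5_001, 10_000, "2", 0.0),
        ]
        y, informative = cnv_signal(bins, segs)
        assert informative.all()
        assert y[0] == pytest.approx(0.5)

    def test_cnv_signal_matches_per_bp_oracle(self):
        rng = np.random.default_rng(29)
        region = GenomicInterval("1", 1, 3_000)
        bins = bin_regions(region, None, 100)
        segs = []
        for _ in range(25):
            start = int(rng.integers(1, 2_900))
            segs.append(
                CNVSegment(
                    "S", "1", start, start + int(rng.integers(0, 400)), "1",
                    float(rng.normal(0, 0.5)),
                )
            )
        y, informative = cnv_signal(bins, segs)
        # per-base-pair accumulation oracle
        wsum = np.zeros(3_001)
        vsum = np.zeros(3_001)
        for seg in segs:
            lo, hi = seg.start, min(seg.end, 3_000)
            wsum[lo : hi + 1] += 1
            vsum[lo : hi + 1] += seg.segmean
        for i, b in enumerate(bins):
            w = wsum[b.start : b.end + 1].sum()
            if w == 0:
                assert not informative[i]
            else:
                assert informative[i]
                assert y[i] == pytest.approx(
                    vsum[b.start : b.end + 1].sum() / w, abs=1e-9
                )

    def test_no_hits_gives_zero_vector(self):
        bins = bin_regions(GenomicInterval("1", 1, 1_000), None, 100)
        assert not sv_signal(bins, []).any()


class TestDriverCorrelation:
    def _segments_for(self, values, bin_size=10, chrom="1"):
        return [
            CNVSegment("S", chrom, i * bin_size + 1, (i + 1) * bin_size, "1", v)
            for i, v in enumerate(values)
        ]

    def test_colinear_signals_give_r_one(self):
        region, _, hits = _bins_with_counts([1, 2, 3])
        segs = self._segments_for([2.0, 4.0, 6.0])
        result = driver_correlation(_fusion(), (region, None), hits, segs, 10)
        assert result.reason == "ok"
        assert result.r == pytest.approx(1.0)

    def test_anticolinear_signals_give_r_minus_one(self):
        region, _, hits = _bins_with_counts([1, 2, 3])
        segs = self._segments_for([3.0, 2.0, 1.0])
        result = driver_correlation(_fusion(), (region, None), hits, segs, 10)
        assert result.r == pytest.approx(-1.0)

    def test_matches_direct_formula_on_random_signals(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            n = int(rng.integers(5, 30))
            counts = [int(k) for k in rng.integers(0, 6, size=n)]
            if len(set(counts)) == 1:
                counts[0] += 1
            values = [float(v) for v in rng.normal(0, 1, size=n)]
            region, _, hits = _bins_with_counts(counts)
            segs = self._segments_for(values)
            result = driver_correlation(_fusion(), (region, None), hits, segs, 10)
            assert result.reason == "ok"
            assert result.r == pytest.approx(
                pearson_direct(counts, values), abs=1e-10
            )

    def test_too_few_informative_bins(self):
        region, _, hits = _bins_with_counts([1, 2, 3])
        segs = self._segments_for([0.5])  # only bin 1 covered
        result = driver_correlation(_fusion(), (region, None), hits, segs, 10)
        assert result.r is None and result.reason == "too_few_bins"

    def test_constant_signal_is_zero_variance_not_zero(self):
        region, _, hits = _bins_with_counts([1, 1, 1])
        segs = self._segments_for([1.0, 2.0, 3.0])
        result = driver_correlation(_fusion(), (region, None), hits, segs, 10)
        assert result.r is None and result.reason == "zero_variance"

    def test_result_counts_bins(self):
        region, bins, hits = _bins_with_counts([1, 0, 2, 0])
        segs = self._segments_for([0.1, 0.2, 0.3])  # last bin uncovered
        result = driver_correlation(_fusion(), (region, None), hits, segs, 10)
        assert result.n_bins_total == 4
        assert result.n_bins_informative == 3

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(37)
        counts = [int(k) for k in rng.integers(0, 5, size=12)]
        counts[0] += 1
        values = [float(v) for v in rng.normal(0, 1, size=12)]
        region, _, hits = _bins_with_counts(counts)
        base = driver_correlation(
            _fusion(), (region, None), hits, self._segments_for(values), 10
        ).r
        scaled = driver_correlation(
            _fusion(), (region, None), hits,
            self._segments_for([3.0 * v + 7.0 for v in values]), 10,
        ).r
        flipped = driver_correlation(
            _fusion(), (region, None), hits,
            self._segments_for([-2.0 * v for v in values]), 10,
        ).r
        assert scaled == pytest.approx(base, abs=1e-12)
        assert flipped == pytest.approx(-base, abs=1e-12)

    def test_spearman_available(self):
        region, _, hits = _bins_with_counts([1, 2, 3])
        segs = self._segments_for([1.0, 10.0, 100.0])  # monotone, not linear
        result = driver_correlation(
            _fusion(), (region, None), hits, segs, 10, method="spearman"
        )
        assert result.r == pytest.approx(1.0)
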
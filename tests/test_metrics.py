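"""Pol2 positional metrics: pileup conservation, ratio conventions, strand
symmetry, and the small study arithmetic."""

import numpy as np
import pytest

from aquahichip.metrics import (
    MetricWindows,
    coverage_from_pairs,
    fold_change,
    gene_metrics,
    loading_ratio,
    pause_ratio,
    segment_deltas,
    tumor_volume,
)
from aquahichip.model import (
    ContactPairSet,
    ContactRecord,
    CoverageTrack,
    GeneModel,
    GenomicInterval,
)


def _gene(start=10_000, end=20_000, strand="+", chrom="chr1"):
    return GeneModel(GenomicInterval(chrom, start, end), strand, "G")


def _uniform_track(n_bins=4_000, bin_size=10, value=5.0):
    return CoverageTrack("chr1", bin_size, np.full(n_bins, value))


class TestCoverageFromPairs:
    def test_two_ended_pileup_single_record(self):
        rec = ContactRecord(
            GenomicInterval("chr1", 100, 150), GenomicInterval("chr1", 1_000, 1_050)
        )
        (trk,) = coverage_from_pairs(
            ContactPairSet.from_records([rec]), bin_size=200
        )
        assert trk.total_mass == pytest.approx(2.0)
        assert trk.signal(GenomicInterval("chr1", 0, 200)) == pytest.approx(1.0)
        assert trk.signal(GenomicInterval("chr1", 1_000, 1_200)) == pytest.approx(1.0)

    def test_empty_pairs_give_no_tracks(self):
        assert coverage_from_pairs(ContactPairSet.empty()) == []

    def test_total_mass_is_twice_count_sum(self, rng):
        recs = [
            ContactRecord(
                GenomicInterval("chr1", int(s), int(s) + int(w)),
                GenomicInterval("chr1", int(s) + 5_000, int(s) + 5_000 + int(w)),
                count=int(c),
            )
            for s, w, c in zip(
                rng.integers(0, 50_000, 200),
                rng.integers(50, 2_000, 200),
                rng.integers(1, 6, 200),
            )
        ]
        pairs = ContactPairSet.from_records(recs)
        tracks = coverage_from_pairs(pairs, bin_size=75)
        total = sum(t.total_mass for t in tracks)
        assert total == pytest.approx(2 * sum(r.count for r in recs))


class TestRatios:
    def test_uniform_track_gives_unit_ratios(self):
        trk = _uniform_track()
        for strand in "+-":
            g = _gene(strand=strand)
            assert pause_ratio(trk, g) == pytest.approx(1.0)
            assert loading_ratio(trk, g) == pytest.approx(1.0)

    def test_pseudocount_formula_on_silent_downstream(self):
        # promoter+body density 1.0, nothing past the TES, eps=0.1 -> 1.1/0.1 = 11
        bin_size = 10
        values = np.zeros(3_000)
        g = _gene(start=10_000, end=20_000, strand="+")
        values[(10_000 - 1_000) // bin_size : 20_000 // bin_size] = bin_size * 1.0
        trk = CoverageTrack("chr1", bin_size, values)
        assert loading_ratio(trk, g, MetricWindows(epsilon=0.1)) == pytest.approx(11.0)

    def test_strand_mirror_symmetry(self):
        # minus-strand gene on the mirrored track equals the plus-strand result
        size = 40_000
        bin_size = 10
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 10, size // bin_size)
        fwd = CoverageTrack("chr1", bin_size, vals)
        rev = CoverageTrack("chr1", bin_size, vals[::-1].copy())
        gp = _gene(start=10_000, end=20_000, strand="+")
        gm = GeneModel(
            GenomicInterval("chr1", size - 20_000, size - 10_000), "-", "G"
        )
        w = MetricWindows()
        assert pause_ratio(fwd, gp, w) == pytest.approx(pause_ratio(rev, gm, w))
        assert loading_ratio(fwd, gp, w) == pytest.approx(loading_ratio(rev, gm, w))

    def test_density_convention_is_scale_invariant(self):
        w = MetricWindows(epsilon=0.0)
        rng = np.random.default_rng(1)
        vals = rng.uniform(0.5, 10, 4_000)
        g = _gene()
        t1 = CoverageTrack("chr1", 10, vals)
        t2 = CoverageTrack("chr1", 10, 7.3 * vals)
        assert pause_ratio(t1, g, w) == pytest.approx(pause_ratio(t2, g, w))
        assert loading_ratio(t1, g, w) == pytest.approx(loading_ratio(t2, g, w))

    def test_gene_too_short_for_body_window(self):
        g = _gene(start=10_000, end=10_200)
        with pytest.raises(ValueError, match="too short"):
            pause_ratio(_uniform_track(), g)

    def test_post_tes_truncated_at_track_edge_with_warning(self):
        trk = _uniform_track(n_bins=2_100)  # track ends at 21 kb
        g = _gene(start=10_000, end=20_000)  # post-TES window 20-23 kb
        with pytest.warns(UserWarning, match="truncated"):
            r = loading_ratio(trk, g)
        assert r == pytest.approx(1.0)

    def test_gene_metrics_record_matches_components(self):
        trk = _uniform_track()
        m = gene_metrics(trk, _gene())
        assert m.pause_ratio == pytest.approx(1.0)
        assert m.body_density == pytest.approx(0.5)  # 5 mass / 10 bp bins


class TestSegmentDeltas:
    SEGS = {
        "a": GenomicInterval("chr1", 0, 1_000),
        "b": GenomicInterval("chr1", 1_000, 3_000),
    }

    def test_identical_tracks_give_zero_deltas(self):
        trk = _uniform_track()
        df = segment_deltas(trk, trk, self.SEGS)
        assert (df["delta"] == 0).all() and (df["log2_ratio"] == 0).all()

    def test_doubling_gives_log2_one(self):
        t1 = _uniform_track(value=100.0)
        t2 = _uniform_track(value=200.0)
        df = segment_deltas(t1, t2, self.SEGS, epsilon=1e-9)
        assert df["log2_ratio"].to_numpy() == pytest.approx([1.0, 1.0])

    def test_mismatched_binning_rejected(self):
        t1 = _uniform_track(bin_size=10)
        t2 = CoverageTrack("chr1", 20, np.ones(10))
        with pytest.raises(ValueError, match="bin size"):
            segment_deltas(t1, t2, self.SEGS)


class TestStudyArithmetic:
    @pytest.mark.parametrize(
        "l,w,expected", [(2, 1, 1.0), (10, 10, 500.0), (3, 3, 0.5 * 27)]
    )
    def test_tumor_volume_formula(self, l, w, expected):
        assert tumor_volume(l, w) == pytest.approx(expected)

    def test_tumor_volume_swaps_when_width_exceeds_length(self):
        with pytest.warns(UserWarning, match="swapping"):
            assert tumor_volume(1, 2) == tumor_volume(2, 1)

    def test_tumor_volume_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            tumor_volume(0, 1)

    @pytest.mark.parametrize("a,b,expected", [(5, 5, 1.0), (0, 5, 0.0)])
    def test_fold_change_basic(self, a, b, expected):
        assert fold_change(a, b) == expected

    def test_fold_change_rejects_zero_denominator(self):
        with pytest.raises(ValueError):
            fold_change(1, 0)
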
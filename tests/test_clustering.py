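"""Loop filtering, shared-anchor clustering vs a brute-force oracle,
connectivity ranking, and APA."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aquahichip.aqua import AquaFactors
from aquahichip.clustering import (
    FilterThresholds,
    anchors_connected,
    apa,
    cluster_loops,
    filter_loops,
    rank_components,
    short_range_candidates,
)
from aquahichip.model import ContactPairSet, ContactRecord, GenomicInterval, Loop

from helpers import oracle_partition, partition_of, random_loops

FACTORS = AquaFactors("s", 0, 10**6)  # scale 1.0


def _iv(s, e, chrom="chr1"):
    return GenomicInterval(chrom, s, e)


def _loop(s1, s2, cpm=10.0, chrom="chr1", width=100):
    return Loop(_iv(s1, s1 + width, chrom), _iv(s2, s2 + width, chrom), raw_count=1, aqua_cpm=cpm)


class TestFilterLoops:
    def test_distance_band(self):
        t = FilterThresholds(min_distance=5_000, max_distance=2_000_000)
        loops = [_loop(0, 1_000), _loop(0, 50_000), _loop(0, 3_000_000, width=100)]
        kept = filter_loops(loops, t)
        assert [lp.distance for lp in kept] == [50_000]

    def test_permissive_thresholds_are_identity_on_cis(self):
        t = FilterThresholds(min_distance=0, max_distance=10**9, min_aqua_cpm=0)
        loops = [_loop(0, 1_000), _loop(0, 50_000)]
        assert filter_loops(loops, t) == loops

    def test_trans_loops_always_dropped(self):
        t = FilterThresholds(min_distance=0, max_distance=10**9, min_aqua_cpm=0)
        trans = Loop(_iv(0, 100, "chr1"), _iv(0, 100, "chr2"), raw_count=1, aqua_cpm=5.0)
        assert filter_loops([trans], t) == []

    @given(st.floats(0, 20))
    def test_raising_cpm_threshold_never_adds_survivors(self, cut):
        rng = np.random.default_rng(7)
        loops = random_loops(rng, 30, coord_max=500_000)
        lo = filter_loops(loops, FilterThresholds(0, 10**9, min_aqua_cpm=cut))
        hi = filter_loops(loops, FilterThresholds(0, 10**9, min_aqua_cpm=cut + 1))
        assert len(hi) <= len(lo)
        assert set(lp.key() for lp in hi) <= set(lp.key() for lp in lo)

    def test_short_range_candidates_reported_separately(self):
        t = FilterThresholds(min_distance=5_000, max_distance=10**6)
        loops = [_loop(0, 1_000), _loop(0, 50_000)]
        assert short_range_candidates(loops, t) == [loops[0]]


class TestAnchorsConnected:
    def test_overlap_and_half_open_boundary(self):
        assert anchors_connected(_iv(100, 200), _iv(150, 300))
        assert not anchors_connected(_iv(100, 200), _iv(200, 300), pad=0)
        assert anchors_connected(_iv(100, 200), _iv(200, 300), pad=1)

    @given(
        st.integers(0, 5_000),
        st.integers(1, 500),
        st.integers(0, 5_000),
        st.integers(1, 500),
        st.sampled_from([0, 1, 500]),
    )
    def test_symmetric(self, s1, w1, s2, w2, pad):
        a, b = _iv(s1, s1 + w1), _iv(s2, s2 + w2)
        assert anchors_connected(a, b, pad) == anchors_connected(b, a, pad)


class TestClusterLoops:
    T = FilterThresholds(min_loops=2)

    def test_shared_anchor_chain_and_disjoint_pair(self):
        a, b, c = _iv(0, 100), _iv(10_000, 10_100), _iv(20_000, 20_100)
        d, e = _iv(100_000, 100_100), _iv(110_000, 110_100)
        ab = Loop(a, b, raw_count=1)
        bc = Loop(b, c, raw_count=1)
        de = Loop(d, e, raw_count=1)
        comps = cluster_loops([ab, bc, de], self.T)
        parts = partition_of(comps, [ab, bc, de])
        assert parts == {frozenset({0, 1}), frozenset({2})}
        labels = {c.n_loops: c.label for c in comps}
        assert labels == {2: "cluster", 1: "loop"}

    def test_single_loop_is_class_loop(self):
        (comp,) = cluster_loops([_loop(0, 10_000)], self.T)
        assert comp.label == "loop" and comp.n_loops == 1

    @pytest.mark.parametrize("k", [2, 5, 17, 50])
    def test_chain_of_k_shared_anchors_is_one_cluster(self, k, rng):
        anchors = []
        pos = 0
        for _ in range(k + 1):
            anchors.append(_iv(pos, pos + 500))
            pos += int(rng.integers(2_000, 9_000))
        chain = [Loop(anchors[i], anchors[i + 1], raw_count=1) for i in range(k)]
        comps = cluster_loops(chain, FilterThresholds(min_loops=k))
        assert len(comps) == 1
        assert comps[0].label == "cluster" and comps[0].n_loops == k

    @pytest.mark.parametrize("pad", [0, 500])
    def test_matches_bruteforce_oracle_on_random_instances(self, pad, rng):
        for _ in range(25):
            loops = random_loops(rng, int(rng.integers(1, 51)))
            comps = cluster_loops(loops, self.T, pad=pad)
            assert partition_of(comps, loops) == oracle_partition(loops, pad)

    def test_partition_conserves_loops_and_ids_dense(self, rng):
        loops = random_loops(rng, 40)
        comps = cluster_loops(loops, self.T)
        assert sum(c.n_loops for c in comps) == len(loops)
        assert [c.component_id for c in comps] == list(range(len(comps)))
        starts = [c.boundary.start for c in comps]
        assert starts == sorted(starts)

    def test_boundary_contains_every_member_anchor(self, rng):
        loops = random_loops(rng, 30)
        for comp in cluster_loops(loops, self.T):
            for a in comp.anchors:
                assert comp.boundary.contains(a)

    def test_chromosomes_never_mix(self):
        l1 = _loop(0, 10_000, chrom="chr1")
        l2 = _loop(0, 10_000, chrom="chr2")
        comps = cluster_loops([l1, l2], self.T)
        assert len(comps) == 2


def _pairs_from(records):
    return ContactPairSet.from_records(records)


class TestRankComponents:
    def _setup(self):
        left = [_loop(0, 10_000), _loop(10_000, 20_000)]
        right = [_loop(100_000, 110_000), _loop(110_000, 120_000)]
        comps = cluster_loops(left + right, FilterThresholds(min_loops=2))
        return comps

    def _contact(self, s1, s2, count=1):
        return ContactRecord(_iv(s1, s1 + 100), _iv(s2, s2 + 100), count=count)

    def test_ordering_by_contained_cpm_sum(self):
        comps = self._setup()
        pairs = _pairs_from(
            [self._contact(100, 5_000, count=50), self._contact(100_100, 105_000, count=30)]
        )
        ranked = rank_components(comps, pairs, FACTORS)
        assert [c.connectivity for c in ranked] == [50.0, 30.0]
        assert [c.rank for c in ranked] == [1, 2]

    def test_component_without_contacts_ranks_last(self):
        comps = self._setup()
        pairs = _pairs_from([self._contact(100, 5_000, count=5)])
        ranked = rank_components(comps, pairs, FACTORS)
        assert ranked[-1].connectivity == 0.0

    def test_outside_contacts_do_not_count(self):
        comps = self._setup()
        base = [self._contact(100, 5_000, count=5)]
        outside = base + [self._contact(500_000, 510_000, count=99)]
        r1 = rank_components(self._setup(), _pairs_from(base), FACTORS)
        r2 = rank_components(self._setup(), _pairs_from(outside), FACTORS)
        assert [c.connectivity for c in r1] == [c.connectivity for c in r2]

    def test_rank_invariant_to_input_order(self, rng):
        loops = random_loops(rng, 30, coord_max=200_000)
        recs = [
            self._contact(int(s), int(s) + 2_000, count=int(c))
            for s, c in zip(rng.integers(0, 200_000, 100), rng.integers(1, 5, 100))
        ]
        pairs = _pairs_from(recs)
        t = FilterThresholds(min_loops=2)
        fwd = rank_components(cluster_loops(loops, t), pairs, FACTORS)
        rev = rank_components(cluster_loops(loops[::-1], t), pairs, FACTORS)
        key = lambda c: (c.boundary.start, c.boundary.end, round(c.connectivity, 9))
        assert [key(c) for c in fwd] == [key(c) for c in rev]


class TestApa:
    def _single(self):
        lp = Loop(_iv(100_000, 101_000), _iv(200_000, 201_000), raw_count=1)
        rec = ContactRecord(_iv(100_400, 100_600), _iv(200_400, 200_600))
        return lp, _pairs_from([rec])

    def test_center_cell_catches_midpoint_contact(self):
        lp, pairs = self._single()
        m = apa([lp], pairs, FACTORS, bin_size=1_000, n_bins=5)
        assert m.center_value == 1.0
        assert m.total_mass == 1.0

    def test_no_contacts_gives_zero_matrix(self):
        lp, _ = self._single()
        m = apa([lp], ContactPairSet.empty(), FACTORS, bin_size=1_000, n_bins=5)
        assert m.total_mass == 0.0

    def test_duplicating_loops_leaves_matrix_unchanged(self):
        lp, pairs = self._single()
        m1 = apa([lp], pairs, FACTORS, bin_size=1_000, n_bins=5)
        m2 = apa([lp, lp], pairs, FACTORS, bin_size=1_000, n_bins=5)
        assert np.array_equal(m1.matrix, m2.matrix)

    def test_zero_loops_and_even_bins_rejected(self):
        _, pairs = self._single()
        with pytest.raises(ValueError):
            apa([], pairs, FACTORS)
        with pytest.raises(ValueError):
            apa([self._single()[0]], pairs, FACTORS, n_bins=4)

    def test_mass_conservation_against_bruteforce_window_sum(self, rng):
        loops = random_loops(rng, 10, coord_max=300_000)
        recs = [
            ContactRecord(
                _iv(int(s), int(s) + 100), _iv(int(s) + int(d), int(s) + int(d) + 100)
            )
            for s, d in zip(rng.integers(0, 300_000, 200), rng.integers(1_000, 50_000, 200))
        ]
        pairs = _pairs_from(recs)
        bin_size, n_bins = 2_000, 7
        m = apa(loops, pairs, FACTORS, bin_size=bin_size, n_bins=n_bins)
        half = n_bins // 2
        expected = 0.0
        for lp in loops:
            for r in recs:
                ok = True
                for anchor_mid, pos in (
                    (lp.anchor1.mid, r.anchor1.mid),
                    (lp.anchor2.mid, r.anchor2.mid),
                ):
                    w0 = anchor_mid - half * bin_size - bin_size // 2
                    idx = (pos - w0) // bin_size
                    ok = ok and 0 <= idx < n_bins
                if ok:
                    expected += r.count * FACTORS.scale
        assert m.total_mass * len(loops) == pytest.approx(expected)
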
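"""Junction calling, merging and filtering: examples and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circdif.circles import (
    MergeParameters,
    call_junctions,
    filter_circles,
    merge_circles,
)
from circdif.formats import CircleRecord, SplitReadAlignment
from circdif.synthgen import SimulationConfig, simulate_cohort, simulate_split_reads


def _aln(s1, e1, s2, e2, chrom="chr1", rid="r1", sid="S"):
    return SplitReadAlignment(rid, chrom, s1, e1, s2, e2, "+", sid)


class TestCallJunctions:
    def test_inverted_segments_give_circle(self):
        # segment1 downstream of segment2 evidences the circular junction
        (c,) = call_junctions([_aln(1990, 2090, 1000, 1100)])
        assert (c.chrom, c.start, c.end, c.split_reads) == ("chr1", 1000, 2090, 1)

    def test_collinear_segments_give_no_circle(self):
        assert call_junctions([_aln(1000, 1100, 1990, 2090)]) == []

    def test_min_non_overlap_boundary(self):
        # segments overlap all but 5 bp each: below the 10 bp threshold
        assert call_junctions([_aln(105, 205, 100, 200)], min_non_overlap=10) == []
        # exactly 10 bp of unique span on each side passes
        (c,) = call_junctions([_aln(110, 210, 100, 200)], min_non_overlap=10)
        assert (c.start, c.end) == (100, 210)

    def test_identical_junctions_aggregate_per_sample(self):
        reads = [_aln(1990, 2090, 1000, 1100, rid=f"r{i}") for i in range(4)]
        (c,) = call_junctions(reads)
        assert c.split_reads == 4
        # different samples stay separate
        reads[0] = _aln(1990, 2090, 1000, 1100, rid="rx", sid="OTHER")
        assert len(call_junctions(reads)) == 2


class TestMerge:
    def test_linked_pair_collapses_to_top_support_representative(self):
        a = CircleRecord("chr1", 100, 500, 2, "S")
        b = CircleRecord("chr1", 105, 495, 3, "S")
        (m,) = merge_circles([a, b], MergeParameters(d_min=10))
        assert (m.start, m.end, m.split_reads) == (105, 495, 5)

    def test_end_distance_at_d_min_not_linked(self):
        a = CircleRecord("chr1", 100, 500, 2, "S")
        b = CircleRecord("chr1", 100, 520, 2, "S")
        assert len(merge_circles([a, b], MergeParameters(d_min=10))) == 2

    def test_empty_input(self):
        assert merge_circles([]) == []

    @pytest.fixture()
    def random_circles(self):
        rng = np.random.default_rng(7)
        out = []
        for i in range(1000):
            start = int(rng.integers(0, 50_000))
            length = int(rng.integers(100, 2_000))
            out.append(CircleRecord("chr1", start, start + length,
                                    int(rng.integers(1, 10)), "S"))
        return out

    def test_idempotence(self, random_circles):
        once = merge_circles(random_circles)
        assert merge_circles(once) == once

    def test_split_read_conservation(self, random_circles):
        merged = merge_circles(random_circles)
        assert (sum(c.split_reads for c in merged)
                == sum(c.split_reads for c in random_circles))

    def test_permutation_invariance(self, random_circles):
        rng = np.random.default_rng(8)
        shuffled = list(random_circles)
        rng.shuffle(shuffled)
        assert merge_circles(shuffled) == merge_circles(random_circles)

    @given(st.lists(
        st.tuples(st.integers(0, 300), st.integers(1, 100), st.integers(1, 5)),
        max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_conservation_and_idempotence_property(self, raw):
        circles = [CircleRecord("chr1", s, s + l, sr, "S") for s, l, sr in raw]
        merged = merge_circles(circles)
        assert sum(c.split_reads for c in merged) == sum(c.split_reads for c in circles)
        assert merge_circles(merged) == merged


class TestFilter:
    def test_low_support_removed(self):
        res = filter_circles([CircleRecord("chr1", 0, 1000, 1, "S")])
        assert res.circles == [] and res.removed["low_support"] == 1

    def test_mitochondrial_removed(self):
        res = filter_circles([CircleRecord("chrM", 0, 16000, 50, "S")])
        assert res.circles == [] and res.removed["excluded_chrom"] == 1

    def test_toy_set_counts(self):
        circles = [
            CircleRecord("chr1", 0, 500, 3, "S"),
            CircleRecord("chr2", 10, 900, 2, "S"),
            CircleRecord("chr3", 5, 4000, 8, "S"),
            CircleRecord("chr1", 0, 300, 1, "S"),        # low support
            CircleRecord("chr1", 0, 150_000, 5, "S"),    # > 100 kbp
            CircleRecord("chrM", 0, 16_000, 9, "S"),     # mitochondrial
        ]
        res = filter_circles(circles)
        assert len(res.circles) == 3
        assert res.removed == {"low_support": 1, "too_long": 1, "excluded_chrom": 1}

    def test_idempotence(self, small_cohort):
        circles = [c for recs in small_cohort.circles.values() for c in recs]
        once = filter_circles(circles)
        again = filter_circles(once.circles)
        assert again.circles == once.circles
        assert sum(again.removed.values()) == 0


def test_call_and_merge_recover_each_planted_circle():
    """With <= 2 bp junction jitter, calling + merging yields exactly one
    circle per planted circle, with all supporting reads pooled."""
    cfg = SimulationConfig(seed=21, baseline_circles_per_sample=100, n_genes=50)
    ds = simulate_cohort(cfg)
    reads = simulate_split_reads(ds, reads_per_circle=3)
    merged = merge_circles(call_junctions(reads))
    planted = [c for recs in ds.circles.values() for c in recs]
    assert len(merged) == len(planted)
    assert all(c.split_reads == 3 for c in merged)
    # every merged circle sits within jitter of a planted junction
    by_sample = {}
    for c in planted:
        by_sample.setdefault(c.sample_id, []).append(c)
    for m in merged:
        assert any(p.chrom == m.chrom and abs(p.start - m.start) <= 2
                   and abs(p.end - m.end) <= 4
                   for p in by_sample[m.sample_id])
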
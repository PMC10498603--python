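"""Gene annotation, PpGC computation and full-gene detection."""

import numpy as np
import pandas as pd
import pytest

from circdif.formats import CircleRecord, GeneModel
from circdif.ppgc import annotate_circles, compute_ppgc, full_gene_summary


def _gene(gid, start, end, chrom="chr1", coding=True):
    return GeneModel(gid, chrom, start, end, coding=coding)


class TestAnnotate:
    def test_one_bp_overlap_assigned(self):
        circle = CircleRecord("chr1", 100, 600, 2, "S")
        (a,) = annotate_circles([circle], [_gene("A", 599, 900)])
        assert a.overlap_bp == 1 and not a.full_gene

    def test_zero_overlap_not_assigned(self):
        circle = CircleRecord("chr1", 100, 600, 2, "S")
        assert annotate_circles([circle], [_gene("A", 600, 900)]) == []

    def test_multi_gene_circle_yields_one_assignment_per_gene(self):
        circle = CircleRecord("chr1", 0, 10_000, 2, "S")
        genes = [_gene("A", 100, 200), _gene("B", 5_000, 20_000)]
        asg = annotate_circles([circle], genes)
        assert sorted(a.gene_id for a in asg) == ["A", "B"]
        flags = {a.gene_id: a.full_gene for a in asg}
        assert flags == {"A": True, "B": False}

    def test_matches_quadratic_brute_force(self, rng):
        genes = []
        for i in range(50):
            start = int(rng.integers(0, 100_000))
            genes.append(_gene(f"G{i}", start, start + int(rng.integers(100, 5_000))))
        circles = []
        for j in range(200):
            start = int(rng.integers(0, 100_000))
            circles.append(CircleRecord("chr1", start,
                                        start + int(rng.integers(50, 8_000)),
                                        int(rng.integers(1, 6)), "S"))
        fast = {(a.gene_id, id(a.circle), a.overlap_bp, a.full_gene)
                for a in annotate_circles(circles, genes)}
        brute = set()
        for g in genes:
            for c in circles:
                ov = min(c.end, g.end) - max(c.start, g.start)
                if ov >= 1:
                    brute.add((g.gene_id, id(c), ov,
                               c.start <= g.start and c.end >= g.end))
        assert fast == brute


class TestComputePpGC:
    def test_hand_computed_example(self):
        genes = [_gene("A", 0, 1_000), _gene("B", 10_000, 12_000)]
        circles = [CircleRecord("chr1", 0, 500, 2, "S"),
                   CircleRecord("chr1", 100, 900, 3, "S"),
                   CircleRecord("chr1", 10_000, 11_000, 4, "S")]
        mat = compute_ppgc(annotate_circles(circles, genes), genes, ["S"])
        assert mat.l_max == 2_000
        assert mat.raw.loc["A", "S"] == 5 and mat.raw.loc["B", "S"] == 4
        assert mat.scaled.loc["A", "S"] == pytest.approx(10.0)
        assert mat.scaled.loc["B", "S"] == pytest.approx(4.0)
        assert mat.final.loc["A", "S"] == pytest.approx(np.log2(11), abs=1e-4)
        assert mat.final.loc["B", "S"] == pytest.approx(np.log2(5), abs=1e-4)

    def test_gene_without_circles_is_zero(self):
        genes = [_gene("A", 0, 1_000), _gene("B", 5_000, 6_000)]
        circles = [CircleRecord("chr1", 0, 500, 2, "S")]
        mat = compute_ppgc(annotate_circles(circles, genes), genes, ["S"])
        assert mat.final.loc["B", "S"] == 0.0

    def test_global_length_scaling_invariance(self, rng):
        """Doubling every gene length (same assignments) leaves the final
        PpGC unchanged: L_Max/L_i is scale-free."""
        genes = [_gene(f"G{i}", i * 10_000, i * 10_000 + 1_000 * (i + 1))
                 for i in range(5)]
        doubled = [_gene(g.gene_id, g.start, g.start + 2 * g.length) for g in genes]
        circles = [CircleRecord("chr1", g.start, g.start + 100,
                                int(rng.integers(1, 8)), "S") for g in genes]
        m1 = compute_ppgc(annotate_circles(circles, genes), genes, ["S"])
        # same raw assignments by construction (circles sit at gene starts)
        m2 = compute_ppgc(annotate_circles(circles, doubled), doubled, ["S"])
        pd.testing.assert_frame_equal(m1.final, m2.final)

    def test_adding_a_circle_never_decreases_final(self):
        genes = [_gene("A", 0, 1_000)]
        base = [CircleRecord("chr1", 0, 500, 2, "S")]
        extra = base + [CircleRecord("chr1", 400, 800, 1, "S")]
        m1 = compute_ppgc(annotate_circles(base, genes), genes, ["S"])
        m2 = compute_ppgc(annotate_circles(extra, genes), genes, ["S"])
        assert (m2.final.to_numpy() >= m1.final.to_numpy()).all()

    def test_l_max_source_switch(self):
        genes = [_gene("A", 0, 1_000), _gene("HUGE", 20_000, 120_000)]
        circles = [CircleRecord("chr1", 0, 500, 2, "S")]   # only A detected
        asg = annotate_circles(circles, genes)
        assert compute_ppgc(asg, genes, ["S"], "detected").l_max == 1_000
        assert compute_ppgc(asg, genes, ["S"], "annotation").l_max == 100_000

    def test_empty_assignments_warn_and_zero(self):
        genes = [_gene("A", 0, 1_000)]
        with pytest.warns(UserWarning, match="all zeros"):
            mat = compute_ppgc([], genes, ["S"])
        assert (mat.final.to_numpy() == 0).all()

    def test_brute_force_raw_sums(self, rng):
        genes = [_gene(f"G{i}", int(i * 2_000), int(i * 2_000 + 1_500))
                 for i in range(50)]
        circles = []
        for j in range(200):
            start = int(rng.integers(0, 100_000))
            circles.append(CircleRecord("chr1", start,
                                        start + int(rng.integers(50, 5_000)),
                                        int(rng.integers(1, 6)),
                                        f"S{j % 3}"))
        samples = ["S0", "S1", "S2"]
        mat = compute_ppgc(annotate_circles(circles, genes), genes, samples)
        for g in genes:
            for s in samples:
                expected = sum(c.split_reads for c in circles
                               if c.sample_id == s
                               and min(c.end, g.end) - max(c.start, g.start) >= 1)
                assert mat.raw.loc[g.gene_id, s] == expected


class TestFullGenes:
    def test_containment_flags(self):
        gene = _gene("A", 2_000, 8_000)
        full = CircleRecord("chr1", 0, 10_000, 2, "S1")
        partial = CircleRecord("chr1", 2_500, 8_000, 2, "S2")
        summary = full_gene_summary(
            annotate_circles([full, partial], [gene]), [gene], ["S1", "S2"])
        assert bool(summary.presence.loc["A", "S1"]) is True
        assert bool(summary.presence.loc["A", "S2"]) is False

    def test_group_fractions_and_sem(self):
        genes = [_gene(f"G{i}", i * 1_000, i * 1_000 + 500) for i in range(10)]
        # sample S1 fully carries G0; S2 fully carries G0 and G1
        circles = [CircleRecord("chr1", 0, 600, 2, "S1"),
                   CircleRecord("chr1", 0, 600, 2, "S2"),
                   CircleRecord("chr1", 900, 1_600, 2, "S2")]
        summary = full_gene_summary(annotate_circles(circles, genes), genes,
                                    ["S1", "S2"], groups={"S1": "g", "S2": "g"})
        assert summary.fractions["S1"] == pytest.approx(0.1)
        assert summary.fractions["S2"] == pytest.approx(0.2)
        assert summary.group_stats.loc["g", "mean"] == pytest.approx(0.15)
        assert summary.group_stats.loc["g", "sem"] == pytest.approx(0.05)

    def test_coding_split(self):
        genes = [_gene("A", 0, 100, coding=True), _gene("B", 200, 300, coding=False)]
        circles = [CircleRecord("chr1", 0, 400, 2, "S")]
        summary = full_gene_summary(annotate_circles(circles, genes), genes, ["S"])
        assert summary.coding_counts.to_dict() == {"coding": 1, "non_coding": 1}
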
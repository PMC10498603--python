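"""DifCir differential testing, chromosome enrichment, length regression."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circdif.difcir import (
    DifCirParameters,
    chromosome_enrichment,
    difcir,
    gene_length_regression,
)
from circdif.formats import GeneModel


def _matrix(rows, samples):
    return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                        columns=samples)


SAMPLES = ["c1", "c2", "c3", "c4", "a1", "a2", "a3", "a4"]
GROUPS = {s: ("control" if s.startswith("c") else "case") for s in SAMPLES}


class TestDifcir:
    def test_matches_textbook_pooled_t(self):
        ctrl = [0.0, 0.0, 0.0, 0.0]
        case = [3.0, 3.2, 3.4, 3.4]
        res = difcir(_matrix([ctrl + case], SAMPLES), GROUPS)
        row = res.iloc[0]
        assert row["delta"] == pytest.approx(3.25)
        # independent pooled-variance computation
        n1 = n2 = 4
        sp2 = ((n1 - 1) * np.var(case, ddof=1) + (n2 - 1) * np.var(ctrl, ddof=1)) / (n1 + n2 - 2)
        t_hand = (np.mean(case) - np.mean(ctrl)) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        p_hand = 2 * stats.t.sf(abs(t_hand), n1 + n2 - 2)
        assert row["t"] == pytest.approx(t_hand)
        assert row["p"] == pytest.approx(p_hand, rel=1e-10)
        assert row["p"] < 0.01 and row["call"] == "up-DPpGC"

    def test_identical_constant_groups(self):
        res = difcir(_matrix([[2.0] * 8], SAMPLES), GROUPS)
        row = res.iloc[0]
        assert row["delta"] == 0 and row["p"] == 1.0 and row["call"] == "none"

    def test_delta_threshold_is_strict(self):
        # constant groups 0 vs 1: p minimal, delta exactly theta -> no call
        with pytest.warns(UserWarning, match="zero variance"):
            res = difcir(_matrix([[0.0] * 4 + [1.0] * 4], SAMPLES), GROUPS)
        row = res.iloc[0]
        assert row["delta"] == 1.0 and row["p"] <= 0.01
        assert row["call"] == "none"
        with pytest.warns(UserWarning, match="zero variance"):
            res2 = difcir(_matrix([[0.0] * 4 + [1.01] * 4], SAMPLES), GROUPS)
        assert res2.iloc[0]["call"] == "up-DPpGC"

    def test_group_swap_symmetry(self, rng):
        final = _matrix(rng.normal(3, 1, size=(30, 8)), SAMPLES)
        res = difcir(final, GROUPS, DifCirParameters(theta=0.3, alpha=0.2))
        swapped = {s: ("case" if g == "control" else "control")
                   for s, g in GROUPS.items()}
        res_swap = difcir(final, swapped, DifCirParameters(theta=0.3, alpha=0.2))
        np.testing.assert_allclose(res_swap["delta"], -res["delta"])
        np.testing.assert_allclose(res_swap["p"], res["p"], rtol=1e-12)
        flips = {"up-DPpGC": "down-DPpGC", "down-DPpGC": "up-DPpGC", "none": "none"}
        assert list(res_swap["call"]) == [flips[c] for c in res["call"]]

    def test_single_sample_group_rejected(self):
        groups = dict(GROUPS)
        groups["c2"] = groups["c3"] = groups["c4"] = "case"
        with pytest.raises(ValueError, match=">= 2"):
            difcir(_matrix([[0.0] * 8], SAMPLES), groups)


class TestChromosomeEnrichment:
    def test_exhaustive_enumeration_example(self):
        # N=20 genes, K=5 up-DPpGCs, chromosome with n=4 tested all hits:
        # P(X >= 4) = C(5,4)C(15,0)/C(20,4) = 5/4845
        genes = [GeneModel(f"g{i}", "chrA" if i < 4 else "chrB",
                           0, 100) for i in range(20)]
        up = [g.gene_id for g in genes[:5]]
        df = chromosome_enrichment(up, genes, adjust=False)
        assert df.loc["chrA", "p"] == pytest.approx(5 / 4845, rel=1e-12)
        # brute-force check over all C(20,4) chromosome draws
        from itertools import combinations
        hits = sum(1 for draw in combinations(range(20), 4)
                   if sum(i < 5 for i in draw) >= 4)
        assert df.loc["chrA", "p"] == pytest.approx(hits / math.comb(20, 4))

    def test_no_hits_gives_p_one(self):
        genes = [GeneModel(f"g{i}", "chrA" if i < 4 else "chrB", 0, 100)
                 for i in range(20)]
        up = [g.gene_id for g in genes[10:12]]   # all on chrB
        df = chromosome_enrichment(up, genes)
        assert df.loc["chrA", "p"] == pytest.approx(1.0)

    def test_single_chromosome_degenerate(self):
        genes = [GeneModel(f"g{i}", "chr1", 0, 100) for i in range(10)]
        df = chromosome_enrichment([g.gene_id for g in genes[:3]], genes)
        assert df.loc["chr1", "p"] == pytest.approx(1.0)

    def test_gene_outside_universe_rejected(self):
        genes = [GeneModel("g0", "chr1", 0, 100)]
        with pytest.raises(ValueError, match="absent"):
            chromosome_enrichment(["missing"], genes)


class TestLengthRegression:
    def _results(self, gene_ids, neg_log10_p):
        return pd.DataFrame({
            "neg_log10_p": neg_log10_p,
            "call": ["up-DPpGC"] * len(gene_ids),
        }, index=gene_ids)

    def test_perfect_line(self):
        genes = [GeneModel(f"g{i}", "chr1", 0, 10_000 * (i + 1)) for i in range(5)]
        y = [2 + 1e-6 * g.length for g in genes]
        slope, intercept, r2 = gene_length_regression(
            self._results([g.gene_id for g in genes], y), genes)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(1e-6)

    def test_constant_response_r2_zero(self):
        genes = [GeneModel(f"g{i}", "chr1", 0, 10_000 * (i + 1)) for i in range(5)]
        _, _, r2 = gene_length_regression(
            self._results([g.gene_id for g in genes], [2.0] * 5), genes)
        assert r2 == 0.0

    def test_matches_closed_form_r2(self, rng):
        genes = [GeneModel(f"g{i}", "chr1", 0, int(l))
                 for i, l in enumerate(rng.integers(10_000, 1_000_000, size=20))]
        x = np.array([g.length for g in genes], dtype=float)
        y = 2 + 1e-6 * x + rng.normal(0, 0.3, size=20)
        _, _, r2 = gene_length_regression(
            self._results([g.gene_id for g in genes], y), genes)
        beta, alpha = np.polyfit(x, y, 1)
        ssr = np.sum((y - (alpha + beta * x)) ** 2)
        sst = np.sum((y - y.mean()) ** 2)
        assert r2 == pytest.approx(1 - ssr / sst, rel=1e-9)

    def test_too_few_points_rejected(self):
        genes = [GeneModel("g0", "chr1", 0, 100), GeneModel("g1", "chr1", 0, 200)]
        with pytest.raises(ValueError, match=">= 3"):
            gene_length_regression(
                self._results(["g0", "g1"], [1.0, 2.0]), genes)
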
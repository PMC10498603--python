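"""DifCir: differential per-gene eccDNA production between two groups.

For each gene the final (log2-equalized) PpGC values are compared between
the two groups by a two-sample Student t-test (pooled variance by
default).  A gene is called an up-DPpGC when the mean difference
delta = mean_case - mean_control exceeds the selection threshold theta
(strict >, default 1 log2 fold change) with p <= alpha (default 0.01);
down-DPpGCs are symmetric.  Raw p-values are thresholded, matching the
original procedure; a Benjamini-Hochberg column is emitted alongside for
transparency.  Two genome-level companions are provided: per-chromosome
hypergeometric enrichment of up-DPpGC genes, and an OLS regression of
-log10 p on gene length over the significant genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats import GeneModel

__all__ = [
    "DifCirParameters",
    "difcir",
    "chromosome_enrichment",
    "gene_length_regression",
]

#: smallest representable positive double, used when a zero-variance gene
#: has unequal group means (the mean difference then decides the call)
_MIN_P = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class DifCirParameters:
    """theta: log2 mean-difference threshold (strict >); alpha:
    significance threshold (inclusive <=); test_variant: "pooled"
    (classic Student) or "unequal" (Welch)."""

    theta: float = 1.0
    alpha: float = 0.01
    test_variant: str = "pooled"

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.test_variant not in {"pooled", "unequal"}:
            raise ValueError("test_variant must be 'pooled' or 'unequal'")


def difcir(final: pd.DataFrame,
           groups: Mapping[str, str],
           params: DifCirParameters = DifCirParameters(),
           control_label: str = "control",
           case_label: str = "case") -> pd.DataFrame:
    """Differential PpGC production per gene.

    ``final`` is the genes x samples matrix of final PpGC values;
    ``groups`` maps each sample id to its group label.  Returns a
    volcano-ready DataFrame indexed by gene with columns mean_control,
    mean_case, delta, t, p, neg_log10_p, p_bh and call
    (up-DPpGC / down-DPpGC / none).
    """
    ctrl_cols = [s for s in final.columns if groups[s] == control_label]
    case_cols = [s for s in final.columns if groups[s] == case_label]
    if len(ctrl_cols) < 2 or len(case_cols) < 2:
        raise ValueError("each group needs >= 2 samples")

    a = final[case_cols].to_numpy(dtype=float)
    b = final[ctrl_cols].to_numpy(dtype=float)
    mean_case, mean_ctrl = a.mean(axis=1), b.mean(axis=1)
    delta = mean_case - mean_ctrl

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(a, b, axis=1,
                               equal_var=params.test_variant == "pooled")
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)

    # degenerate variance: both groups constant
    const = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    equal_const = const & (delta == 0)
    unequal_const = const & (delta != 0)
    t[equal_const], p[equal_const] = 0.0, 1.0
    if unequal_const.any():
        warnings.warn(
            f"{int(unequal_const.sum())} gene(s) have zero variance but unequal "
            "means; p set to the minimum representable positive value",
            stacklevel=2)
        t[unequal_const] = np.sign(delta[unequal_const]) * np.inf
        p[unequal_const] = _MIN_P
    # any residual NaN (numerical edge cases) -> conservative p = 1
    bad = ~np.isfinite(p)
    t[bad], p[bad] = 0.0, 1.0

    call = np.full(len(final), "none", dtype=object)
    sig = p <= params.alpha
    call[(delta > params.theta) & sig] = "up-DPpGC"
    call[(delta < -params.theta) & sig] = "down-DPpGC"

    return pd.DataFrame({
        "mean_control": mean_ctrl,
        "mean_case": mean_case,
        "delta": delta,
        "t": t,
        "p": p,
        "neg_log10_p": -np.log10(p),
        "p_bh": multipletests(p, method="fdr_bh")[1],
        "call": call,
    }, index=final.index)


def chromosome_enrichment(dppgc_genes: Sequence[str],
                          all_tested: Sequence[GeneModel],
                          adjust: bool = True) -> pd.DataFrame:
    """Per-chromosome upper-tail hypergeometric enrichment of up-DPpGCs.

    Population N = all tested genes, successes K = up-DPpGC genes, draws
    n_c = tested genes on chromosome c, observed k_c; the reported
    p-value is P(X >= k_c).  Every up-DPpGC gene must belong to the
    tested universe.
    """
    chrom_of = {g.gene_id: g.chrom for g in all_tested}
    missing = [g for g in dppgc_genes if g not in chrom_of]
    if missing:
        raise ValueError(f"up-DPpGC genes absent from tested universe: {missing[:5]}")
    N, K = len(all_tested), len(set(dppgc_genes))
    dppgc_set = set(dppgc_genes)
    rows = []
    for chrom in sorted({g.chrom for g in all_tested}):
        tested_c = [g for g in all_tested if g.chrom == chrom]
        n_c = len(tested_c)
        k_c = sum(g.gene_id in dppgc_set for g in tested_c)
        p = float(stats.hypergeom.sf(k_c - 1, N, K, n_c))
        rows.append({"chrom": chrom, "n_tested": n_c, "n_dppgc": k_c, "p": p})
    df = pd.DataFrame(rows).set_index("chrom")
    if adjust:
        df["p_bh"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df


def gene_length_regression(results: pd.DataFrame,
                           genes: Sequence[GeneModel]) -> tuple[float, float, float]:
    """OLS of -log10 p on gene length L_i over the up-DPpGC genes.

    Returns (slope, intercept, R^2); a constant response gives R^2 = 0 by
    convention.  Requires >= 3 significant genes.
    """
    up = results[results["call"] == "up-DPpGC"]
    lengths = {g.gene_id: g.length for g in genes}
    x = np.array([lengths[g] for g in up.index], dtype=float)
    y = up["neg_log10_p"].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("gene-length regression needs >= 3 significant genes")
    if np.all(y == y[0]):
        slope, intercept = 0.0, float(y[0])
        return slope, intercept, 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)
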
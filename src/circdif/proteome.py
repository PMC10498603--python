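"""Differential protein abundance per subcellular fraction.

Matched case/control replicate pairs are compared per protein with a
paired t-test on the per-pair log2 ratios; p-values are corrected with
Storey's q-value procedure (pi0 estimated on a lambda grid with a cubic
smoother); a protein is called a DEP when q < 0.05 and the absolute
average log2 ratio exceeds 0.38.  Fractions (CP, ME, sNE, cNE, Cysk) are
analyzed independently; a protein's overall DEP status is its call in
any fraction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats import AbundanceMatrix

__all__ = [
    "DEPParameters",
    "paired_t",
    "storey_pi0",
    "storey_q",
    "call_deps",
]

logger = logging.getLogger(__name__)

_MIN_P = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class DEPParameters:
    """q_threshold and log2_ratio_threshold are the DEP gates (q strictly
    below, |ratio| strictly above); pi0_method selects the Storey pi0
    estimator ("smoother" over the lambda grid, or "fixed" at lambda 0.5,
    the small-m fallback)."""

    q_threshold: float = 0.05
    log2_ratio_threshold: float = 0.38
    pi0_method: str = "smoother"

    def __post_init__(self) -> None:
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must be in (0, 1)")
        if self.log2_ratio_threshold < 0:
            raise ValueError("log2_ratio_threshold must be >= 0")
        if self.pi0_method not in {"smoother", "fixed"}:
            raise ValueError("pi0_method must be 'smoother' or 'fixed'")


def paired_t(case: Sequence[float], control: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test: one-sample t on the per-pair differences.

    All differences zero gives (t, p) = (0, 1); constant nonzero
    differences give p equal to the minimum representable positive value
    with a warning.  Requires >= 2 pairs of equal length.
    """
    a = np.asarray(case, dtype=float)
    b = np.asarray(control, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if len(a) < 2:
        raise ValueError("paired t-test needs >= 2 pairs")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        warnings.warn("constant nonzero paired differences; p set to minimum "
                      "representable positive value", stacklevel=2)
        return float(np.sign(d[0]) * np.inf), float(_MIN_P)
    res = stats.ttest_1samp(d, 0.0)
    return float(res.statistic), float(res.pvalue)


_LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)


def storey_pi0(p: np.ndarray, method: str = "smoother",
               lambda_grid: np.ndarray = _LAMBDA_GRID) -> float:
    """Estimate the null proportion pi0.

    The smoother method computes pi0(lambda) = #{p > lambda} / (m (1 -
    lambda)) on the grid and evaluates a cubic polynomial smoother at the
    largest lambda (the grid's lambda -> 1 limit).  The fixed method uses
    lambda = 0.5 only.  The estimate is clamped to (0, 1].
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    if method == "fixed" or m < 100:
        lam = 0.5
        pi0 = (p > lam).sum() / (m * (1 - lam))
    else:
        pi0_l = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambda_grid])
        coeffs = np.polyfit(lambda_grid, pi0_l, deg=3)
        pi0 = float(np.polyval(coeffs, lambda_grid[-1]))
    return float(min(1.0, max(pi0, _MIN_P)))


def storey_q(p_values: Sequence[float],
             params: DEPParameters = DEPParameters(),
             pi0: float | None = None) -> np.ndarray:
    """Storey q-values.

    q_(i) = min_{j >= i} pi0 * m * p_(j) / j over the sorted p-values,
    mapped back to input order.  With pi0 = 1 this is exactly the
    Benjamini-Hochberg adjusted p-value; in general q = pi0 * BH.
    q is monotone non-decreasing in p and bounded by 1.
    """
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = storey_pi0(p, method=params.pi0_method)
    m = len(p)
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    q_sorted = pi0 * m * p_sorted / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_deps(matrices: Mapping[str, AbundanceMatrix],
              params: DEPParameters = DEPParameters()) -> pd.DataFrame:
    """DEP calling per subcellular fraction.

    ``matrices`` maps fraction labels to abundance matrices (raw positive
    intensities) whose ``pairing`` lists (case_sample, control_sample)
    replicate pairs.  Per protein and fraction: average log2 ratio over
    pairs, paired-t p on the per-pair log2 ratios, Storey q (within the
    fraction), and the call (up / down / none).  Proteins with a missing
    or non-positive value in more than half of the pairs are excluded
    with a logged count.
    """
    frames = []
    for fraction in sorted(matrices):
        mat = matrices[fraction]
        if not mat.pairing:
            raise ValueError(f"fraction {fraction!r}: matrix has no pairing")
        df = mat.values
        case_cols = [c for c, _ in mat.pairing]
        ctrl_cols = [c for _, c in mat.pairing]
        with np.errstate(divide="ignore", invalid="ignore"):
            la = np.log2(df[case_cols].to_numpy(dtype=float))
            lb = np.log2(df[ctrl_cols].to_numpy(dtype=float))
        ratios = la - lb                        # per-pair log2 ratios
        ratios[~np.isfinite(ratios)] = np.nan
        n_ok = np.isfinite(ratios).sum(axis=1)
        usable = (n_ok > len(mat.pairing) / 2) & (n_ok >= 2)
        n_excluded = int((~usable).sum())
        if n_excluded:
            logger.info("fraction %s: excluded %d protein(s) missing in more "
                        "than half the pairs", fraction, n_excluded)
        sub = ratios[usable]
        t = np.zeros(len(sub))
        p = np.ones(len(sub))
        for i, row in enumerate(sub):
            vals = row[np.isfinite(row)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t[i], p[i] = paired_t(vals, np.zeros_like(vals))
        q = storey_q(p, params) if len(p) else np.array([])
        avg = np.nanmean(sub, axis=1) if len(sub) else np.array([])
        call = np.full(len(sub), "none", dtype=object)
        hit = (q < params.q_threshold) & (np.abs(avg) > params.log2_ratio_threshold)
        call[hit & (avg > 0)] = "up"
        call[hit & (avg < 0)] = "down"
        frames.append(pd.DataFrame({
            "protein_id": df.index[usable],
            "fraction": fraction,
            "avg_log2_ratio": avg,
            "t": t,
            "p": p,
            "q": q,
            "call": call,
        }))
    if not frames:
        raise ValueError("no fractions supplied")
    return pd.concat(frames, ignore_index=True)
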
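"""Democratic voting for commonly produced per-gene circles (CPpGCs).

Within one group, the vote threshold is the ceiling of the mode of the
empirical distribution of the positive final PpGC values (zeros are
excluded — the zero spike would otherwise always dominate).  A sample
votes for gene *i* when its final PpGC_i is at least the threshold;
genes with at least ``min_votes`` votes (default 3) are the group's
CPpGCs.  Thresholds are computed independently per group, so the two
groups may vote at different cutoffs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DemocraticParameters",
    "DemocraticResult",
    "ceil_threshold",
    "mode_threshold",
    "find_cppgc",
]


@dataclass(frozen=True)
class DemocraticParameters:
    """min_votes: samples required for a CPpGC; grid_size: KDE evaluation
    grid over [0, max positive PpGC] (Silverman bandwidth)."""

    min_votes: int = 3
    grid_size: int = 1024

    def __post_init__(self) -> None:
        if self.min_votes < 1:
            raise ValueError("min_votes must be >= 1")
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")


@dataclass
class DemocraticResult:
    group: str
    mode_value: float
    threshold: int
    votes: pd.Series          # votes per gene
    cppgc: list[str]          # genes with votes >= min_votes


def ceil_threshold(mode_value: float) -> int:
    """The vote threshold implied by a distribution mode: its ceiling.

    An exact integer mode maps to that integer (ceil(8) = 8)."""
    return math.ceil(mode_value)


def mode_threshold(values: Sequence[float],
                   params: DemocraticParameters = DemocraticParameters(),
                   ) -> tuple[float, int]:
    """Mode of the positive PpGC values and the resulting vote threshold.

    The mode is the argmax of a Gaussian kernel-density estimate
    (Silverman bandwidth) evaluated on a fixed grid over [0, max] —
    fixed grid and bandwidth keep the estimate deterministic.  A mode
    within one grid step of an integer is snapped to that integer so the
    ceiling rule is not perturbed by grid discretization.  Requires at
    least 10 positive values.
    """
    pos = np.asarray([v for v in np.ravel(values) if v > 0], dtype=float)
    if len(pos) < 10:
        raise ValueError(
            f"only {len(pos)} positive PpGC values; too few for a kernel mode "
            "estimate — supply a manual threshold instead")
    grid = np.linspace(0.0, float(pos.max()), params.grid_size)
    dens = stats.gaussian_kde(pos, bw_method="silverman")(grid)
    mode = float(grid[int(np.argmax(dens))])
    step = grid[1] - grid[0]
    if abs(mode - round(mode)) <= step:
        mode = float(round(mode))
    return mode, ceil_threshold(mode)


def find_cppgc(final: pd.DataFrame,
               group_samples: Sequence[str],
               group: str = "",
               params: DemocraticParameters = DemocraticParameters(),
               threshold: int | None = None) -> DemocraticResult:
    """Vote counts and CPpGC list for one group.

    ``final`` is the genes x samples final PpGC matrix.  When
    ``threshold`` is not given it is derived from the group's positive
    values via :func:`mode_threshold`.  A sample votes for a gene when
    its value is >= threshold (inclusive).
    """
    sub = final[list(group_samples)]
    if threshold is None:
        mode, threshold = mode_threshold(sub.to_numpy().ravel(), params)
    else:
        mode = float(threshold)
    votes = (sub >= threshold).sum(axis=1)
    votes.name = "votes"
    cppgc = sorted(votes.index[votes >= params.min_votes])
    return DemocraticResult(group, mode, int(threshold), votes, cppgc)
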
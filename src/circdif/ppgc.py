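"""Gene annotation of circles and the produced-per-gene-circle (PpGC) matrix.

For each gene *i* and sample, the split reads of every circle carrying
that gene or a fragment of it (>= 1 bp overlap, half-open, strand-blind)
are summed to the raw PpGC.  The raw sum is scaled by L_Max / L_i — the
length of the longest gene found in the dataset over the length of gene
*i* — and equalized with log2(PpGC + 1) to give the final PpGC used by
all downstream statistics.  A circle spanning several genes contributes
its full split-read count to each of them.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .formats import CircleRecord, GeneModel

__all__ = [
    "GeneCircleAssignment",
    "PpGCMatrix",
    "annotate_circles",
    "compute_ppgc",
    "full_gene_summary",
    "FullGeneSummary",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneCircleAssignment:
    """One (gene, circle) overlap; ``full_gene`` marks circle ⊇ gene."""

    gene_id: str
    circle: CircleRecord
    overlap_bp: int
    full_gene: bool

    def __post_init__(self) -> None:
        if self.overlap_bp < 1:
            raise ValueError("assignments require >= 1 bp overlap")


@dataclass
class PpGCMatrix:
    """Genes x samples PpGC tables: raw split-read sums, length-scaled
    values, and the final log2(scaled + 1) matrix, plus the L_Max used."""

    raw: pd.DataFrame
    scaled: pd.DataFrame
    final: pd.DataFrame
    l_max: int

    @property
    def genes(self) -> pd.Index:
        return self.final.index

    @property
    def samples(self) -> pd.Index:
        return self.final.columns


def annotate_circles(circles: Iterable[CircleRecord],
                     genes: Sequence[GeneModel]) -> list[GeneCircleAssignment]:
    """All (gene, circle) pairs with >= 1 bp overlap (half-open semantics).

    A circle overlapping k genes yields k assignments; ``full_gene`` is
    set when the circle interval fully contains the gene interval.
    Strand is ignored.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    by_id = {}
    for g in genes:
        trees[g.chrom][g.start:g.end] = g.gene_id
        by_id[g.gene_id] = g
    out: list[GeneCircleAssignment] = []
    for c in circles:
        tree = trees.get(c.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(c.start, c.end)):
            overlap = min(c.end, iv.end) - max(c.start, iv.begin)
            out.append(GeneCircleAssignment(
                iv.data, c, overlap,
                full_gene=c.start <= iv.begin and c.end >= iv.end))
    return out


def compute_ppgc(assignments: Iterable[GeneCircleAssignment],
                 genes: Sequence[GeneModel],
                 samples: Sequence[str],
                 l_max_source: str = "detected") -> PpGCMatrix:
    """Build the PpGC matrix from per-sample gene-circle assignments.

    ``l_max_source`` selects what "longest gene found in the dataset"
    means: ``"detected"`` (default) takes the maximum L_i over genes with
    at least one circle assignment in at least one sample of the run;
    ``"annotation"`` takes the maximum over the whole annotation.  Genes
    with no assignment anywhere are retained with final PpGC 0.
    """
    if l_max_source not in {"detected", "annotation"}:
        raise ValueError("l_max_source must be 'detected' or 'annotation'")
    gene_ids = [g.gene_id for g in genes]
    lengths = pd.Series({g.gene_id: g.length for g in genes})
    samples = list(samples)
    sample_pos = {s: j for j, s in enumerate(samples)}
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    arr = np.zeros((len(gene_ids), len(samples)))
    n_assigned = 0
    for a in assignments:
        sid = a.circle.sample_id
        if sid not in sample_pos:
            raise KeyError(f"assignment sample {sid!r} not in sample list")
        arr[gene_pos[a.gene_id], sample_pos[sid]] += a.circle.split_reads
        n_assigned += 1
    raw = pd.DataFrame(arr, index=pd.Index(gene_ids, name="gene"), columns=samples)
    if n_assigned == 0:
        warnings.warn("no gene-circle assignments: PpGC matrix is all zeros",
                      stacklevel=2)
        l_max = int(lengths.max()) if len(lengths) else 0
        return PpGCMatrix(raw, raw.copy(), raw.copy(), l_max)

    if l_max_source == "detected":
        detected = raw.sum(axis=1) > 0
        l_max = int(lengths[detected].max())
    else:
        l_max = int(lengths.max())
    scaled = raw.mul(l_max / lengths.loc[raw.index], axis=0)
    final = np.log2(scaled + 1.0)
    return PpGCMatrix(raw, scaled, final, l_max)


@dataclass
class FullGeneSummary:
    """Per-sample full-gene content and group-level fractions."""

    presence: pd.DataFrame           # genes x samples Boolean table
    fractions: pd.Series             # per-sample fraction of loci fully carried
    group_stats: pd.DataFrame | None  # per-group mean / SEM of the fractions
    coding_counts: pd.Series         # full-gene loci split into coding / non-coding


def full_gene_summary(assignments: Iterable[GeneCircleAssignment],
                      genes: Sequence[GeneModel],
                      samples: Sequence[str],
                      groups: Mapping[str, str] | None = None) -> FullGeneSummary:
    """Which gene loci are fully contained in at least one circle, per sample.

    The per-sample fraction is (full-gene loci) / (total annotated gene
    loci); per-group mean ± SEM of those fractions is reported when group
    labels are supplied.  Coding vs non-coding loci are split using the
    gene models' coding flag.
    """
    gene_ids = [g.gene_id for g in genes]
    coding = {g.gene_id: g.coding for g in genes}
    samples = list(samples)
    sample_pos = {s: j for j, s in enumerate(samples)}
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    arr = np.zeros((len(gene_ids), len(samples)), dtype=bool)
    for a in assignments:
        if a.full_gene:
            arr[gene_pos[a.gene_id], sample_pos[a.circle.sample_id]] = True
    presence = pd.DataFrame(arr, index=pd.Index(gene_ids, name="gene"),
                            columns=samples)

    n_loci = len(gene_ids)
    fractions = presence.sum(axis=0) / n_loci if n_loci else presence.sum(axis=0) * 0.0
    fractions.name = "full_gene_fraction"

    group_stats = None
    if groups is not None:
        rows = {}
        labels = pd.Series({s: groups[s] for s in samples})
        for label in sorted(set(labels)):
            vals = fractions[labels[labels == label].index].to_numpy(dtype=float)
            sem = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
            rows[label] = {"mean": float(np.mean(vals)), "sem": sem, "n": len(vals)}
        group_stats = pd.DataFrame(rows).T

    any_full = presence.any(axis=1)
    full_ids = presence.index[any_full]
    coding_counts = pd.Series({
        "coding": int(sum(coding[g] for g in full_ids)),
        "non_coding": int(sum(not coding[g] for g in full_ids)),
    })
    return FullGeneSummary(presence, fractions, group_stats, coding_counts)
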
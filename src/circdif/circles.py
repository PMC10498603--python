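"""Circle junction calling, near-duplicate coalescing, and filtering.

A circular template leaves a signature in short-read data: a read whose
first (read-order) segment maps genomically *downstream* of its second
segment.  ``call_junctions`` turns such split-read alignments into circle
intervals; ``merge_circles`` coalesces circles whose breakpoints lie
within ``d_min`` of each other, summing their split-read support; and
``filter_circles`` applies the support / length / mitochondrial filters.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from .formats import MITO_NAMES, CircleRecord, SplitReadAlignment

__all__ = [
    "MergeParameters",
    "FilterResult",
    "call_junctions",
    "merge_circles",
    "filter_circles",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MergeParameters:
    """Coalescing and filtering parameters.

    d_min
        breakpoint distance (bp) below which two circles are coalesced.
    min_split_reads
        minimum split-read support for a circle to be kept.
    max_length
        length cutoff in bp for short circles.
    excluded_chroms
        chromosome names removed by the filter (mitochondrial).
    """

    d_min: int = 10
    min_split_reads: int = 2
    max_length: int = 100_000
    excluded_chroms: frozenset[str] = MITO_NAMES

    def __post_init__(self) -> None:
        if self.d_min < 0:
            raise ValueError("d_min must be >= 0")
        if self.min_split_reads < 1:
            raise ValueError("min_split_reads must be >= 1")
        if self.max_length <= 0:
            raise ValueError("max_length must be > 0")


def call_junctions(alignments: Iterable[SplitReadAlignment],
                   min_non_overlap: int = 10) -> list[CircleRecord]:
    """Call circle junctions from split-read alignments.

    A junction is emitted when the read-order-first segment maps
    genomically downstream of the read-order-second segment (inverted
    order implies a circular template) and both segments contribute at
    least ``min_non_overlap`` bp of genomic span outside their mutual
    overlap.  The circle spans (chrom, min start, max end).  Identical
    junctions within a sample are aggregated: each supporting read adds 1
    to ``split_reads``.  Alignments whose segments sit on different
    chromosomes are skipped with a logged count (inter-chromosomal events
    are out of scope).
    """
    support: dict[tuple[str, str, int, int], int] = defaultdict(int)
    n_interchrom = 0
    for aln in alignments:
        chrom2 = getattr(aln, "chrom2", None)
        if chrom2 is not None and chrom2 != aln.chrom:
            n_interchrom += 1
            continue
        # collinear (segment1 upstream of segment2) is an ordinary linear
        # split, not a circular junction
        if aln.seg1_start <= aln.seg2_start:
            continue
        overlap = max(0, min(aln.seg1_end, aln.seg2_end)
                      - max(aln.seg1_start, aln.seg2_start))
        span1 = (aln.seg1_end - aln.seg1_start) - overlap
        span2 = (aln.seg2_end - aln.seg2_start) - overlap
        if min(span1, span2) < min_non_overlap:
            continue
        start = min(aln.seg1_start, aln.seg2_start)
        end = max(aln.seg1_end, aln.seg2_end)
        support[(aln.sample_id, aln.chrom, start, end)] += 1
    if n_interchrom:
        logger.info("call_junctions: skipped %d inter-chromosomal alignments",
                    n_interchrom)
    return [CircleRecord(chrom, start, end, n, sample_id=sid)
            for (sid, chrom, start, end), n in sorted(support.items())]


def merge_circles(circles: Sequence[CircleRecord],
                  params: MergeParameters = MergeParameters()) -> list[CircleRecord]:
    """Coalesce near-duplicate circles within a sample.

    Two circles are linked when they share a chromosome and both
    |start1 - start2| < d_min and |end1 - end2| < d_min (strict).  Linked
    clusters (single linkage, connected components) collapse to one
    circle whose split_reads is the sum over members and whose
    coordinates are those of the highest-support member (ties break to
    smallest start, then smallest end).  Total split-read mass is
    conserved and the operation is idempotent and permutation-invariant.
    """
    d = params.d_min
    groups: dict[tuple[str, str], list[CircleRecord]] = defaultdict(list)
    for c in circles:
        groups[(c.sample_id, c.chrom)].append(c)

    merged: list[CircleRecord] = []
    for (sid, chrom), members in groups.items():
        members = sorted(members, key=lambda c: (c.start, c.end, -c.split_reads))
        n = len(members)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i: int, j: int) -> None:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri

        # starts are sorted: only a window of neighbors can satisfy
        # |start_i - start_j| < d
        for i in range(n):
            j = i + 1
            while j < n and members[j].start - members[i].start < d:
                if abs(members[j].end - members[i].end) < d:
                    union(i, j)
                j += 1

        clusters: dict[int, list[CircleRecord]] = defaultdict(list)
        for i, c in enumerate(members):
            clusters[find(i)].append(c)
        for cluster in clusters.values():
            rep = min(cluster, key=lambda c: (-c.split_reads, c.start, c.end))
            total = sum(c.split_reads for c in cluster)
            merged.append(CircleRecord(chrom, rep.start, rep.end, total, sid))

    merged.sort(key=lambda c: (c.sample_id, c.chrom, c.start, c.end))
    return merged


class FilterResult(NamedTuple):
    circles: list[CircleRecord]
    removed: dict[str, int]


def filter_circles(circles: Iterable[CircleRecord],
                   params: MergeParameters = MergeParameters()) -> FilterResult:
    """Keep circles with split_reads >= min_split_reads, length <=
    max_length and chromosome outside the excluded set.

    Returns the surviving circles plus per-criterion removal counts
    (a circle failing several criteria is counted once, in the order
    low_support, too_long, excluded_chrom).
    """
    kept: list[CircleRecord] = []
    removed = {"low_support": 0, "too_long": 0, "excluded_chrom": 0}
    for c in circles:
        if c.split_reads < params.min_split_reads:
            removed["low_support"] += 1
        elif c.length > params.max_length:
            removed["too_long"] += 1
        elif c.chrom in params.excluded_chroms:
            removed["excluded_chrom"] += 1
        else:
            kept.append(c)
    return FilterResult(kept, removed)
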
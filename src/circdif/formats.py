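"""On-disk formats and core domain types.

Everything downstream works on three carriers: :class:`CircleRecord` (one
mapped eccDNA interval with its split-read support), :class:`GeneModel`
(a named genomic interval whose length drives PpGC scaling) and
:class:`AbundanceMatrix` (features x samples, used for both PpGC and
protein tables).

All genomic coordinates are 0-based half-open (BED convention) internally;
GTF input (1-based inclusive) is converted on read.  Readers reject
malformed input with a :class:`FormatError` naming the offending line —
they never silently coerce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "CircleRecord",
    "GeneModel",
    "SplitReadAlignment",
    "AbundanceMatrix",
    "MITO_NAMES",
    "read_circles",
    "write_circles",
    "read_genes",
    "write_genes_bed",
    "read_split_reads",
    "write_split_reads",
    "read_matrix",
    "write_matrix",
    "read_fasta",
    "write_fasta",
    "read_gene_list",
]

#: chromosome names treated as mitochondrial by default
MITO_NAMES = frozenset({"chrM", "MT", "chrMT"})


class FormatError(ValueError):
    """Raised for malformed or invariant-violating input."""


@dataclass(frozen=True)
class CircleRecord:
    """One mapped eccDNA in one sample, with its split-read support."""

    chrom: str
    start: int
    end: int
    split_reads: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"circle requires 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.split_reads < 1:
            raise FormatError(f"split_reads must be >= 1, got {self.split_reads}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene locus; ``length`` is the L_i entering the PpGC scale factor."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    gene_name: str = ""
    coding: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"gene {self.gene_id}: requires 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SplitReadAlignment:
    """A read whose prefix (segment1) and suffix (segment2) map separately.

    A circular junction is evidenced when segment1 maps genomically
    downstream of segment2 (inverted order relative to the read).
    """

    read_id: str
    chrom: str
    seg1_start: int
    seg1_end: int
    seg2_start: int
    seg2_end: int
    strand: str = "+"
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.seg1_end - self.seg1_start < 1 or self.seg2_end - self.seg2_start < 1:
            raise FormatError(f"read {self.read_id}: segment lengths must be >= 1")


@dataclass
class AbundanceMatrix:
    """Features x samples table with optional group labels and pairing.

    ``values`` is a pandas DataFrame whose index holds feature ids and
    whose columns hold sample ids.  ``pairing`` lists (case_sample,
    control_sample) replicate pairs for paired tests.
    """

    values: pd.DataFrame
    groups: Mapping[str, str] | None = None
    pairing: Sequence[tuple[str, str]] | None = None

    def validate(self, allow_missing: bool = False) -> None:
        df = self.values
        if df.index.has_duplicates:
            raise FormatError("duplicate feature ids in matrix")
        if df.columns.has_duplicates:
            raise FormatError("duplicate sample ids in matrix")
        arr = df.to_numpy(dtype=float)
        if allow_missing:
            if np.isinf(arr).any():
                raise FormatError("matrix contains infinite values")
        elif not np.isfinite(arr).all():
            raise FormatError("matrix contains non-finite values")
        if self.pairing is not None:
            for case_s, ctrl_s in self.pairing:
                for s in (case_s, ctrl_s):
                    if s not in df.columns:
                        raise FormatError(f"paired sample {s!r} absent from matrix")


# ---------------------------------------------------------------------------
# circles (BED-derived, >= 4 columns)
# ---------------------------------------------------------------------------

def read_circles(path: str | Path, sample_id: str | None = None) -> list[CircleRecord]:
    """Read circles from a tab-separated BED-like file.

    Columns: chrom, start, end, split_reads[, sample_id].  ``sample_id``
    given here overrides any fifth column.  Ordering is preserved.
    """
    records: list[CircleRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected >= 4 columns")
            chrom = fields[0]
            try:
                start, end, sr = int(fields[1]), int(fields[2]), int(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field ({exc})") from None
            sid = sample_id if sample_id is not None else (
                fields[4] if len(fields) > 4 else "")
            try:
                records.append(CircleRecord(chrom, start, end, sr, sid))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return records


def write_circles(records: Iterable[CircleRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.split_reads}\t{r.sample_id}\n")


# ---------------------------------------------------------------------------
# genes (BED6 or minimal GTF)
# ---------------------------------------------------------------------------

def read_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED6 or a minimal GTF (``gene`` features).

    Format is chosen by extension (``.gtf`` / ``.gff``); anything else is
    parsed as BED6 where the score column carries the coding flag (1 =
    coding, 0 = non-coding/pseudogene).  Duplicate gene ids are rejected.
    """
    path = Path(path)
    if path.suffix.lower() in {".gtf", ".gff"}:
        genes = _read_genes_gtf(path)
    else:
        genes = _read_genes_bed(path)
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise FormatError(f"{path}: duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    return genes


def _read_genes_bed(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected BED6 (6 columns)")
            chrom, name, score, strand = fields[0], fields[3], fields[4], fields[5]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            coding = score not in {"0", "0.0"}
            try:
                genes.append(GeneModel(name, chrom, start, end, strand,
                                       gene_name=name, coding=coding))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return genes


def _parse_gtf_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for item in attrs.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, val = item.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def _read_genes_gtf(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != "gene":
                continue
            attrs = _parse_gtf_attrs(fields[8])
            gid = attrs.get("gene_id")
            if not gid:
                raise FormatError(f"{path}:{lineno}: gene feature without gene_id")
            try:
                # GTF is 1-based inclusive -> 0-based half-open
                start, end = int(fields[3]) - 1, int(fields[4])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            biotype = attrs.get("gene_type", attrs.get("gene_biotype", "protein_coding"))
            try:
                genes.append(GeneModel(
                    gid, fields[0], start, end, fields[6],
                    gene_name=attrs.get("gene_name", gid),
                    coding=biotype == "protein_coding"))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return genes


def write_genes_bed(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t"
                     f"{1 if g.coding else 0}\t{g.strand}\n")


# ---------------------------------------------------------------------------
# split reads (documented 8-column TSV)
# ---------------------------------------------------------------------------

_SPLIT_HEADER = ("read_id", "chrom", "seg1_start", "seg1_end",
                 "seg2_start", "seg2_end", "strand", "sample_id")


def read_split_reads(path: str | Path) -> list[SplitReadAlignment]:
    """Read the 8-column split-read TSV (header optional)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "read_id":
                continue
            if len(fields) != 8:
                raise FormatError(f"{path}:{lineno}: expected 8 columns")
            try:
                coords = [int(x) for x in fields[2:6]]
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            try:
                out.append(SplitReadAlignment(
                    fields[0], fields[1], *coords, fields[6], fields[7]))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return out


def write_split_reads(reads: Iterable[SplitReadAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_SPLIT_HEADER) + "\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.chrom}\t{r.seg1_start}\t{r.seg1_end}\t"
                     f"{r.seg2_start}\t{r.seg2_end}\t{r.strand}\t{r.sample_id}\n")


# ---------------------------------------------------------------------------
# matrices (TSV, header row of sample ids, first column feature ids)
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, allow_missing: bool = False) -> AbundanceMatrix:
    """Read a features x samples TSV; rejects ragged rows and (by default)
    non-finite values."""
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            rows.append(line.split("\t"))
            if len(rows[-1]) != len(rows[0]):
                raise FormatError(
                    f"{path}:{lineno}: ragged row ({len(rows[-1])} fields, "
                    f"header has {len(rows[0])})")
    if not rows:
        raise FormatError(f"{path}: empty matrix file")
    header = rows[0][1:]
    index, data = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        index.append(row[0])
        try:
            data.append([float(x) for x in row[1:]])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric value") from None
    df = pd.DataFrame(data, index=pd.Index(index, name="feature"), columns=header)
    mat = AbundanceMatrix(df)
    try:
        mat.validate(allow_missing=allow_missing)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None
    return mat


def write_matrix(matrix: AbundanceMatrix | pd.DataFrame, path: str | Path) -> None:
    """Write a matrix as TSV at 12 significant digits (read∘write identity
    to well below 1e-9 absolute on PpGC-scale values)."""
    df = matrix.values if isinstance(matrix, AbundanceMatrix) else matrix
    with open(path, "w") as fh:
        fh.write("feature\t" + "\t".join(str(c) for c in df.columns) + "\n")
        for idx, row in zip(df.index, df.to_numpy()):
            vals = "\t".join(_fmt(v) for v in row)
            fh.write(f"{idx}\t{vals}\n")


def _fmt(v: float) -> str:
    if math.isnan(v):
        return "NA"
    return f"{v:.12g}"


# ---------------------------------------------------------------------------
# FASTA (circle consensus sequences) and plain gene lists
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as (id, uppercased sequence) pairs."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and # comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
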
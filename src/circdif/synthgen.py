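"""Synthetic eccDNA cohort generator.

Produces fully self-contained two-group cohorts with the statistical
structure the downstream analysis assumes: chromosome-scattered circles
whose lengths mix components at integer multiples of a ~200 bp period
plus a long tail below 100 Kbp; a case group with a several-fold higher
circle load; planted hotspot genes that shed extra circles only in case
samples; mitochondrial circles destined for the filter; telomeric
circles carrying TTAGGG minisatellites; and a paired protein-abundance
matrix with planted differential proteins.  Every planted signal is
recorded in a ground-truth ledger so recovery can be tested end to end.

The defaults mirror the study conditions the pipeline targets: 10
control and 9 case samples, a six-fold case enrichment in unique
circles, ~480 background circles per control sample, 200 bp length
periodicity (sd 20), six hotspot genes, and 5 matched proteomics
replicate pairs per group.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import (
    AbundanceMatrix,
    CircleRecord,
    GeneModel,
    SplitReadAlignment,
    write_circles,
    write_fasta,
    write_genes_bed,
    write_matrix,
    write_split_reads,
)

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "CohortDataset",
    "simulate_cohort",
    "simulate_split_reads",
    "write_cohort",
]

_DEFAULT_CHROMS: tuple[tuple[str, int], ...] = tuple(
    (f"chr{i}", 8_000_000) for i in range(1, 20)) + (("chrM", 16_299),)

MOTIF = "TTAGGG"
_RC = str.maketrans("ACGT", "TGCA")


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Counts must be non-negative and multipliers positive; a fixed seed
    makes the generated dataset byte-identical across runs.
    """

    seed: int = 0
    n_control: int = 10
    n_case: int = 9
    chromosomes: tuple[tuple[str, int], ...] = _DEFAULT_CHROMS
    n_genes: int = 400
    #: log-normal gene lengths: median ~30 kbp with a heavy right tail
    gene_length_median: float = 30_000.0
    gene_length_sigma: float = 1.4
    baseline_circles_per_sample: float = 480.0
    case_abundance_multiplier: float = 6.0
    #: (gene_id, extra circles per case sample, split-read boost);
    #: None auto-selects ``n_hotspots`` genes
    hotspot_genes: tuple[tuple[str, int, int], ...] | None = None
    n_hotspots: int = 6
    hotspot_extra_circles: int = 5
    hotspot_split_read_boost: int = 4
    periodicity_bp: float = 200.0
    periodicity_sd: float = 20.0
    n_periodicity_components: int = 5
    fraction_tail: float = 0.01
    fraction_mito: float = 0.05
    #: (sample_id, n telomeric circles, TTAGGG repeats per circle);
    #: None plants 25 circles x 200 repeats (30 Kbp) in every sample
    telomeric_circles: tuple[tuple[str, int, int], ...] | None = None
    #: background circle sequences emitted per sample (for the ECTR path)
    n_background_sequences: int = 30
    protein_panel: int = 800
    n_dep: int = 40
    dep_log2_shift: float = 1.0
    protein_noise_sd: float = 0.2
    n_protein_pairs: int = 5
    fractions: tuple[str, ...] = ("CP",)

    def validate(self) -> None:
        if not self.chromosomes:
            raise ConfigurationError("at least one chromosome required")
        if self.n_genes < 1:
            raise ConfigurationError("at least one gene required")
        for name, count in (("n_control", self.n_control), ("n_case", self.n_case),
                            ("n_hotspots", self.n_hotspots), ("n_dep", self.n_dep),
                            ("protein_panel", self.protein_panel)):
            if count < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name, mult in (("case_abundance_multiplier", self.case_abundance_multiplier),
                           ("periodicity_bp", self.periodicity_bp)):
            if mult <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not 0 <= self.fraction_mito < 1 or not 0 <= self.fraction_tail < 1:
            raise ConfigurationError("fractions must lie in [0, 1)")


@dataclass
class CohortDataset:
    """In-memory synthetic cohort plus its ground-truth ledger."""

    config: SimulationConfig
    samples: pd.DataFrame                      # sample_id, group
    circles: dict[str, list[CircleRecord]]     # per sample, unfiltered
    genes: list[GeneModel]
    sequences: dict[str, list[tuple[str, str]]]
    proteins: dict[str, AbundanceMatrix]       # per fraction
    truth: dict

    @property
    def groups(self) -> dict[str, str]:
        return dict(zip(self.samples["sample_id"], self.samples["group"]))


def _reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _draw_lengths(rng: np.random.Generator, n: int,
                  cfg: SimulationConfig) -> np.ndarray:
    """Mixture of normals at k * period (k = 1..K) truncated > 0, plus a
    log-uniform long tail capped below 100 kbp."""
    k = rng.integers(1, cfg.n_periodicity_components + 1, size=n)
    lengths = rng.normal(k * cfg.periodicity_bp, cfg.periodicity_sd)
    lengths = np.maximum(np.rint(lengths), 50).astype(int)
    tail = rng.random(n) < cfg.fraction_tail
    n_tail = int(tail.sum())
    if n_tail:
        lengths[tail] = np.exp(rng.uniform(math.log(2_000), math.log(99_000),
                                           size=n_tail)).astype(int)
    return lengths


def _place_genes(rng: np.random.Generator, cfg: SimulationConfig) -> list[GeneModel]:
    chroms = [(c, l) for c, l in cfg.chromosomes if c not in {"chrM", "MT", "chrMT"}]
    if not chroms:
        raise ConfigurationError("need at least one non-mitochondrial chromosome")
    names = np.array([c for c, _ in chroms])
    lens = np.array([l for _, l in chroms], dtype=float)
    weights = lens / lens.sum()
    mu = math.log(cfg.gene_length_median)
    genes = []
    width = len(str(cfg.n_genes))
    for i in range(cfg.n_genes):
        glen = int(rng.lognormal(mu, cfg.gene_length_sigma))
        glen = max(glen, 200)
        ci = rng.choice(len(names), p=weights)
        glen = min(glen, int(lens[ci]) // 2)
        start = int(rng.integers(0, int(lens[ci]) - glen))
        gid = f"G{i + 1:0{width}d}"
        genes.append(GeneModel(gid, str(names[ci]), start, start + glen,
                               strand="+" if rng.random() < 0.5 else "-",
                               gene_name=gid, coding=bool(rng.random() < 0.9)))
    return genes


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def simulate_cohort(config: SimulationConfig = SimulationConfig()) -> CohortDataset:
    """Generate a cohort per the configuration; deterministic under the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom_len = dict(config.chromosomes)
    mito = [c for c in chrom_len if c in {"chrM", "MT", "chrMT"}]
    genomic = [(c, l) for c, l in config.chromosomes if c not in mito]
    gnames = np.array([c for c, _ in genomic])
    glens = np.array([l for _, l in genomic], dtype=float)
    gweights = glens / glens.sum()

    sample_ids = ([f"C{i + 1}" for i in range(config.n_control)]
                  + [f"A{i + 1}" for i in range(config.n_case)])
    labels = ["control"] * config.n_control + ["case"] * config.n_case
    samples = pd.DataFrame({"sample_id": sample_ids, "group": labels})

    genes = _place_genes(rng, config)
    by_id = {g.gene_id: g for g in genes}

    hotspots = config.hotspot_genes
    if hotspots is None:
        eligible = [g.gene_id for g in genes if g.length >= 2_000]
        chosen = rng.choice(len(eligible), size=min(config.n_hotspots, len(eligible)),
                            replace=False)
        hotspots = tuple((eligible[int(i)], config.hotspot_extra_circles,
                          config.hotspot_split_read_boost) for i in sorted(chosen))
    for gid, extra, boost in hotspots:
        if gid not in by_id:
            raise ConfigurationError(f"hotspot gene {gid!r} not in annotation")

    circles: dict[str, list[CircleRecord]] = {}
    for sid, grp in zip(sample_ids, labels):
        mean = config.baseline_circles_per_sample
        if grp == "case":
            mean *= config.case_abundance_multiplier
        n = int(rng.poisson(mean))
        lengths = _draw_lengths(rng, n, config)
        is_mito = (rng.random(n) < config.fraction_mito) if mito else np.zeros(n, bool)
        chrom_idx = rng.choice(len(gnames), size=n, p=gweights)
        srs = 1 + rng.poisson(1.5, size=n)
        recs: list[CircleRecord] = []
        for length, on_mito, ci, sr in zip(lengths, is_mito, chrom_idx, srs):
            if on_mito:
                chrom = mito[0]
                length = min(int(length), chrom_len[chrom] - 1)
                start = int(rng.integers(0, chrom_len[chrom] - length))
            else:
                chrom = str(gnames[ci])
                length = min(int(length), int(glens[ci]) - 1)
                start = int(rng.integers(0, int(glens[ci]) - length))
            recs.append(CircleRecord(chrom, start, start + length, int(sr), sid))
        if grp == "case":
            for gid, extra, boost in hotspots:
                g = by_id[gid]
                for _ in range(extra):
                    length = int(rng.integers(500, 5_001))
                    lo = max(0, g.start - length + 1)
                    hi = min(g.end, chrom_len[g.chrom] - length)
                    start = int(rng.integers(lo, max(lo + 1, hi)))
                    sr = boost + int(rng.poisson(1.0))
                    recs.append(CircleRecord(g.chrom, start, start + length, sr, sid))
        circles[sid] = recs

    # circle consensus sequences: telomeric plants + random backgrounds
    telomeric = config.telomeric_circles
    if telomeric is None:
        telomeric = tuple((sid, 25, 200) for sid in sample_ids)
    telo_by_sample: dict[str, tuple[int, int]] = {}
    for sid, n_circ, repeats in telomeric:
        if sid not in set(sample_ids):
            raise ConfigurationError(f"telomeric sample {sid!r} unknown")
        telo_by_sample[sid] = (n_circ, repeats)

    sequences: dict[str, list[tuple[str, str]]] = {}
    telomeric_kbp: dict[str, float] = {}
    for sid in sample_ids:
        seqs: list[tuple[str, str]] = []
        n_bg = min(config.n_background_sequences, len(circles[sid]))
        for j in range(n_bg):
            length = min(circles[sid][j].length, 2_000)
            seqs.append((f"{sid}_circ{j + 1}", _random_seq(rng, length)))
        n_circ, repeats = telo_by_sample.get(sid, (0, 0))
        for j in range(n_circ):
            seq = MOTIF * repeats
            if rng.random() < 0.5:          # report the other strand
                seq = _reverse_complement(seq)
            seqs.append((f"{sid}_telo{j + 1}", seq))
        sequences[sid] = seqs
        telomeric_kbp[sid] = n_circ * repeats * 6 / 1000

    proteins, planted_deps = _simulate_proteins(rng, config, genes, hotspots)

    truth = {
        "hotspot_genes": [list(h) for h in hotspots],
        "planted_deps": planted_deps,
        "telomeric_kbp": telomeric_kbp,
        "n_circles": {sid: len(v) for sid, v in circles.items()},
    }
    dataset = CohortDataset(config, samples, circles, genes, sequences,
                            proteins, truth)
    _check_bounds(dataset, chrom_len)
    return dataset


def _simulate_proteins(rng: np.random.Generator, cfg: SimulationConfig,
                       genes: Sequence[GeneModel],
                       hotspots: Sequence[tuple[str, int, int]],
                       ) -> tuple[dict[str, AbundanceMatrix], dict]:
    """Paired case/control abundance matrices with planted log2 shifts.

    The protein panel reuses gene ids (hotspot genes first, so that
    eccDNA-DEP tandems exist by construction) padded with synthetic
    PROT#### ids; planted differential proteins get the configured log2
    shift with a random sign.
    """
    hotspot_ids = [h[0] for h in hotspots]
    other = [g.gene_id for g in genes if g.gene_id not in set(hotspot_ids)]
    other = list(rng.permutation(other))
    panel = (hotspot_ids + other)[: cfg.protein_panel]
    extra = cfg.protein_panel - len(panel)
    panel += [f"PROT{i + 1:04d}" for i in range(max(0, extra))]

    n_dep = min(cfg.n_dep, len(panel))
    dep_ids = panel[:n_dep]                      # hotspots first by design
    shifts = {pid: float(cfg.dep_log2_shift * (1 if rng.random() < 0.5 else -1))
              for pid in dep_ids}

    case_cols = [f"case_{i + 1}" for i in range(cfg.n_protein_pairs)]
    ctrl_cols = [f"ctrl_{i + 1}" for i in range(cfg.n_protein_pairs)]
    pairing = list(zip(case_cols, ctrl_cols))
    groups = {**{c: "case" for c in case_cols}, **{c: "control" for c in ctrl_cols}}

    matrices: dict[str, AbundanceMatrix] = {}
    planted: dict[str, list[list[object]]] = {}
    for fraction in cfg.fractions:
        base = rng.uniform(18.0, 30.0, size=len(panel))
        log2 = np.tile(base[:, None], (1, 2 * cfg.n_protein_pairs))
        log2 += rng.normal(0.0, cfg.protein_noise_sd,
                           size=(len(panel), 2 * cfg.n_protein_pairs))
        for i, pid in enumerate(panel):
            if pid in shifts:
                log2[i, : cfg.n_protein_pairs] += shifts[pid]
        df = pd.DataFrame(2.0 ** log2, index=pd.Index(panel, name="protein"),
                          columns=case_cols + ctrl_cols)
        matrices[fraction] = AbundanceMatrix(df, groups=groups, pairing=pairing)
        planted[fraction] = [[pid, shifts[pid]] for pid in dep_ids]
    return matrices, planted


def _check_bounds(dataset: CohortDataset, chrom_len: Mapping[str, int]) -> None:
    for sid, recs in dataset.circles.items():
        for c in recs:
            if c.end > chrom_len[c.chrom]:
                raise AssertionError(
                    f"{sid}: circle {c.chrom}:{c.start}-{c.end} exceeds "
                    f"chromosome length {chrom_len[c.chrom]}")


def simulate_split_reads(dataset: CohortDataset, reads_per_circle: int,
                         segment_length: int = 50,
                         jitter: int = 2) -> list[SplitReadAlignment]:
    """Split-read alignment records evidencing each circle's junction.

    Each circle yields exactly ``reads_per_circle`` records whose
    read-order-first segment maps at the circle end and second segment at
    the circle start (inverted order).  Junction coordinates of reads
    from the same circle agree within ±``jitter`` bp.
    """
    if reads_per_circle < 1:
        raise ValueError("reads_per_circle must be >= 1")
    rng = np.random.default_rng([dataset.config.seed, 7_919])
    out: list[SplitReadAlignment] = []
    n_read = 0
    for sid in dataset.samples["sample_id"]:
        for c in dataset.circles[sid]:
            seg = min(segment_length, max(10, c.length // 3))
            for _ in range(reads_per_circle):
                n_read += 1
                s = max(0, c.start + int(rng.integers(-jitter, jitter + 1)))
                e = c.end + int(rng.integers(-jitter, jitter + 1))
                e = max(e, s + 2 * seg + 20)   # keep segments separated
                out.append(SplitReadAlignment(
                    read_id=f"r{n_read}", chrom=c.chrom,
                    seg1_start=e - seg, seg1_end=e,
                    seg2_start=s, seg2_end=s + seg,
                    strand="+", sample_id=sid))
    return out


def write_cohort(dataset: CohortDataset, outdir: str | Path,
                 split_reads: Sequence[SplitReadAlignment] | None = None) -> None:
    """Write the cohort to disk in the pipeline's plain-text formats."""
    outdir = Path(outdir)
    (outdir / "circles").mkdir(parents=True, exist_ok=True)
    (outdir / "sequences").mkdir(exist_ok=True)
    (outdir / "proteins").mkdir(exist_ok=True)

    dataset.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    write_genes_bed(dataset.genes, outdir / "genes.bed")
    for sid, recs in dataset.circles.items():
        write_circles(recs, outdir / "circles" / f"{sid}.bed")
    for sid, seqs in dataset.sequences.items():
        write_fasta(seqs, outdir / "sequences" / f"{sid}.fasta")
    for fraction, mat in dataset.proteins.items():
        write_matrix(mat, outdir / "proteins" / f"{fraction}.tsv")
    if dataset.proteins:
        first = next(iter(dataset.proteins.values()))
        with open(outdir / "proteins" / "pairs.tsv", "w") as fh:
            fh.write("case\tcontrol\n")
            for case_s, ctrl_s in first.pairing:
                fh.write(f"{case_s}\t{ctrl_s}\n")
    if split_reads is not None:
        write_split_reads(split_reads, outdir / "split_reads.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(dataset.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
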
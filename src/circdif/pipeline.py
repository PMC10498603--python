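"""End-to-end orchestration: config, stage order, manifest.

Stage order: junction calling (optional) -> merge -> filter -> gene
annotation / PpGC -> DifCir -> democratic voting -> size profiling ->
ECTR (if sequences) -> DEP calling (if protein matrices) -> integration.
Reruns with an identical config and inputs produce bit-identical output
directories; the manifest records every parameter, input hash and the
package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .circles import MergeParameters, call_junctions, filter_circles, merge_circles
from .democratic import DemocraticParameters, find_cppgc
from .difcir import DifCirParameters, chromosome_enrichment, difcir, gene_length_regression
from .ectr import ectr_group_compare, ectr_sweep
from .formats import (
    AbundanceMatrix,
    read_circles,
    read_fasta,
    read_genes,
    read_matrix,
    read_split_reads,
    write_circles,
    write_matrix,
)
from .integrate import load_risk_list, match_tandems, rdc_compare, risk_overlap
from .ppgc import annotate_circles, compute_ppgc, full_gene_summary
from .proteome import DEPParameters, call_deps
from .sizes import size_profile, unique_count_comparison
from .synthgen import SimulationConfig, simulate_cohort, write_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters (defaults are the published values) plus
    input paths.  Round-trips losslessly through YAML."""

    # inputs (a simulated cohort fills these in when ``simulate`` is set)
    circles_dir: str | None = None
    genes_path: str | None = None
    samples_path: str | None = None
    split_reads_path: str | None = None
    sequences_dir: str | None = None
    proteins_dir: str | None = None
    risk_list_paths: list[str] = field(default_factory=list)
    rdc_list_path: str | None = None
    simulate: bool = False
    seed: int = 0
    # junction calling / merging / filtering
    min_non_overlap: int = 10
    d_min: int = 10
    min_split_reads: int = 2
    max_length: int = 100_000
    excluded_chroms: list[str] = field(default_factory=lambda: ["chrM", "MT", "chrMT"])
    # PpGC
    l_max_source: str = "detected"
    # DifCir
    theta: float = 1.0
    alpha: float = 0.01
    # democratic
    min_votes: int = 3
    # sizes
    window: int = 31
    max_len: int = 10_000
    # ECTR
    k: int = 4
    # DEP
    q_threshold: float = 0.05
    log2_ratio_threshold: float = 0.38
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run every applicable stage; returns the run directory.

    With ``config.simulate`` a synthetic cohort is generated under
    ``<outdir>/cohort`` first and its files become the inputs.  Any stage
    failure raises with the stage name attached.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.replace(config)

    if cfg.simulate:
        dataset = simulate_cohort(SimulationConfig(seed=cfg.seed))
        cohort_dir = outdir / "cohort"
        write_cohort(dataset, cohort_dir)
        cfg.circles_dir = str(cohort_dir / "circles")
        cfg.genes_path = str(cohort_dir / "genes.bed")
        cfg.samples_path = str(cohort_dir / "samples.tsv")
        cfg.sequences_dir = str(cohort_dir / "sequences")
        cfg.proteins_dir = str(cohort_dir / "proteins")

    stage = "inputs"
    try:
        if cfg.genes_path is None or not Path(cfg.genes_path).exists():
            raise FileNotFoundError(f"genes file not found: {cfg.genes_path}")
        if cfg.samples_path is None or not Path(cfg.samples_path).exists():
            raise FileNotFoundError(f"samples file not found: {cfg.samples_path}")
        genes = read_genes(cfg.genes_path)
        samples_df = pd.read_csv(cfg.samples_path, sep="\t")
        sample_ids = list(samples_df["sample_id"].astype(str))
        groups = dict(zip(sample_ids, samples_df["group"].astype(str)))
        input_files = [Path(cfg.genes_path), Path(cfg.samples_path)]

        mp = MergeParameters(cfg.d_min, cfg.min_split_reads, cfg.max_length,
                             frozenset(cfg.excluded_chroms))

        stage = "call"
        per_sample: dict[str, list] = {}
        if cfg.circles_dir is not None:
            for sid in sample_ids:
                path = Path(cfg.circles_dir) / f"{sid}.bed"
                if not path.exists():
                    raise FileNotFoundError(f"circles file not found: {path}")
                per_sample[sid] = read_circles(path, sample_id=sid)
                input_files.append(path)
        elif cfg.split_reads_path is not None:
            reads = read_split_reads(cfg.split_reads_path)
            input_files.append(Path(cfg.split_reads_path))
            called = call_junctions(reads, cfg.min_non_overlap)
            for sid in sample_ids:
                per_sample[sid] = [c for c in called if c.sample_id == sid]
        else:
            raise ValueError("either circles_dir or split_reads_path is required")

        stage = "merge+filter"
        (outdir / "circles_filtered").mkdir(exist_ok=True)
        filtered: dict[str, list] = {}
        filter_log: dict[str, dict] = {}
        for sid in sample_ids:
            merged = merge_circles(per_sample[sid], mp)
            result = filter_circles(merged, mp)
            filtered[sid] = result.circles
            filter_log[sid] = {"kept": len(result.circles), **result.removed}
            write_circles(result.circles, outdir / "circles_filtered" / f"{sid}.bed")
        _dump(filter_log, outdir / "filter_log.json")

        stage = "ppgc"
        all_circles = [c for sid in sample_ids for c in filtered[sid]]
        assignments = annotate_circles(all_circles, genes)
        mat = compute_ppgc(assignments, genes, sample_ids,
                           l_max_source=cfg.l_max_source)
        write_matrix(mat.raw, outdir / "ppgc_raw.tsv")
        write_matrix(mat.scaled, outdir / "ppgc_scaled.tsv")
        write_matrix(mat.final, outdir / "ppgc_final.tsv")
        fg = full_gene_summary(assignments, genes, sample_ids, groups)
        fg.presence.astype(int).to_csv(outdir / "full_genes.tsv", sep="\t")
        _dump({"fractions": {s: float(v) for s, v in fg.fractions.items()},
               "group_stats": (fg.group_stats.to_dict() if fg.group_stats is not None
                               else None),
               "coding_counts": fg.coding_counts.to_dict()},
              outdir / "full_genes.json")

        stage = "difcir"
        dp = DifCirParameters(cfg.theta, cfg.alpha)
        results = difcir(mat.final, groups, dp)
        results.to_csv(outdir / "difcir.tsv", sep="\t")
        up_genes = list(results.index[results["call"] == "up-DPpGC"])
        enrich = chromosome_enrichment(up_genes, genes) if up_genes else None
        if enrich is not None:
            enrich.to_csv(outdir / "chromosome_enrichment.tsv", sep="\t")
        regression = None
        if len(up_genes) >= 3:
            slope, intercept, r2 = gene_length_regression(results, genes)
            regression = {"slope": slope, "intercept": intercept, "r2": r2}
            _dump(regression, outdir / "length_regression.json")

        stage = "democratic"
        demo_params = DemocraticParameters(min_votes=cfg.min_votes)
        demo_out = {}
        for label in sorted(set(groups.values())):
            members = [s for s in sample_ids if groups[s] == label]
            try:
                res = find_cppgc(mat.final, members, group=label, params=demo_params)
            except ValueError as exc:
                logger.warning("democratic (%s): %s", label, exc)
                continue
            res.votes.to_csv(outdir / f"votes_{label}.tsv", sep="\t")
            demo_out[label] = {"mode": res.mode_value, "threshold": res.threshold,
                               "cppgc": res.cppgc}
        _dump(demo_out, outdir / "democratic.json")

        stage = "sizes"
        counts = {sid: len(filtered[sid]) for sid in sample_ids}
        profiles = {}
        for sid in sample_ids:
            prof = size_profile(filtered[sid], window=cfg.window, max_len=cfg.max_len)
            profiles[sid] = {"n": prof.n_circles,
                             "peaks": prof.peaks.tolist(),
                             "median_spacing": prof.median_spacing,
                             "fraction_below": prof.fraction_below}
        ctrl = [counts[s] for s in sample_ids if groups[s] == "control"]
        case = [counts[s] for s in sample_ids if groups[s] == "case"]
        comparison = (unique_count_comparison(ctrl, case).as_dict()
                      if len(ctrl) >= 1 and len(case) >= 1 else None)
        _dump({"per_sample": profiles, "unique_counts": counts,
               "comparison": comparison}, outdir / "sizes.json")

        stage = "ectr"
        ectr_out = None
        if cfg.sequences_dir is not None and Path(cfg.sequences_dir).exists():
            sweeps = []
            per_sample_kbp: dict[str, float] = {}
            for sid in sample_ids:
                path = Path(cfg.sequences_dir) / f"{sid}.fasta"
                if not path.exists():
                    continue
                input_files.append(path)
                seqs = read_fasta(path)
                sweep = ectr_sweep(seqs, sample_id=sid)
                sweeps.append(sweep)
                per_sample_kbp[sid] = float(
                    sweep.loc[sweep["k"] == cfg.k, "ectr_kbp"].iloc[0])
            if sweeps:
                pd.concat(sweeps, ignore_index=True).to_csv(
                    outdir / "ectr_sweep.tsv", sep="\t", index=False)
                by_group = {}
                for label in sorted(set(groups.values())):
                    by_group[label] = [per_sample_kbp[s] for s in per_sample_kbp
                                       if groups[s] == label]
                if len(by_group) == 2 and all(len(v) >= 2 for v in by_group.values()):
                    ectr_out = ectr_group_compare(by_group).reset_index().to_dict(
                        orient="records")
                _dump({"per_sample_kbp": per_sample_kbp, "k": cfg.k,
                       "group_compare": ectr_out}, outdir / "ectr.json")

        stage = "dep"
        dep_results = None
        if cfg.proteins_dir is not None and Path(cfg.proteins_dir).exists():
            pdir = Path(cfg.proteins_dir)
            pairs_path = pdir / "pairs.tsv"
            pairing = None
            if pairs_path.exists():
                pairs_df = pd.read_csv(pairs_path, sep="\t")
                pairing = list(zip(pairs_df["case"], pairs_df["control"]))
                input_files.append(pairs_path)
            matrices = {}
            for path in sorted(pdir.glob("*.tsv")):
                if path.name == "pairs.tsv":
                    continue
                mat_p = read_matrix(path, allow_missing=True)
                mat_p.pairing = pairing
                matrices[path.stem] = mat_p
                input_files.append(path)
            if matrices:
                dep_params = DEPParameters(cfg.q_threshold, cfg.log2_ratio_threshold)
                dep_results = call_deps(matrices, dep_params)
                dep_results.to_csv(outdir / "dep.tsv", sep="\t", index=False)

        stage = "integrate"
        report = {}
        if dep_results is not None:
            tandems = match_tandems(results, dep_results)
            tandems.to_csv(outdir / "tandems.tsv", sep="\t", index=False)
            report["n_up_dppgc"] = len(up_genes)
            report["n_tandems"] = len(tandems)
            if cfg.risk_list_paths and len(tandems):
                lists = [load_risk_list(p) for p in cfg.risk_list_paths]
                input_files.extend(Path(p) for p in cfg.risk_list_paths)
                overlap = risk_overlap(list(tandems["gene"]), lists)
                report["tandem_risk_overlap"] = overlap.reset_index().to_dict(
                    orient="records")
        if cfg.rdc_list_path is not None:
            rdc = load_risk_list(cfg.rdc_list_path, "rdc")
            input_files.append(Path(cfg.rdc_list_path))
            try:
                report["rdc"] = rdc_compare(mat.final, rdc, groups)
            except ValueError as exc:
                logger.warning("rdc comparison skipped: %s", exc)
        if report:
            _dump(report, outdir / "integration.json")

        stage = "manifest"

        def _rel(p) -> str:
            # paths inside the run directory are stored relative so that
            # identical runs in different directories stay hash-equal
            if p is None:
                return p
            try:
                return str(Path(p).relative_to(outdir))
            except ValueError:
                return str(p)

        params = dataclasses.asdict(cfg)
        for key in ("circles_dir", "genes_path", "samples_path", "split_reads_path",
                    "sequences_dir", "proteins_dir", "rdc_list_path"):
            params[key] = _rel(params[key])
        params["risk_list_paths"] = [_rel(p) for p in params["risk_list_paths"]]
        manifest = {
            "version": __version__,
            "parameters": params,
            "inputs": {_rel(p): _sha256(p) for p in sorted(set(input_files))},
        }
        _dump(manifest, outdir / "manifest.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outdir
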
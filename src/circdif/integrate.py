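"""Cross-referencing up-DPpGCs with DEPs and risk-gene lists.

A *tandem* is an up-DPpGC gene whose protein product is a DEP in at
least one subcellular fraction; a tandem is *concordant* when the eccDNA
delta and the protein log2 ratio share a sign.  ``risk_overlap`` counts
how many genes of a set are indexed in user-supplied risk lists (per
list and as a duplicate-free union), reporting percentages to one
decimal.  ``rdc_compare`` contrasts pooled PpGC values of a
recurrent-DSB-cluster (RDC) gene set between the groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats import read_gene_list
from .sizes import rank_sum_p

__all__ = [
    "RiskGeneList",
    "normalize_symbol",
    "load_risk_list",
    "load_bundled_list",
    "match_tandems",
    "risk_overlap",
    "rdc_compare",
]


def normalize_symbol(symbol: str) -> str:
    """Case-fold + strip; mouse symbols match human lists case-insensitively."""
    return symbol.strip().casefold()


@dataclass(frozen=True)
class RiskGeneList:
    """A named risk-gene list with case-normalized symbols."""

    name: str
    symbols: frozenset[str]

    @classmethod
    def from_symbols(cls, name: str, symbols: Iterable[str]) -> "RiskGeneList":
        return cls(name, frozenset(normalize_symbol(s) for s in symbols))

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)


def load_risk_list(path: str, name: str | None = None) -> RiskGeneList:
    """Load a one-symbol-per-line risk list from a file."""
    from pathlib import Path

    return RiskGeneList.from_symbols(name or Path(path).stem, read_gene_list(path))


def load_bundled_list(name: str) -> RiskGeneList:
    """Load one of the bundled gene lists shipped with the package.

    Available: ``harmonizome_tandem``, ``gwas_catalog_tandem``,
    ``gwas_catalog_updppgc``, ``rdc_printed_subset``.
    """
    ref = resources.files("circdif.data").joinpath(f"{name}.txt")
    symbols = [line.strip() for line in ref.read_text().splitlines()
               if line.strip() and not line.startswith("#")]
    return RiskGeneList.from_symbols(name, symbols)


def match_tandems(difcir_results: pd.DataFrame,
                  dep_results: pd.DataFrame,
                  mapping: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Pair up-DPpGC genes with their DEP proteins.

    ``difcir_results`` is the DifCir output (indexed by gene, with
    ``delta`` and ``call``); ``dep_results`` the DEP table.  ``mapping``
    translates gene ids to protein ids (identity by default); two genes
    mapping to one protein is an error.  Returns one row per tandem with
    the fractions, DEP directions and a concordance flag
    (sign(delta) == sign(avg log2 ratio) in >= 1 called fraction).
    """
    up = difcir_results[difcir_results["call"] == "up-DPpGC"]
    if mapping is not None:
        seen: dict[str, str] = {}
        for g, prot in mapping.items():
            if prot in seen.values():
                raise ValueError(f"mapping collision: protein {prot!r} mapped "
                                 "from multiple genes")
            seen[g] = prot
    deps = dep_results[dep_results["call"] != "none"]
    by_protein: dict[str, pd.DataFrame] = {
        pid: grp for pid, grp in deps.groupby("protein_id")}

    rows = []
    for gene in up.index:
        prot = mapping.get(gene, gene) if mapping is not None else gene
        hit = by_protein.get(prot)
        if hit is None:
            continue
        delta = float(up.loc[gene, "delta"])
        concordant = bool(((np.sign(hit["avg_log2_ratio"]) == np.sign(delta))).any())
        rows.append({
            "gene": gene,
            "protein_id": prot,
            "delta": delta,
            "fractions": ",".join(sorted(hit["fraction"])),
            "directions": ",".join(hit.sort_values("fraction")["call"]),
            "concordant": concordant,
        })
    return pd.DataFrame(rows, columns=["gene", "protein_id", "delta",
                                       "fractions", "directions", "concordant"])


def risk_overlap(gene_set: Sequence[str],
                 risk_lists: Sequence[RiskGeneList]) -> pd.DataFrame:
    """Per-list and union overlap of ``gene_set`` with risk lists.

    Percentages are 100 * count / |gene_set| to one decimal.  The union
    row counts each gene once however many lists index it.
    """
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    norm = {normalize_symbol(g) for g in gene_set}
    denom = len(norm)
    rows = []
    union: set[str] = set()
    for rl in risk_lists:
        hit = norm & rl.symbols
        union |= hit
        rows.append({"list": rl.name, "overlap": len(hit),
                     "percent": round(100 * len(hit) / denom, 1)})
    rows.append({"list": "union", "overlap": len(union),
                 "percent": round(100 * len(union) / denom, 1)})
    return pd.DataFrame(rows).set_index("list")


def rdc_compare(final: pd.DataFrame,
                rdc_list: RiskGeneList | Iterable[str],
                groups: Mapping[str, str],
                control_label: str = "control",
                case_label: str = "case",
                test: str = "wilcoxon") -> dict[str, float]:
    """Pooled PpGC comparison over an RDC gene set.

    Pools all (RDC gene, sample) final PpGC values per group and reports
    the group means, their ratio FC = case mean / control mean, and a
    two-sided p (exact Wilcoxon by default, or t with ``test="t"``).
    Errors if no RDC gene is present in the matrix.
    """
    if not isinstance(rdc_list, RiskGeneList):
        rdc_list = RiskGeneList.from_symbols("rdc", rdc_list)
    norm_index = {normalize_symbol(g): g for g in final.index}
    present = [norm_index[s] for s in sorted(rdc_list.symbols) if s in norm_index]
    if not present:
        raise ValueError(
            f"no RDC genes found in matrix; missing: {sorted(rdc_list.symbols)}")
    ctrl_cols = [s for s in final.columns if groups[s] == control_label]
    case_cols = [s for s in final.columns if groups[s] == case_label]
    pooled_ctrl = final.loc[present, ctrl_cols].to_numpy().ravel()
    pooled_case = final.loc[present, case_cols].to_numpy().ravel()
    mean_ctrl = float(pooled_ctrl.mean())
    mean_case = float(pooled_case.mean())
    if test == "wilcoxon":
        p = rank_sum_p(pooled_ctrl, pooled_case)
    elif test == "t":
        p = float(stats.ttest_ind(pooled_case, pooled_ctrl).pvalue)
    else:
        raise ValueError("test must be 'wilcoxon' or 't'")
    return {
        "n_genes": len(present),
        "mean_control": mean_ctrl,
        "mean_case": mean_case,
        "fc": mean_case / mean_ctrl if mean_ctrl != 0 else float("inf"),
        "p": p,
    }
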
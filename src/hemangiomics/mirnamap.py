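"""The microRNA layer: DE calling, target tables, and backward mapping.

Backward mapping runs miRNA -> mRNA: each query miRNA is looked up in a
TargetScan-dialect prediction table and a (miRNA, gene) link is retained
only when it is supported in both species of the declared pair (a
human-mouse homolog-consistency filter; symbols are matched
case-insensitively so mouse Myo1b pairs with human MYO1B).  Coverage
statistics over a gene list, sole-targeting miRNA assignment, and the
putative-biomarker call (core genes mapped by at least one miRNA) are
derived from the resulting gene -> miRNA-set mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .diffexp import two_group_ttest
from .exprmatrix import ExpressionMatrix
from .genesets import GeneSet

#: default TargetScan-style column names
DEFAULT_DIALECT = {"mirna": "miR Family", "gene": "Gene Symbol", "species": "Species ID"}


@dataclass
class TargetTable:
    """Parsed miRNA->gene prediction records.

    ``records`` has columns mirna, gene, species (and optional score,
    flagged); ``n_skipped`` counts dead/blank entries dropped at parse
    time, mirroring retired database identifiers.
    """

    records: pd.DataFrame
    n_skipped: int = 0
    known_species: tuple[str, ...] = ()


@dataclass
class CoverageReport:
    """Coverage of a gene list by a gene -> miRNA-set mapping."""

    list_name: str
    n_genes: int
    n_covered: int
    per_gene_mirnas: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def fraction_covered(self) -> float:
        return self.n_covered / self.n_genes

    @property
    def per_gene_counts(self) -> dict[str, int]:
        return {g: len(m) for g, m in self.per_gene_mirnas.items()}

    @property
    def min_count(self) -> int:
        return min(self.per_gene_counts.values())

    def to_dict(self) -> dict:
        return {
            "list": self.list_name, "n_genes": self.n_genes,
            "n_covered": self.n_covered,
            "fraction_covered": self.fraction_covered,
            "min_mirna_count": self.min_count,
            "per_gene_counts": self.per_gene_counts,
        }


def mirna_de(matrix: ExpressionMatrix, groups, contrast: tuple[str, str],
             variant: str = "pooled", fdr: float = 0.05):
    """miRNA differential expression: two-group t test + BH.

    Returns the full result table and the GeneSet of significant miRNAs
    at the declared FDR.
    """
    res = two_group_ttest(matrix, groups, contrast, variant=variant, fdr=fdr)
    sig = res.loc[res["q"] <= fdr, "feature"].tolist()
    return res, GeneSet("mirna_de", tuple(sig),
                        {m: f"q <= {fdr} ({contrast[0]} vs {contrast[1]})" for m in sig})


def read_target_table(path: str | Path, dialect: dict | None = None,
                      known_species: tuple[str, ...] = ("9606", "10090"),
                      sep: str = "\t") -> TargetTable:
    """Parse a TargetScan-dialect TSV of miRNA->gene predictions.

    Rows with a blank miRNA or gene field are skipped and counted.
    Unknown species tags are retained but flagged in column
    ``species_known`` (lenient parse).
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [v for k, v in dialect.items() if k in ("mirna", "gene", "species")
               and v not in df.columns]
    if missing:
        raise ValueError(f"target table missing mandatory columns: {missing}")
    out = pd.DataFrame({
        "mirna": df[dialect["mirna"]].fillna("").str.strip(),
        "gene": df[dialect["gene"]].fillna("").str.strip(),
        "species": df[dialect["species"]].fillna("").str.strip(),
    })
    if "score" in dialect and dialect["score"] in df.columns:
        out["score"] = pd.to_numeric(df[dialect["score"]], errors="coerce")
    blank = (out["mirna"] == "") | (out["gene"] == "")
    n_skipped = int(blank.sum())
    out = out.loc[~blank].reset_index(drop=True)
    out["species_known"] = out["species"].isin(known_species)
    return TargetTable(out, n_skipped=n_skipped, known_species=known_species)


def backward_map(mirnas, targets: TargetTable | pd.DataFrame,
                 species_pair: tuple[str, str]) -> dict[str, set[str]]:
    """Map query miRNAs to genes, keeping homolog-consistent links only.

    A (miRNA, gene) link survives iff it is present for both species of
    ``species_pair``; gene symbols are uppercase-folded before matching.
    Returns gene (uppercased) -> set of query miRNAs.
    """
    rec = targets.records if isinstance(targets, TargetTable) else targets
    sp_a, sp_b = species_pair
    query = set(mirnas)
    if not query:
        return {}
    sub = rec[rec["mirna"].isin(query)]
    links_a = set(zip(sub.loc[sub["species"] == sp_a, "mirna"],
                      sub.loc[sub["species"] == sp_a, "gene"].str.upper()))
    links_b = set(zip(sub.loc[sub["species"] == sp_b, "mirna"],
                      sub.loc[sub["species"] == sp_b, "gene"].str.upper()))
    consistent = links_a & links_b
    mapping: dict[str, set[str]] = {}
    for mirna, gene in sorted(consistent):
        mapping.setdefault(gene, set()).add(mirna)
    return mapping


def coverage(gene_list: GeneSet, mapping: dict[str, set[str]]) -> CoverageReport:
    """Fraction of list genes mapped by >= 1 miRNA, with per-gene counts."""
    if len(gene_list) == 0:
        raise ValueError("coverage of an empty gene list is undefined")
    per_gene = {g: tuple(sorted(mapping.get(g.upper(), set()))) for g in gene_list}
    n_covered = sum(1 for m in per_gene.values() if m)
    return CoverageReport(gene_list.name, len(gene_list), n_covered, per_gene)


def sole_targeting_mirnas(mapping: dict[str, set[str]],
                          lists: dict[str, GeneSet]) -> dict[str, str]:
    """Assign each miRNA with >= 1 target in the union of lists to the one
    list all its in-union targets belong to, or to "shared".

    A gene that is a member of more than one list disqualifies sole
    status for any miRNA targeting it.
    """
    membership: dict[str, set[str]] = {}
    for name, gs in lists.items():
        for g in gs:
            membership.setdefault(g.upper(), set()).add(name)
    targets_of: dict[str, set[str]] = {}
    for gene, mirnas in mapping.items():
        if gene in membership:
            for m in mirnas:
                targets_of.setdefault(m, set()).add(gene)
    out: dict[str, str] = {}
    for mirna, genes in targets_of.items():
        hit_lists = set().union(*(membership[g] for g in genes))
        multi_genes = any(len(membership[g]) > 1 for g in genes)
        if len(hit_lists) == 1 and not multi_genes:
            out[mirna] = next(iter(hit_lists))
        else:
            out[mirna] = "shared"
    return out


def putative_biomarkers(core: GeneSet, mapping: dict[str, set[str]],
                        name: str | None = None) -> GeneSet:
    """Core genes mapped by at least one retained miRNA."""
    kept = [g for g in core if mapping.get(g.upper())]
    prov = {g: "mapped by " + ",".join(sorted(mapping[g.upper()])) for g in kept}
    return GeneSet(name or f"{core.name}_biomarkers", tuple(kept), prov)


def forward_map_surrogate(genes: GeneSet, targets: TargetTable,
                          species: str, min_score: float | None = None) -> dict[str, set[str]]:
    """Surrogate forward mapping (gene -> miRNAs) by thresholded table lookup.

    This is a plain table lookup on supplied scores, not a probabilistic
    targeting model; it exists so the forward direction of the analysis
    can be exercised with explicit, auditable inputs.
    """
    rec = targets.records
    sub = rec[rec["species"] == species].copy()
    if min_score is not None:
        if "score" not in sub.columns:
            raise ValueError("target table has no score column to threshold")
        sub = sub[sub["score"] >= min_score]
    sub["gene_u"] = sub["gene"].str.upper()
    wanted = {g.upper() for g in genes}
    out: dict[str, set[str]] = {}
    for gene_u, mirna in zip(sub["gene_u"], sub["mirna"]):
        if gene_u in wanted:
            out.setdefault(gene_u, set()).add(mirna)
    return out
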
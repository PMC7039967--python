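"""Cross-species harmonization of the toxicological DE list.

The rodent propranolol time-course genes are carried into human symbol
space through a static homolog table (many-to-many allowed; unmapped
genes are dropped and counted), constitutively-biased genes are removed
by comparing baseline mean raw counts between a hepatocyte panel and an
endothelial panel (|log2 fold change| must be strictly below the
threshold to keep a gene), and the survivors are intersected with the
basic IH transcriptome list to give the toxicological transcriptome core.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exprmatrix import ExpressionMatrix
from .genesets import GeneSet, geneset_from_iterable


@dataclass
class HomologMap:
    """Many-to-many source -> human symbol mapping."""

    table: pd.DataFrame  # columns: source_id, human_id

    def __post_init__(self) -> None:
        need = {"source_id", "human_id"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"homolog table needs columns {sorted(need)}")
        t = self.table
        if (t["source_id"].astype(str).str.len() == 0).any() or \
           (t["human_id"].astype(str).str.len() == 0).any():
            raise ValueError("homolog table contains empty IDs")

    def targets_of(self, source: str) -> list[str]:
        hits = self.table.loc[self.table["source_id"] == source, "human_id"]
        return sorted(set(hits.astype(str)))

    def __len__(self) -> int:
        return len(self.table)


def read_homolog_map(path: str | Path, sep: str = "\t") -> HomologMap:
    df = pd.read_csv(path, sep=sep, dtype=str)
    df.columns = [c.strip() for c in df.columns]
    if list(df.columns[:2]) != ["source_id", "human_id"]:
        df = df.rename(columns={df.columns[0]: "source_id", df.columns[1]: "human_id"})
    return HomologMap(df[["source_id", "human_id"]].dropna())


@dataclass
class ConstitutiveFilterConfig:
    """Threshold and pseudocount for the baseline-expression filter."""

    log2fc_threshold: float = 2.0
    pseudocount: float = 1.0
    tissue_a: str = "hepatocyte"
    tissue_b: str = "endothelial"

    def __post_init__(self) -> None:
        if self.log2fc_threshold <= 0:
            raise ValueError("log2fc_threshold must be > 0")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


def map_homologs(genes: GeneSet, hmap: HomologMap,
                 name: str | None = None) -> tuple[GeneSet, dict]:
    """Translate a gene set into human space; union over all homologs.

    Returns the mapped GeneSet and a report: dropped (no homolog) genes,
    and per-source multiplicity for one-to-many mappings.
    """
    if len(hmap) == 0:
        raise ValueError("empty homolog map (cannot distinguish from empty result)")
    lookup: dict[str, list[str]] = {}
    for src, hum in hmap.table[["source_id", "human_id"]].itertuples(index=False):
        lookup.setdefault(str(src), []).append(str(hum))
    mapped: dict[str, str] = {}
    dropped: list[str] = []
    multiplicity: dict[str, int] = {}
    for g in genes:
        targets = sorted(set(lookup.get(g, [])))
        if not targets:
            dropped.append(g)
            continue
        multiplicity[g] = len(targets)
        for t in targets:
            mapped.setdefault(t, f"homolog of {g}")
    out = GeneSet(name or f"{genes.name}_human", tuple(mapped), dict(mapped))
    report = {"n_input": len(genes), "n_mapped_sources": len(multiplicity),
              "n_output": len(out), "dropped": dropped,
              "multiplicity": multiplicity}
    return out, report


def constitutive_filter(counts: ExpressionMatrix, panels,
                        cfg: ConstitutiveFilterConfig | None = None,
                        name: str = "comparable_baseline") -> tuple[GeneSet, dict]:
    """Keep genes with comparable baseline expression across the two panels.

    ``panels`` maps sample ID -> tissue label.  A gene is kept iff
    |log2((mean_A + c) / (mean_B + c))| < threshold (strict), with means
    taken over raw counts within each panel.  Genes missing (all-NaN) in
    one panel are excluded with a warning entry in the report.
    """
    cfg = cfg or ConstitutiveFilterConfig()
    panels = pd.Series(panels)
    a_cols = [s for s in counts.sample_ids if panels.get(s) == cfg.tissue_a]
    b_cols = [s for s in counts.sample_ids if panels.get(s) == cfg.tissue_b]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError(
            f"need >= 2 samples per panel; got {len(a_cols)} {cfg.tissue_a!r}, "
            f"{len(b_cols)} {cfg.tissue_b!r}")
    mean_a = counts.data[a_cols].mean(axis=1)
    mean_b = counts.data[b_cols].mean(axis=1)
    missing = mean_a.isna() | mean_b.isna()
    with np.errstate(divide="ignore"):
        log2fc = np.log2((mean_a + cfg.pseudocount) / (mean_b + cfg.pseudocount))
    keep = (np.abs(log2fc) < cfg.log2fc_threshold) & ~missing
    kept_genes = [str(g) for g in counts.data.index[keep]]
    gs = geneset_from_iterable(
        name, kept_genes,
        {g: f"|log2FC|={abs(log2fc[g]):.3f} < {cfg.log2fc_threshold}"
         for g in kept_genes})
    report = {
        "n_input": counts.shape[0], "n_kept": len(gs),
        "n_excluded_constitutive": int((~keep & ~missing).sum()),
        "n_missing_panel": int(missing.sum()),
        "missing_genes": [str(g) for g in counts.data.index[missing]],
    }
    return gs, report


def toxicological_core(tox_de: GeneSet, comparable: GeneSet,
                       basic_ih: GeneSet, name: str = "tox_core") -> tuple[GeneSet, dict]:
    """(tox DE in human space) ∩ (comparable baseline) ∩ (basic IH list).

    The report records, for every excluded tox gene, which filter removed
    it first (constitutive baseline, then basic-list membership).
    """
    comparable_set = comparable.as_set()
    basic_set = basic_ih.as_set()
    kept = []
    excluded: dict[str, str] = {}
    for g in tox_de:
        if g not in comparable_set:
            excluded[g] = "constitutive baseline (|log2FC| >= threshold or missing)"
        elif g not in basic_set:
            excluded[g] = "not in basic IH transcriptome list"
        else:
            kept.append(g)
    core = GeneSet(name, tuple(kept),
                   {g: "tox DE, comparable baseline, in basic IH list" for g in kept})
    assert core.as_set() <= tox_de.as_set()
    assert core.as_set() <= comparable_set
    assert core.as_set() <= basic_set
    report = {"n_tox_de": len(tox_de), "n_core": len(core), "excluded": excluded}
    return core, report
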
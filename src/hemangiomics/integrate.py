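"""Final set algebra, phase assignment, qPCR fold changes, and reporting.

The basic IH transcriptome list is intersected with published
proliferating/involuting gene lists (minus any manually excluded genes,
each with a required free-text reason) to form the phase core lists;
core genes are partitioned into linearly responsive (LI/LD, with
direction) and non-linearly responsive (CD/CU) biomarkers; qPCR
validation uses the 2^-ddCt relative-quantification rule; and
``build_report`` assembles every stage's sizes and exclusions into a
single bundle with a conservation check (|output| + |excluded| = |input|
at every logged filter).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genesets import GeneSet
from .trajectory import ShapeClass


def assign_phase(mean_proliferating: float, mean_involuting: float) -> str:
    """proliferating iff higher in proliferating samples; ties reported."""
    if mean_proliferating > mean_involuting:
        return "proliferating"
    if mean_proliferating < mean_involuting:
        return "involuting"
    return "tied"


def core_lists(basic: GeneSet, published_prolif: GeneSet, published_invol: GeneSet,
               exclusions: GeneSet | None = None) -> tuple[GeneSet, GeneSet]:
    """Intersect the basic list with published phase lists, minus exclusions.

    A gene may legitimately appear in both cores (it is then the shared
    phase biomarker reported separately downstream).
    """
    prolif = basic.intersect(published_prolif, name="proliferating_core")
    invol = basic.intersect(published_invol, name="involuting_core")
    if exclusions is not None and len(exclusions):
        prolif = prolif.difference(exclusions, name="proliferating_core")
        invol = invol.difference(exclusions, name="involuting_core")
    return prolif, invol


def read_exclusions(path: str | Path) -> GeneSet:
    """Read a YAML mapping symbol -> reason; every exclusion needs a reason."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("exclusions file must map gene symbol -> reason")
    for gene, reason in raw.items():
        if not reason or not str(reason).strip():
            raise ValueError(f"exclusion {gene!r} has no reason")
    return GeneSet("exclusions", tuple(raw), {g: str(r) for g, r in raw.items()})


def partition_by_linearity(core: GeneSet, shapes: dict[str, ShapeClass] | pd.Series):
    """Split a core list into linear (with direction), nonlinear, and flat.

    ``shapes`` maps gene -> ShapeClass (or its string value).  A core gene
    without a shape call is an error.
    """
    if isinstance(shapes, pd.Series):
        shapes = shapes.to_dict()
    linear: dict[str, str] = {}
    nonlinear: list[str] = []
    flat: list[str] = []
    for g in core:
        if g not in shapes:
            raise ValueError(f"core gene {g!r} has no trajectory call")
        s = ShapeClass(shapes[g])
        if s is ShapeClass.LI:
            linear[g] = "increasing"
        elif s is ShapeClass.LD:
            linear[g] = "decreasing"
        elif s in (ShapeClass.CD, ShapeClass.CU):
            nonlinear.append(g)
        else:
            flat.append(g)
    return linear, nonlinear, flat


def ddct_fold_change(records: pd.DataFrame, reference_gene: str = "ACTB",
                     calibrator_group: str | None = None,
                     per_replicate: bool = False) -> pd.DataFrame:
    """Relative quantification by the 2^-ddCt rule.

    ``records`` columns: gene, group, ct, and (when ``calibrator_group``
    is not given) role in {sample, calibrator} marking the calibrator
    group's rows.  Per gene and group, dCt = mean Ct(gene) - mean
    Ct(reference); ddCt = dCt(group) - dCt(calibrator); fold = 2^-ddCt.
    With ``per_replicate`` the Ct values are differenced replicate-wise
    (paired by order) before averaging.

    Returns a DataFrame indexed by gene with one fold-change column per
    non-calibrator group.
    """
    need = {"gene", "group", "ct"}
    if not need.issubset(records.columns):
        raise ValueError(f"qPCR records need columns {sorted(need)}")
    df = records.copy()
    df["ct"] = pd.to_numeric(df["ct"])
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    if calibrator_group is None:
        if "role" not in df.columns:
            raise ValueError("designate a calibrator: role column or calibrator_group")
        cal_groups = df.loc[df["role"] == "calibrator", "group"].unique()
        if len(cal_groups) != 1:
            raise ValueError(f"exactly one calibrator group required, got {list(cal_groups)}")
        calibrator_group = str(cal_groups[0])

    genes = [g for g in df["gene"].unique() if g != reference_gene]
    groups = [g for g in df["group"].unique()]
    if calibrator_group not in groups:
        raise ValueError(f"calibrator group {calibrator_group!r} absent from records")

    def dct(gene: str, group: str) -> float:
        tgt = df[(df["gene"] == gene) & (df["group"] == group)]["ct"].to_numpy()
        ref = df[(df["gene"] == reference_gene) & (df["group"] == group)]["ct"].to_numpy()
        if ref.size == 0:
            raise ValueError(f"missing reference {reference_gene!r} Ct for group {group!r}")
        if tgt.size == 0:
            raise ValueError(f"missing {gene!r} Ct for group {group!r}")
        if per_replicate:
            if tgt.size != ref.size:
                raise ValueError(f"replicate counts differ for {gene!r} in {group!r}")
            return float(np.mean(tgt - ref))
        return float(tgt.mean() - ref.mean())

    out = {}
    for gene in genes:
        d_cal = dct(gene, calibrator_group)
        row = {}
        for group in groups:
            if group == calibrator_group:
                continue
            ddct = dct(gene, group) - d_cal
            row[group] = 2.0 ** (-ddct)
        out[gene] = row
    return pd.DataFrame.from_dict(out, orient="index").rename_axis("gene")


class ConservationError(AssertionError):
    """A filter's input is not fully accounted for by output + exclusions."""


def log_filter(log: list[dict], stage: str, n_in: int, n_out: int,
               n_excluded: int, note: str = "") -> None:
    """Append a filter record; sizes must conserve."""
    if n_out + n_excluded != n_in:
        raise ConservationError(
            f"stage {stage!r}: {n_out} kept + {n_excluded} excluded != {n_in} input")
    log.append({"stage": stage, "n_in": n_in, "n_out": n_out,
                "n_excluded": n_excluded, "note": note})


def build_report(basic: GeneSet, calls: pd.DataFrame,
                 prolif_core: GeneSet, invol_core: GeneSet,
                 tox_core: GeneSet, coverage_reports: list,
                 sole_targeting: dict[str, str],
                 biomarkers: dict[str, GeneSet],
                 filter_log: list[dict]) -> dict:
    """Assemble the final report bundle (JSON-serializable dict).

    Verifies the conservation ledger and the core subset chain before
    returning; violations raise :class:`ConservationError`.
    """
    for entry in filter_log:
        if entry["n_out"] + entry["n_excluded"] != entry["n_in"]:
            raise ConservationError(f"inconsistent filter log entry: {entry}")
    basic_set = basic.as_set()
    for core in (prolif_core, invol_core, tox_core):
        if not core.as_set() <= basic_set:
            raise ConservationError(f"core {core.name!r} not a subset of basic list")
    for name, bset in biomarkers.items():
        parents = {"proliferating_core": prolif_core, "involuting_core": invol_core,
                   "tox_core": tox_core}
        if name in parents and not bset.as_set() <= parents[name].as_set():
            raise ConservationError(f"biomarkers {name!r} not a subset of its core")

    from .trajectory import shape_counts

    report = {
        "counts": {
            "basic_list": len(basic),
            "proliferating_core": len(prolif_core),
            "involuting_core": len(invol_core),
            "toxicological_core": len(tox_core),
            "shared_phase_genes": len(prolif_core.as_set() & invol_core.as_set()),
            "shape_counts": shape_counts(calls),
            "biomarkers": {k: len(v) for k, v in biomarkers.items()},
        },
        "coverage": [c.to_dict() for c in coverage_reports],
        "sole_targeting": dict(sorted(sole_targeting.items())),
        "gene_lists": {
            "basic": list(basic.genes),
            "proliferating_core": list(prolif_core.genes),
            "involuting_core": list(invol_core.genes),
            "toxicological_core": list(tox_core.genes),
            **{f"biomarkers_{k}": list(v.genes) for k, v in biomarkers.items()},
        },
        "filter_log": list(filter_log),
    }
    return report


def write_report(report: dict, out_dir: str | Path, calls: pd.DataFrame | None = None) -> None:
    """Write the JSON summary and TSV tables for a report bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "summary.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    if calls is not None:
        calls.to_csv(out / "trajectory_calls.tsv", sep="\t", index=False)
    pd.DataFrame(report["filter_log"]).to_csv(out / "filter_log.tsv", sep="\t", index=False)
    rows = [{"mirna": m, "assignment": l} for m, l in report["sole_targeting"].items()]
    pd.DataFrame(rows, columns=["mirna", "assignment"]).to_csv(
        out / "sole_targeting.tsv", sep="\t", index=False)
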
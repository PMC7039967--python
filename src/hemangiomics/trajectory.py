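"""Stage-mean trajectory classification and the propranolol range filter.

The IH layer works on five group means per gene: control (m0), lesions at
6, 12 and 24 months (m1, m2, m3), and propranolol-treated lesions (mp).
Genes are kept as candidates when any of the four contrasts
m0-m1, m1-m2, m2-m3, m0-mp is significant at the declared FDR, their
three stage means are classified into a response shape by the sign
pattern of consecutive differences

    LD  linear decreasing   (m1 > m2 > m3)
    LI  linear increasing   (m1 < m2 < m3)
    CD  concave down        (interior peak at 12 months)
    CU  concave up          (interior trough at 12 months)
    FLAT no change beyond the tie tolerance

and genes whose propranolol mean lies outside the range of the
piecewise-linear interpolation of (m1, m2, m3) are eliminated: their
propranolol response does not resemble any point of the natural disease
trajectory.  Survivors form the basic IH transcriptome list.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exprmatrix import ExpressionMatrix, SampleSheet
from .genesets import GeneSet

IH_GROUPS = ("control", "6mo", "12mo", "24mo", "propranolol")
#: canonical contrast keys, in pipeline order
IH_CONTRASTS = (
    ("6mo", "control"),
    ("12mo", "6mo"),
    ("24mo", "12mo"),
    ("propranolol", "control"),
)


class ShapeClass(str, enum.Enum):
    LD = "LD"
    LI = "LI"
    CD = "CD"
    CU = "CU"
    FLAT = "FLAT"


@dataclass
class GroupMeanProfile:
    """Per-gene group means plus significance flags for the four contrasts."""

    gene: str
    m0: float
    m1: float
    m2: float
    m3: float
    mp: float
    sig: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in (self.m0, self.m1, self.m2, self.m3, self.mp):
            if not np.isfinite(v):
                raise ValueError(f"non-finite mean for gene {self.gene!r}")
        if len(self.sig) != 4:
            raise ValueError(
                f"profile for {self.gene!r} needs exactly 4 contrast flags, "
                f"got {sorted(self.sig)}")


@dataclass
class TrajectoryCall:
    gene: str
    shape: ShapeClass
    prop_in_range: bool
    selected: bool
    epsilon: float


def contrast_name(a: str, b: str) -> str:
    return f"{a}_vs_{b}"


def classify_shape(m1: float, m2: float, m3: float, epsilon: float = 0.0) -> ShapeClass:
    """Classify the 6/12/24-month means by consecutive-difference signs.

    Differences within ``epsilon`` of zero are ties.  Both tied -> FLAT;
    exactly one tied -> the linear class of the signed difference (the
    weak-inequality reading of a monotone chain); otherwise the four sign
    patterns map to LI, LD, CD (interior peak) and CU (interior trough).
    """
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    d1 = m2 - m1
    d2 = m3 - m2
    t1 = abs(d1) <= epsilon
    t2 = abs(d2) <= epsilon
    if t1 and t2:
        return ShapeClass.FLAT
    if t1 or t2:
        signed = d2 if t1 else d1
        return ShapeClass.LI if signed > 0 else ShapeClass.LD
    if d1 > 0 and d2 > 0:
        return ShapeClass.LI
    if d1 < 0 and d2 < 0:
        return ShapeClass.LD
    if d1 > 0 and d2 < 0:
        return ShapeClass.CD
    return ShapeClass.CU


def interpolation_range_filter(m1: float, m2: float, m3: float, mp: float) -> bool:
    """True (kept) iff mp lies within the range of the piecewise-linear
    interpolant of (m1, m2, m3); bounds inclusive.

    For a piecewise-linear function the range is exactly
    [min(m1,m2,m3), max(m1,m2,m3)].
    """
    return bool(min(m1, m2, m3) <= mp <= max(m1, m2, m3))


def select_candidates(profile: GroupMeanProfile) -> bool:
    """True iff any of the four contrasts is significant."""
    return any(profile.sig.values())


def build_profiles(matrix: ExpressionMatrix, sheet: SampleSheet,
                   de_results: pd.DataFrame, fdr: float = 0.05,
                   center_control: bool = False) -> list[GroupMeanProfile]:
    """Compute per-gene group means and attach contrast significance flags.

    ``de_results`` is the concatenation of the four contrast tables from
    :func:`hemangiomics.diffexp.two_group_ttest` (columns feature,
    contrast, q).  A feature absent from any contrast is an error.  With
    ``center_control`` the control mean is subtracted from every group
    mean (m0 becomes 0); significance flags are unaffected.
    """
    sheet.validate_against(matrix)
    missing_groups = [g for g in IH_GROUPS if not sheet.samples_in(g)]
    if missing_groups:
        raise ValueError(f"sample sheet missing groups: {missing_groups}")
    means = {}
    for g in IH_GROUPS:
        cols = sheet.samples_in(g)
        means[g] = matrix.data[cols].mean(axis=1)

    wanted = {contrast_name(a, b) for a, b in IH_CONTRASTS}
    have = set(de_results["contrast"].unique())
    if wanted - have:
        raise ValueError(f"DE results missing contrasts: {sorted(wanted - have)}")
    qtab = de_results.pivot(index="feature", columns="contrast", values="q")

    profiles = []
    for gene in matrix.feature_ids:
        if gene not in qtab.index:
            raise ValueError(f"feature {gene!r} absent from DE results")
        sig = {}
        for a, b in IH_CONTRASTS:
            name = contrast_name(a, b)
            qv = qtab.at[gene, name]
            if pd.isna(qv):
                raise ValueError(f"feature {gene!r} absent from contrast {name!r}")
            sig[name] = bool(qv <= fdr)
        m0 = float(means["control"][gene])
        vals = [float(means[g][gene]) for g in ("6mo", "12mo", "24mo", "propranolol")]
        if center_control:
            vals = [v - m0 for v in vals]
            m0 = 0.0
        profiles.append(GroupMeanProfile(gene, m0, *vals, sig=sig))
    return profiles


def build_basic_list(profiles: list[GroupMeanProfile], epsilon: float = 0.0,
                     name: str = "basic_ih") -> tuple[GeneSet, pd.DataFrame]:
    """Apply significance selection and the range filter; classify survivors.

    Returns the basic IH transcriptome GeneSet plus the full per-gene call
    table (gene, means, shape, prop_in_range, selected, epsilon).
    """
    rows = []
    for p in profiles:
        shape = classify_shape(p.m1, p.m2, p.m3, epsilon)
        in_range = interpolation_range_filter(p.m1, p.m2, p.m3, p.mp)
        selected = select_candidates(p) and in_range
        rows.append({
            "gene": p.gene, "m0": p.m0, "m1": p.m1, "m2": p.m2, "m3": p.m3,
            "mp": p.mp, "shape": shape.value, "prop_in_range": in_range,
            "any_significant": select_candidates(p), "selected": selected,
            "epsilon": epsilon,
        })
    calls = pd.DataFrame(rows, columns=[
        "gene", "m0", "m1", "m2", "m3", "mp", "shape", "prop_in_range",
        "any_significant", "selected", "epsilon"])
    kept = calls.loc[calls["selected"], "gene"].tolist()
    prov = {}
    for _, r in calls.iterrows():
        if r["selected"]:
            prov[r["gene"]] = f"shape={r['shape']}, propranolol in range"
    basic = GeneSet(name, tuple(kept), prov)
    return basic, calls


def shape_counts(calls: pd.DataFrame, selected_only: bool = True) -> dict[str, int]:
    sub = calls[calls["selected"]] if selected_only else calls
    counts = sub["shape"].value_counts().to_dict()
    return {s.value: int(counts.get(s.value, 0)) for s in ShapeClass}
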
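"""Synthetic inputs with planted truth for every pipeline stage.

Four generators emulate the designs the pipeline consumes:

* a five-group IH microarray experiment (control, 6, 12, 24 months,
  propranolol) with planted LD/LI/CD/CU/FLAT stage-mean trajectories and
  propranolol levels planted inside or outside the trajectory range;
* a two-arm rodent liver time course (vehicle vs propranolol over a
  14-day window) with a planted fraction of genes whose smooth time
  trends diverge between arms;
* a two-panel baseline count matrix (hepatocyte vs endothelial) with a
  planted fraction of constitutively biased genes;
* a miRNA expression matrix plus a TargetScan-style link table with
  planted differential miRNAs and homolog-consistent target links.

Each generator draws from its own RNG stream derived from the master
seed, so adding or re-running one generator never perturbs another, and
identical configs give byte-identical outputs.  Noise is i.i.d. Gaussian
on the log2 scale (counts are negative-binomial around planted means);
``noise_sd=0`` produces exactly the planted means, which is what makes
the planted truth recoverable with zero errors downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exprmatrix import ExpressionMatrix, SampleSheet
from .trajectory import IH_GROUPS, ShapeClass

DEFAULT_SHAPE_FRACTIONS = {"LD": 0.2, "LI": 0.2, "CD": 0.2, "CU": 0.2, "FLAT": 0.2}

# fixed per-generator RNG stream tags
_STREAMS = {"ih": 11, "tox": 23, "baseline": 37, "mirna": 53, "homologs": 71}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults are the study conditions every recovery test runs under:
    five groups of five samples, a 2 log2-unit effect, 0.1 log2 units of
    noise, a 14-day two-arm time course sampled on days 1/3/7/14, 30%
    constitutively biased baseline genes, and 30% differential miRNAs
    linking to 5 targets each.
    """

    n_genes: int = 1000
    samples_per_group: int = 5
    shape_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SHAPE_FRACTIONS))
    frac_prop_in_range: float = 0.7
    effect_size: float = 2.0
    noise_sd: float = 0.1
    seed: int = 0
    time_points: tuple[float, ...] = (1.0, 3.0, 7.0, 14.0)
    frac_divergent: float = 0.1
    baseline_frac_constitutive: float = 0.3
    mirna_frac_de: float = 0.3
    targets_per_mirna: int = 5
    # generator-size knobs the design leaves implicit
    n_mirnas: int = 30
    frac_one_species: float = 0.0
    baseline_samples: int = 2
    baseline_dispersion: float = 10.0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.samples_per_group < 2:
            raise ValueError("samples_per_group must be >= 2")
        total = sum(self.shape_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"shape_fractions must sum to 1, got {total}")
        for key, frac in list(self.shape_fractions.items()) + [
                ("frac_prop_in_range", self.frac_prop_in_range),
                ("frac_divergent", self.frac_divergent),
                ("baseline_frac_constitutive", self.baseline_frac_constitutive),
                ("mirna_frac_de", self.mirna_frac_de),
                ("frac_one_species", self.frac_one_species)]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {key!r} must be in [0,1], got {frac}")
        if key_missing := set(self.shape_fractions) - {s.value for s in ShapeClass}:
            raise ValueError(f"unknown shapes: {sorted(key_missing)}")
        non_flat = sum(v for k, v in self.shape_fractions.items() if k != "FLAT")
        if self.effect_size <= 0 and non_flat > 0:
            raise ValueError("effect_size must be > 0 when non-FLAT shapes are planted")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.targets_per_mirna < 0 or self.n_mirnas < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators (one field per layer)."""

    shapes: pd.Series | None = None           # gene -> shape label
    prop_in_range: pd.Series | None = None    # gene -> bool
    selected: pd.Series | None = None         # gene -> bool (basic-list truth)
    group_means: pd.DataFrame | None = None   # gene x (m0,m1,m2,m3,mp)
    divergent: pd.Series | None = None        # tox layer
    constitutive: pd.Series | None = None     # baseline layer
    mirna_de: pd.Series | None = None         # miRNA layer
    links: pd.DataFrame | None = None         # full miRNA->gene link list


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAMS[stream]])


def gene_ids(n: int, prefix: str = "G") -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(1, n + 1)]


def _allocate(labels_fracs: dict[str, float], n: int,
              rng: np.random.Generator) -> np.ndarray:
    """Deterministic largest-remainder allocation of n items, then shuffle."""
    labels = sorted(labels_fracs)
    raw = np.array([labels_fracs[l] * n for l in labels])
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - np.floor(raw)))
    for i in range(remainder):
        counts[order[i % len(labels)]] += 1
    out = np.repeat(labels, counts)
    rng.shuffle(out)
    return out


def simulate_ih_experiment(config: SimConfig):
    """Five-group IH experiment with planted trajectories.

    Returns (log2 ExpressionMatrix, SampleSheet, PlantedTruth).  Planted
    means per shape (baseline b, effect e):
    LD (b+e, b, b-e); LI (b-e, b, b+e); CD (b, b+e, b); CU (b, b-e, b);
    FLAT (b, b, b); control m0 = b.  In-range genes get mp at the
    midpoint of [min, max] of the stage means, out-of-range genes get
    mp = max + e (unambiguous under noise).
    """
    rng = _rng(config, "ih")
    n, spg, e = config.n_genes, config.samples_per_group, config.effect_size
    genes = gene_ids(n)
    b = rng.uniform(6.0, 12.0, size=n)
    shapes = _allocate(config.shape_fractions, n, rng)
    in_range = _allocate({"in": config.frac_prop_in_range,
                          "out": 1.0 - config.frac_prop_in_range}, n, rng) == "in"

    m = np.empty((n, 5))  # m0, m1, m2, m3, mp
    m[:, 0] = b
    for shape, (o1, o2, o3) in {
            "LD": (e, 0.0, -e), "LI": (-e, 0.0, e),
            "CD": (0.0, e, 0.0), "CU": (0.0, -e, 0.0),
            "FLAT": (0.0, 0.0, 0.0)}.items():
        mask = shapes == shape
        m[mask, 1] = b[mask] + o1
        m[mask, 2] = b[mask] + o2
        m[mask, 3] = b[mask] + o3
    lo = m[:, 1:4].min(axis=1)
    hi = m[:, 1:4].max(axis=1)
    m[:, 4] = np.where(in_range, (lo + hi) / 2.0, hi + e)

    cols, data, rows = [], [], []
    for gi, group in enumerate(IH_GROUPS):
        for r in range(spg):
            sample = f"{group}_{r + 1}"
            cols.append(sample)
            rows.append({"sample": sample, "group": group})
            data.append(m[:, gi] + rng.normal(0.0, config.noise_sd, size=n)
                        if config.noise_sd > 0 else m[:, gi].copy())
    matrix = ExpressionMatrix(
        pd.DataFrame(np.column_stack(data), index=genes, columns=cols), scale="log2")
    sheet = SampleSheet(pd.DataFrame(rows), groups=IH_GROUPS)

    # truth: a gene belongs on the basic list iff some contrast truly
    # differs and the planted propranolol level is in range
    diffs = np.column_stack([
        m[:, 1] - m[:, 0], m[:, 2] - m[:, 1], m[:, 3] - m[:, 2], m[:, 4] - m[:, 0]])
    selected = (np.abs(diffs) > 1e-12).any(axis=1) & in_range
    truth = PlantedTruth(
        shapes=pd.Series(shapes, index=genes, name="shape"),
        prop_in_range=pd.Series(in_range, index=genes, name="prop_in_range"),
        selected=pd.Series(selected, index=genes, name="selected"),
        group_means=pd.DataFrame(m, index=genes,
                                 columns=["m0", "m1", "m2", "m3", "mp"]))
    return matrix, sheet, truth


def simulate_tox_timecourse(config: SimConfig, gene_prefix: str = "Rno_G"):
    """Two-arm liver time course with a planted divergent fraction.

    Shared per-gene smooth trend b + a1*z + a2*z^2 on normalized time z;
    divergent genes add effect_size * sin(pi*z) to the propranolol arm
    (maximal divergence effect_size at the window midpoint).
    """
    times = tuple(float(t) for t in config.time_points)
    if len(set(times)) < 4:
        raise ValueError(f"need >= 4 distinct time points, got {sorted(set(times))}")
    rng = _rng(config, "tox")
    n, spg = config.n_genes, config.samples_per_group
    genes = [f"{gene_prefix}{i:05d}" for i in range(1, n + 1)]
    b = rng.uniform(6.0, 12.0, size=n)
    a1 = rng.normal(0.0, 1.0, size=n)
    a2 = rng.normal(0.0, 1.0, size=n)
    divergent = _allocate({"d": config.frac_divergent,
                           "s": 1.0 - config.frac_divergent}, n, rng) == "d"

    tmin, tmax = min(times), max(times)
    cols, data, rows = [], [], []
    for arm in ("control", "propranolol"):
        for t in times:
            z = (t - tmin) / (tmax - tmin)
            mean = b + a1 * z + a2 * z * z
            if arm == "propranolol":
                mean = mean + np.where(divergent,
                                       config.effect_size * np.sin(np.pi * z), 0.0)
            for r in range(spg):
                sample = f"{arm}_d{t:g}_{r + 1}"
                cols.append(sample)
                rows.append({"sample": sample, "group": arm, "time": t, "arm": arm})
                data.append(mean + rng.normal(0.0, config.noise_sd, size=n)
                            if config.noise_sd > 0 else mean.copy())
    matrix = ExpressionMatrix(
        pd.DataFrame(np.column_stack(data), index=genes, columns=cols), scale="log2")
    sheet = SampleSheet(pd.DataFrame(rows), groups=("control", "propranolol"))
    truth = PlantedTruth(divergent=pd.Series(divergent, index=genes, name="divergent"))
    return matrix, sheet, truth


def simulate_baseline_counts(config: SimConfig,
                             tissues: tuple[str, str] = ("hepatocyte", "endothelial")):
    """Two-panel baseline counts with planted constitutive bias.

    Constitutive genes have |log2 mean ratio| in [3, 5] between panels,
    comparable genes in [0, 1]; means are >= 50 so pseudocounts cannot
    flip a decision.  Counts are negative-binomial around the planted
    means; noise_sd = 0 yields exact rounded means.
    """
    rng = _rng(config, "baseline")
    n = config.n_genes
    genes = gene_ids(n)
    constitutive = _allocate({"c": config.baseline_frac_constitutive,
                              "n": 1.0 - config.baseline_frac_constitutive},
                             n, rng) == "c"
    mean_a = np.exp(rng.uniform(np.log(50.0), np.log(500.0), size=n))
    shift = np.where(
        constitutive,
        rng.uniform(3.0, 5.0, size=n) * rng.choice([-1.0, 1.0], size=n),
        rng.uniform(-1.0, 1.0, size=n))
    mean_b = mean_a * 2.0 ** (-shift)

    cols, data, rows = [], [], []
    for tissue, means in zip(tissues, (mean_a, mean_b)):
        for r in range(max(2, config.baseline_samples)):
            sample = f"{tissue}_{r + 1}"
            cols.append(sample)
            rows.append({"sample": sample, "group": tissue})
            if config.noise_sd > 0:
                size = config.baseline_dispersion
                p = size / (size + means)
                data.append(rng.negative_binomial(size, p).astype(float))
            else:
                data.append(np.round(means))
    matrix = ExpressionMatrix(
        pd.DataFrame(np.column_stack(data), index=genes, columns=cols), scale="raw")
    sheet = SampleSheet(pd.DataFrame(rows), groups=tissues)
    truth = PlantedTruth(
        constitutive=pd.Series(constitutive, index=genes, name="constitutive"))
    return matrix, sheet, truth


def simulate_mirna_layer(config: SimConfig, species_pair: tuple[str, str] = ("9606", "10090")):
    """miRNA expression plus a TargetScan-style link table.

    Each of ``n_mirnas`` synthetic miRNAs links to ``targets_per_mirna``
    genes of the shared gene universe; links are recorded in both species
    (homolog-consistent by construction) except a ``frac_one_species``
    fraction recorded in one species only.  ``mirna_frac_de`` miRNAs have
    their propranolol-arm mean shifted by effect_size.
    """
    rng = _rng(config, "mirna")
    n_mir, spg = config.n_mirnas, config.samples_per_group
    mirnas = [f"sim-miR-{i:03d}" for i in range(1, n_mir + 1)]
    genes = gene_ids(config.n_genes)
    de = _allocate({"de": config.mirna_frac_de, "n": 1.0 - config.mirna_frac_de},
                   max(n_mir, 1), rng)[:n_mir] == "de" if n_mir else np.array([], bool)
    b = rng.uniform(4.0, 10.0, size=n_mir)

    cols, data, rows = [], [], []
    for group in ("control", "propranolol"):
        for r in range(spg):
            sample = f"{group}_{r + 1}"
            cols.append(sample)
            rows.append({"sample": sample, "group": group})
            mean = b + (config.effect_size * de if group == "propranolol" else 0.0)
            data.append(mean + rng.normal(0.0, config.noise_sd, size=n_mir)
                        if config.noise_sd > 0 else np.asarray(mean, float).copy())
    matrix = ExpressionMatrix(
        pd.DataFrame(np.column_stack(data) if n_mir else np.empty((0, len(cols))),
                     index=mirnas, columns=cols), scale="log2")
    sheet = SampleSheet(pd.DataFrame(rows), groups=("control", "propranolol"))

    link_rows = []
    sp_a, sp_b = species_pair
    for i, mir in enumerate(mirnas):
        k = min(config.targets_per_mirna, len(genes))
        targets = rng.choice(genes, size=k, replace=False) if k else []
        for g in targets:
            one_species = rng.random() < config.frac_one_species
            link_rows.append({"mirna": mir, "gene": str(g).upper(), "species": sp_a,
                              "both_species": not one_species})
            if not one_species:
                link_rows.append({"mirna": mir, "gene": str(g).capitalize(),
                                  "species": sp_b, "both_species": True})
    links = pd.DataFrame(link_rows,
                         columns=["mirna", "gene", "species", "both_species"])
    truth = PlantedTruth(mirna_de=pd.Series(de, index=mirnas, name="mirna_de"),
                         links=links)
    return matrix, links, sheet, truth


def make_homolog_map(source_genes: list[str], human_genes: list[str],
                     frac_unmapped: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """One-to-one source -> human homolog table with a dropped fraction.

    Pairing is positional (source_genes[i] -> human_genes[i]); a
    ``frac_unmapped`` fraction of sources is left out of the table,
    emulating probes without human homologs.
    """
    if len(source_genes) != len(human_genes):
        raise ValueError("source and human gene lists must align")
    rng = np.random.default_rng([int(seed), _STREAMS["homologs"]])
    n = len(source_genes)
    unmapped = rng.random(n) < frac_unmapped
    rows = [{"source_id": s, "human_id": h}
            for s, h, u in zip(source_genes, human_genes, unmapped) if not u]
    return pd.DataFrame(rows, columns=["source_id", "human_id"])


def write_truth(truth: PlantedTruth, out_dir) -> None:
    """Persist planted truth as TSV (per-gene labels) + JSON-able links."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    per_gene = {}
    for name in ("shapes", "prop_in_range", "selected", "divergent",
                 "constitutive", "mirna_de"):
        s = getattr(truth, name)
        if s is not None:
            per_gene[name] = s
    if per_gene:
        pd.DataFrame(per_gene).to_csv(out / "truth.tsv", sep="\t",
                                      index_label="feature")
    if truth.group_means is not None:
        truth.group_means.to_csv(out / "truth_means.tsv", sep="\t",
                                 index_label="feature")
    if truth.links is not None:
        truth.links.to_csv(out / "truth_links.tsv", sep="\t", index=False)
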
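"""End-to-end synthetic pipeline: all three layers plus integration.

``run_synthetic_pipeline`` generates every layer from one
:class:`~hemangiomics.simdata.SimConfig`, runs the full analysis — IH
contrasts, trajectory classification and range filter, spline
time-course test, homolog harmonization, constitutive filter,
toxicological core, miRNA DE, backward mapping, coverage,
sole-targeting, putative biomarkers — and assembles the final report
bundle.  The published proliferating/involuting lists for the synthetic
study are derived from the planted phase (whether the exact 6-month mean
exceeds the 24-month mean), mirroring the phase-assignment rule applied
to real published lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import crossspecies, diffexp, mirnamap, simdata, trajectory
from .genesets import GeneSet, geneset_from_iterable
from .integrate import build_report, core_lists, log_filter
from .simdata import SimConfig


@dataclass
class PipelineResult:
    """Everything the synthetic end-to-end run produces."""

    config: SimConfig
    basic: GeneSet
    calls: pd.DataFrame
    prolif_core: GeneSet
    invol_core: GeneSet
    tox_de_human: GeneSet
    comparable: GeneSet
    tox_core: GeneSet
    mapping: dict
    coverage_reports: list
    sole_targeting: dict
    biomarkers: dict
    report: dict
    truths: dict = field(default_factory=dict)
    de_tables: dict = field(default_factory=dict)


def run_synthetic_pipeline(config: SimConfig, fdr: float = 0.05,
                           epsilon: float | None = None,
                           homolog_frac_unmapped: float = 0.0,
                           spline_moderation: bool = False) -> PipelineResult:
    """Run the whole analysis on freshly generated synthetic data.

    ``epsilon`` is the trajectory tie tolerance; by default 0 for
    noise-free runs and effect_size/4 otherwise (comfortably above the
    noise floor of a group mean, comfortably below the planted effect).
    """
    if epsilon is None:
        epsilon = 0.0 if config.noise_sd == 0 else config.effect_size / 4.0
    filter_log: list[dict] = []

    # --- IH layer -----------------------------------------------------
    ih_matrix, ih_sheet, ih_truth = simdata.simulate_ih_experiment(config)
    groups = ih_sheet.group_of()
    de_parts = [diffexp.two_group_ttest(ih_matrix, groups, (a, b), variant="pooled")
                for a, b in trajectory.IH_CONTRASTS]
    ih_de = pd.concat(de_parts, ignore_index=True)
    profiles = trajectory.build_profiles(ih_matrix, ih_sheet, ih_de, fdr=fdr)
    basic, calls = trajectory.build_basic_list(profiles, epsilon=epsilon)
    n_sig = int(calls["any_significant"].sum())
    log_filter(filter_log, "ih_significance", len(calls), n_sig,
               len(calls) - n_sig, f"any contrast q <= {fdr}")
    log_filter(filter_log, "ih_range_filter", n_sig, len(basic),
               n_sig - len(basic), "propranolol level within stage-mean range")

    # --- published phase lists (planted-phase surrogate) --------------
    means = ih_truth.group_means
    prolif_pub = geneset_from_iterable(
        "published_proliferating", means.index[means["m1"] > means["m3"]])
    invol_pub = geneset_from_iterable(
        "published_involuting", means.index[means["m3"] > means["m1"]])
    prolif_core, invol_core = core_lists(basic, prolif_pub, invol_pub)
    log_filter(filter_log, "proliferating_core", len(basic), len(prolif_core),
               len(basic) - len(prolif_core), "basic ∩ published proliferating")
    log_filter(filter_log, "involuting_core", len(basic), len(invol_core),
               len(basic) - len(invol_core), "basic ∩ published involuting")

    # --- toxicological layer ------------------------------------------
    tox_matrix, tox_sheet, tox_truth = simdata.simulate_tox_timecourse(config)
    time = tox_sheet.table.set_index("sample")["time"]
    arm = tox_sheet.table.set_index("sample")["arm"]
    spline_res = diffexp.spline_timecourse_test(
        tox_matrix, time, arm,
        diffexp.SplineTestConfig(n_knots=3, moderation=spline_moderation))
    tox_sig = spline_res.loc[spline_res["q"] <= fdr, "feature"].tolist()
    tox_de = geneset_from_iterable("tox_de_rat", tox_sig)
    log_filter(filter_log, "tox_spline_test", len(spline_res), len(tox_de),
               len(spline_res) - len(tox_de), f"interaction q <= {fdr}")

    human_ids = [g.replace("Rno_", "") for g in tox_matrix.feature_ids]
    hmap = crossspecies.HomologMap(simdata.make_homolog_map(
        tox_matrix.feature_ids, human_ids,
        frac_unmapped=homolog_frac_unmapped, seed=config.seed))
    tox_de_human, map_report = crossspecies.map_homologs(tox_de, hmap)
    log_filter(filter_log, "homolog_mapping", len(tox_de),
               map_report["n_mapped_sources"], len(map_report["dropped"]),
               "rat genes with >= 1 human homolog")

    counts, count_sheet, base_truth = simdata.simulate_baseline_counts(config)
    comparable, base_report = crossspecies.constitutive_filter(
        counts, count_sheet.group_of())
    log_filter(filter_log, "constitutive_filter", base_report["n_input"],
               base_report["n_kept"],
               base_report["n_excluded_constitutive"] + base_report["n_missing_panel"],
               "|log2FC(hepatocyte/endothelial)| < 2")

    tox_core, core_report = crossspecies.toxicological_core(
        tox_de_human, comparable, basic)
    log_filter(filter_log, "toxicological_core", len(tox_de_human), len(tox_core),
               len(tox_de_human) - len(tox_core), "∩ comparable ∩ basic")

    # --- miRNA layer --------------------------------------------------
    mir_matrix, links, mir_sheet, mir_truth = simdata.simulate_mirna_layer(config)
    mir_res, mir_sig = mirnamap.mirna_de(
        mir_matrix, mir_sheet.group_of(), ("propranolol", "control"), fdr=fdr)
    log_filter(filter_log, "mirna_de", len(mir_res), len(mir_sig),
               len(mir_res) - len(mir_sig), f"q <= {fdr}")
    mapping = mirnamap.backward_map(list(mir_sig), links, ("9606", "10090"))

    coverage_reports = []
    biomarkers = {}
    for core in (prolif_core, invol_core, tox_core):
        if len(core):
            coverage_reports.append(mirnamap.coverage(core, mapping))
            biomarkers[core.name] = mirnamap.putative_biomarkers(core, mapping)
    sole = mirnamap.sole_targeting_mirnas(
        mapping, {"proliferating": prolif_core, "involuting": invol_core})

    report = build_report(basic, calls, prolif_core, invol_core, tox_core,
                          coverage_reports, sole, biomarkers, filter_log)
    return PipelineResult(
        config=config, basic=basic, calls=calls,
        prolif_core=prolif_core, invol_core=invol_core,
        tox_de_human=tox_de_human, comparable=comparable, tox_core=tox_core,
        mapping=mapping, coverage_reports=coverage_reports,
        sole_targeting=sole, biomarkers=biomarkers, report=report,
        truths={"ih": ih_truth, "tox": tox_truth, "baseline": base_truth,
                "mirna": mir_truth},
        de_tables={"ih": ih_de, "spline": spline_res, "mirna": mir_res})


def planted_tox_core(result: PipelineResult,
                     homolog_frac_unmapped: float = 0.0) -> set[str]:
    """The planted-truth expectation for the toxicological core.

    Divergent rat genes with a homolog row (the map is regenerated
    deterministically from the same seed), minus constitutively biased
    baseline genes, intersected with the planted basic list.
    """
    truths = result.truths
    divergent_rat = set(truths["tox"].divergent.index[truths["tox"].divergent])
    rat_ids = list(truths["tox"].divergent.index)
    human_ids = [g.replace("Rno_", "") for g in rat_ids]
    hmap = simdata.make_homolog_map(rat_ids, human_ids,
                                    frac_unmapped=homolog_frac_unmapped,
                                    seed=result.config.seed)
    mapped = {h for s, h in zip(hmap["source_id"], hmap["human_id"])
              if s in divergent_rat}
    constitutive = set(
        truths["baseline"].constitutive.index[truths["baseline"].constitutive])
    basic_truth = set(truths["ih"].selected.index[truths["ih"].selected])
    return (mapped - constitutive) & basic_truth
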
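"""End-to-end orchestration: read -> preprocess -> model -> enrich -> write.

Stages run in a fixed order (normalize, peptide filter, impute, fit,
simplify, group/merge, heterotrophy and TAG enrichment), every intermediate
table is persisted as TSV, and a JSON manifest records the configuration,
seed and per-stage row counts so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import enrichment, factorial, io, preprocess
from .core import PipelineConfig
from .enrichment import HETEROTROPHY_TARGET, TAG_TARGETS
from .simulate import SimulationParams, simulate_factorial_proteome, truth_table

log = logging.getLogger("ferroglc")


def run_full_pipeline(
    abundance_path,
    metadata_path,
    out_dir,
    config: PipelineConfig | None = None,
    values_are_log2: bool = False,
    overwrite: bool = False,
) -> dict:
    """Run the complete categorization + enrichment analysis on one dataset.

    Returns a dict with the key result tables and written file paths.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    counts: dict[str, int] = {}

    matrix = io.read_abundance_table(abundance_path, metadata_path, config,
                                     values_are_log2=values_are_log2)
    counts["proteins_read"] = matrix.n_proteins
    log.info("read %d proteins x %d samples", matrix.n_proteins, len(matrix.samples))

    matrix = preprocess.normalize_central_tendency(matrix, config.normalization_center)
    matrix, few_peptides = preprocess.filter_min_peptides(matrix, config.min_unique_peptides)
    counts["proteins_min_peptides"] = matrix.n_proteins
    matrix, never_detected = preprocess.drop_all_missing(matrix)
    counts["proteins_detected"] = matrix.n_proteins
    log.info("filtered: %d below %d peptides, %d never detected; %d remain",
             len(few_peptides), config.min_unique_peptides,
             len(never_detected), matrix.n_proteins)
    matrix = preprocess.impute_missing_conditions(matrix, config.impute_minimum)

    qc_tables: dict[str, pd.DataFrame] = {}
    try:
        qc_tables["pca_summary"] = preprocess.pca_summary(matrix, config.min_unique_peptides)
        corr = preprocess.replicate_correlation(matrix, config.min_unique_peptides)
        qc_tables["replicate_correlation"] = corr.reset_index(names="sample_id")
    except ValueError as err:
        log.warning("QC summaries skipped: %s", err)

    fits = factorial.fit_proteome(matrix)
    equations, adj = factorial.simplify_proteome(fits, config)
    counts["proteins_with_terms"] = sum(1 for e in equations if e.retained)
    log.info("%d/%d proteins received >=1 dominant term",
             counts["proteins_with_terms"], len(equations))

    groups = factorial.assign_subgroups(equations, matrix)
    merged = factorial.merge_groups(groups, config.merge_correlation)
    counts["subgroups"] = len(groups)
    counts["subgroups_merged"] = len(merged)

    cv_report, cv_summary = factorial.cross_validate_reduced(matrix, equations, config)

    enrich_tables = {}
    for analysis, targets in (("heterotrophy", HETEROTROPHY_TARGET), ("tag", TAG_TARGETS)):
        fe, glc = targets[0].fe, targets[0].glc
        for direction in ("lowest", "highest"):
            predicted = (
                enrichment.equation_predicted_extremes(equations, direction, fe=fe, glc=glc)
                if analysis == "heterotrophy" else set()
            )
            table = enrichment.extreme_condition_test(
                matrix, targets, direction, config, equation_predicted=predicted)
            enrich_tables[f"enrichment_{analysis}_{direction}"] = table
            counts[f"{analysis}_{direction}_stringent"] = int((table["tier"] == "stringent").sum())
            counts[f"{analysis}_{direction}_expanded"] = int((table["tier"] != "none").sum())
            log.info("%s %s: %d stringent / %d expanded", analysis, direction,
                     counts[f"{analysis}_{direction}_stringent"],
                     counts[f"{analysis}_{direction}_expanded"])

    membership = pd.DataFrame(
        [{"protein_id": pid, "subgroup": g.label, "subgroup_size": g.size}
         for g in merged for pid in g.members]
    )
    profiles = pd.DataFrame({g.label: g.profile for g in merged}).T
    profiles.index.name = "subgroup"

    tables = {
        "full_fits": factorial.fits_table(fits, adj),
        "simplified_equations": factorial.equations_table(equations),
        "subgroup_membership": membership,
        "subgroup_profiles": profiles.reset_index(),
        "cross_validation": cv_report,
        **qc_tables,
        **enrich_tables,
    }
    paths = io.write_results(
        tables, out_dir, config=config, seed=config.rng_seed, overwrite=overwrite,
        extra_manifest={"stage_counts": counts, "cross_validation_summary": cv_summary},
    )
    return {
        "matrix": matrix,
        "fits": fits,
        "equations": equations,
        "groups": merged,
        "enrichment": enrich_tables,
        "cross_validation": (cv_report, cv_summary),
        "counts": counts,
        "paths": paths,
    }


def demo_dataset(
    out_dir,
    seed: int = 7,
    n_proteins: int = 1000,
    **overrides,
) -> dict[str, Path]:
    """Write a seeded synthetic proteome (+ truth table) for docs and demos.

    The generator plants 2% lowest- and 2% highest-in-heterotrophy proteins
    plus TAG classes among generic-effect and null proteins, mirroring the
    12-condition x 4-replicate design.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = SimulationParams(
        n_proteins=n_proteins,
        rng_seed=seed,
        fraction_lowest_het=overrides.pop("fraction_lowest_het", 0.02),
        fraction_highest_het=overrides.pop("fraction_highest_het", 0.02),
        fraction_tag_high=overrides.pop("fraction_tag_high", 0.02),
        fraction_tag_low=overrides.pop("fraction_tag_low", 0.01),
        **overrides,
    )
    matrix, truths = simulate_factorial_proteome(params)
    paths = {
        "abundance": out_dir / "abundance.tsv",
        "samples": out_dir / "samples.tsv",
        "truth": out_dir / "truth.tsv",
    }
    io.write_abundance_matrix(matrix, paths["abundance"], paths["samples"])
    truth_table(truths).to_csv(paths["truth"], sep="\t", index=False)
    log.info("demo dataset written to %s (%d proteins, seed %d)",
             out_dir, n_proteins, seed)
    return paths
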
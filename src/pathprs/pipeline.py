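"""End-to-end pipeline: simulate/load -> harmonize -> score -> associate
-> meta-analyze -> correct -> heritability -> clinical.

Every output TSV carries ``# key=value`` metadata (package version,
seed, configuration hash); nothing time- or host-dependent is written,
so a run is byte-reproducible from its configuration and seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as pio
from .association import (
    correct_pvalues,
    correlation_matrix,
    effective_tests,
    fit_cohort_associations,
    meta_analyze,
)
from .clinical import clinical_correlation_table, describe_groups
from .config import RunConfig
from .data import PathwayCollection
from .errors import DataError
from .harmonize import harmonize_cohorts
from .heritability import compute_grm, estimate_h2_table
from .scoring import compute_prs_profile, align_alleles
from .simulate import simulate_cohort

logger = logging.getLogger(__name__)

OUTPUT_FILES = (
    "harmonized.tsv",
    "prs.tsv",
    "prs_exclusions.tsv",
    "associations.tsv",
    "meta.tsv",
    "significance.tsv",
    "heritability.tsv",
    "clinical.tsv",
)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the output directory.

    Stage failures raise with a stage-named message; the CLI maps them
    to non-zero exit codes.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"pathprs_version": __version__, "seed": config.seed, "config_hash": config.config_hash()}

    def stage(name):
        logger.info("stage %s", name)

    try:
        if config.simulate is not None:
            stage("simulate")
            sim = config.simulate
            if sim.seed != config.seed:
                sim = type(sim)(**{**sim.to_dict(), "seed": config.seed})
                sim.maf_range = tuple(sim.maf_range)
            genotypes, pathways, sumstats, phenotypes = simulate_cohort(sim)
            data_dir = out / "data"
            data_dir.mkdir(exist_ok=True)
            pio.write_vcf(genotypes, data_dir / "genotypes.vcf", meta)
            pio.write_dosage_tsv(genotypes, data_dir / "dosages.tsv", meta)
            pio.write_sumstats(sumstats, data_dir / "sumstats.tsv", meta)
            pio.write_bed(pathways.gene_table, data_dir / "genes.bed")
            pio.write_gmt(pathways.sets, data_dir / "pathways.gmt")
            pio.write_phenotypes(phenotypes, data_dir / "phenotypes.tsv", meta)
        else:
            stage("load")
            genotypes = pio.read_genotypes(config.genotypes)
            sumstats = pio.read_sumstats(config.sumstats)
            pathways = pio.read_gene_sets(config.pathways, config.genes, window=config.window)
            phenotypes = pio.read_phenotypes(config.phenotypes)
        pathways = PathwayCollection(
            gene_table=pathways.gene_table,
            sets=pathways.sets,
            window=config.window,
            all_snp_sets=pathways.all_snp_sets,
        )
        logger.info("%d samples, %d SNPs, %d pathways", genotypes.n_samples, genotypes.n_snps, len(pathways.sets))
    except DataError as exc:
        raise DataError(f"input stage failed: {exc}") from exc

    stage("harmonize")
    harmonized = harmonize_cohorts(
        phenotypes, remove_sd=config.remove_sd, winsorize_sd=config.winsorize_sd
    )
    pio.write_table(harmonized, out / "harmonized.tsv", meta)
    logger.info(
        "harmonized %d records (%d removed, %d winsorized)",
        len(harmonized),
        int((harmonized["status"] == "removed").sum()),
        int((harmonized["status"] == "winsorized").sum()),
    )

    stage("score")
    profile = compute_prs_profile(genotypes, sumstats, pathways, thresholds=tuple(config.thresholds))
    if profile.empty:
        raise DataError("scoring stage failed: no (pathway, threshold) cell has SNPs")
    pio.write_table(profile, out / "prs.tsv", meta)
    aligned = align_alleles(genotypes, sumstats)
    pio.write_table(
        pd.DataFrame(
            {
                "reason": ["strand_ambiguous", "allele_mismatch", "unmatched_id"],
                "n_snps": [aligned.n_ambiguous_dropped, aligned.n_mismatch_dropped, aligned.n_unmatched],
            }
        ),
        out / "prs_exclusions.tsv",
        meta,
    )

    stage("associate")
    assoc = fit_cohort_associations(harmonized, profile, phenotypes)
    if assoc.empty:
        raise DataError("association stage failed: no cohort cell could be fitted")
    pio.write_table(assoc, out / "associations.tsv", meta)

    stage("meta")
    pooled = meta_analyze(assoc)
    pio.write_table(pooled, out / "meta.tsv", meta)

    stage("correct")
    if config.correction_mode == "effective":
        z_wide = harmonized.pivot_table(index="sample_id", columns="phenotype", values="z")
        widest = max(config.thresholds)
        s_wide = profile[profile["threshold"] == widest].pivot_table(
            index="sample_id", columns="pathway", values="score"
        )
        m_eff_ph = effective_tests(correlation_matrix(z_wide))
        m_eff_prs = effective_tests(correlation_matrix(s_wide))
        flags = correct_pvalues(
            pooled, alpha=config.alpha, mode="effective",
            m_eff_phenotypes=m_eff_ph, m_eff_prs=m_eff_prs,
        )
    else:
        flags = correct_pvalues(pooled, alpha=config.alpha, mode="declared")
    pio.write_table(flags, out / "significance.tsv", meta)

    stage("h2")
    grm = compute_grm(genotypes)
    h2 = estimate_h2_table(grm, harmonized, phenotypes, n_perm=config.n_perm, seed=config.seed)
    pio.write_table(h2, out / "heritability.tsv", meta)

    stage("clinical")
    clin = clinical_correlation_table(harmonized, phenotypes, alpha=config.alpha)
    pio.write_table(clin, out / "clinical.tsv", meta)

    return out


def describe_to_file(phenotypes: pd.DataFrame, path: str | Path, meta: dict | None = None) -> pd.DataFrame:
    """Write a demographics-style group table (means, SDs, F/chi2, p)."""
    table = describe_groups(phenotypes)
    pio.write_table(table, path, meta)
    return table
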
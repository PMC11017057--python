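"""Synthetic multi-cohort generator.

Emulates the data structure of a multi-site schizophrenia imaging-genetics
consortium: per-cohort case/control samples with genotypes under
Hardy-Weinberg equilibrium, a discovery GWAS whose effects are
concentrated in a designated gene pathway, raw ventricular and callosal
volumes with covariate structure and a configurable diagnostic shift in
control-SD units, and clinical measures (GAF, PANSS-like symptom totals,
IQ) with configurable rank correlation to the CC:LV ratio.

Each stage draws from its own named random stream derived from
``config.seed``, so outputs are byte-reproducible and the true SNP
effects used for summary statistics and for phenotypes coincide.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimulationConfig
from .data import (
    CC_PHENOTYPES,
    GenotypeMatrix,
    PathwayCollection,
    VOLUME_PHENOTYPES,
    validate_sumstats,
)
from .errors import ParameterError
from .scoring import map_snps_to_pathway

# Named sub-streams so that adding draws to one stage never perturbs another.
_STREAMS = {"genotypes": 1, "genes": 2, "effects": 3, "sumstats": 4, "phenotypes": 5, "clinical": 6}

#: Control-scale means and SDs (mm^3) of the generated raw volumes,
#: in the range of atlas-based segmentations of adult brains.
_VOLUME_SCALE = {
    "LV": (15_500.0, 7_000.0),
    "CC_anterior": (800.0, 130.0),
    "CC_mid_anterior": (500.0, 90.0),
    "CC_central": (450.0, 80.0),
    "CC_mid_posterior": (450.0, 80.0),
    "CC_posterior": (900.0, 140.0),
    "CC_total": (3_100.0, 450.0),
}

_NONAMBIGUOUS_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAMS[stream]])


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw an individuals x SNPs dosage matrix under Hardy-Weinberg.

    SNPs are independent by default; with ``config.ld_blocks`` set, a
    block-exchangeable latent AR(1) copula with correlation ``ld_rho``
    induces within-block linkage disequilibrium on each haplotype.
    Simulated arrays are strand-aligned, so ref/alt pairs are drawn from
    non-ambiguous combinations.
    """
    config.validate()
    rng = _rng(config, "genotypes")
    m, n = config.n_snps, config.n_samples

    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)

    per_chrom = np.array_split(np.arange(m), config.n_chromosomes)
    chrom = np.empty(m, dtype=int)
    pos = np.empty(m, dtype=int)
    for c, idx in enumerate(per_chrom, start=1):
        chrom[idx] = c
        p = np.sort(rng.integers(1, config.genome_length, size=len(idx)))
        pos[idx] = p + np.arange(len(idx))  # force strictly increasing

    pair_idx = rng.integers(0, len(_NONAMBIGUOUS_PAIRS), size=m)
    ref = np.array([_NONAMBIGUOUS_PAIRS[i][0] for i in pair_idx])
    alt = np.array([_NONAMBIGUOUS_PAIRS[i][1] for i in pair_idx])

    if config.ld_blocks:
        dosages = _ld_dosages(rng, n, mafs, config.ld_blocks, config.ld_rho)
    else:
        dosages = rng.binomial(2, mafs, size=(n, m)).astype(float)

    snp_map = pd.DataFrame(
        {
            "snp_id": [f"snp{i:06d}" for i in range(m)],
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "maf": mafs,
        }
    )
    order = np.lexsort((snp_map["pos"].to_numpy(), snp_map["chrom"].to_numpy()))
    snp_map = snp_map.iloc[order].reset_index(drop=True)
    dosages = dosages[:, order]

    sample_ids = [f"ind{i:05d}" for i in range(n)]
    return GenotypeMatrix(dosages=dosages, snp_map=snp_map, sample_ids=sample_ids).validate()


def _ld_dosages(rng, n, mafs, n_blocks, rho):
    """Haplotype-level Gaussian AR(1) copula within blocks of SNPs."""
    m = len(mafs)
    thresholds = stats.norm.ppf(mafs)
    dosages = np.zeros((n, m))
    for hap in range(2):
        z = np.empty((n, m))
        for idx in np.array_split(np.arange(m), n_blocks):
            prev = None
            for j in idx:
                eps = rng.standard_normal(n)
                prev = eps if prev is None else rho * prev + np.sqrt(1 - rho**2) * eps
                z[:, j] = prev
        dosages += (z < thresholds).astype(float)
    return dosages


def simulate_pathways(config: SimulationConfig) -> PathwayCollection:
    """Lay out genes on the simulated genome and form the pathway sets.

    Produces the five gene-set pathways, the single-gene MIR137 score,
    and the unrestricted genome-wide set.  Gene lengths are drawn from
    5-100 kb; the MIR137 gene itself is kept out of the five pathway
    sets (it regulates them; it is not a member).
    """
    config.validate()
    rng = _rng(config, "genes")
    g = config.n_genes
    if g < 10:
        raise ParameterError("n_genes must be >= 10 to populate the pathway sets")

    lengths = rng.integers(5_000, 100_000, size=g)
    chrom = rng.integers(1, config.n_chromosomes + 1, size=g)
    start = rng.integers(1, config.genome_length - 100_000, size=g)
    names = [f"gene{i:04d}" for i in range(g)]

    gene_table = pd.DataFrame(
        {"gene": names, "chrom": chrom, "start": start, "end": start + lengths}
    ).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    shuffled = list(rng.permutation(gene_table["gene"].to_numpy()))
    mir137 = shuffled.pop()  # reserved: regulator gene, excluded from the pathway sets
    gene_table.loc[gene_table["gene"] == mir137, "gene"] = "MIR137"

    n_large = max(3, g // 6)
    n_small = max(3, g // 8)
    cuts = np.cumsum([n_large, n_large, n_small, n_small])
    sets = {
        "ephrin": tuple(shuffled[: cuts[0]]),
        "axon_guidance": tuple(shuffled[cuts[0]:cuts[1]]),
        "LTP": tuple(shuffled[cuts[1]:cuts[2]]),
        "PKA": tuple(shuffled[cuts[2]:cuts[3]]),
        "mir137_targets": tuple(sorted(rng.choice(shuffled, size=max(4, int(0.4 * g)), replace=False))),
        "mir137_gene": ("MIR137",),
        "genome_wide": (),
    }
    return PathwayCollection(gene_table=gene_table, sets=sets).validate()


def true_effects(genotypes: GenotypeMatrix, pathways: PathwayCollection, config: SimulationConfig) -> np.ndarray:
    """True per-SNP log odds ratios on the liability scale.

    A fraction ``pathway_effect_fraction`` of the total squared-effect
    budget ``total_effect_var`` is spread over SNPs inside the gene
    windows of ``config.target_pathway``; the remainder over all other
    SNPs.  Deterministic in ``config.seed``.
    """
    rng = _rng(config, "effects")
    in_set = map_snps_to_pathway(
        genotypes.snp_map, pathways.genes_of(config.target_pathway), window=pathways.window
    )
    mask = genotypes.snp_map["snp_id"].isin(in_set).to_numpy()
    if not mask.any():
        raise ParameterError(f"target pathway {config.target_pathway!r} covers no SNPs")

    m_in = int(mask.sum())
    m_out = int((~mask).sum())
    frac = config.pathway_effect_fraction if m_out else 1.0
    b = np.zeros(genotypes.n_snps)
    var_in = config.total_effect_var * frac / m_in
    b[mask] = rng.normal(0.0, np.sqrt(var_in), size=m_in) if var_in > 0 else 0.0
    if m_out:
        var_out = config.total_effect_var * (1.0 - frac) / m_out
        b[~mask] = rng.normal(0.0, np.sqrt(var_out), size=m_out) if var_out > 0 else 0.0
    return b


def simulate_sumstats(
    genotypes: GenotypeMatrix, pathways: PathwayCollection, config: SimulationConfig
) -> pd.DataFrame:
    """Discovery GWAS summary statistics consistent with the true effects.

    The estimated log odds ratio is the true effect plus sampling noise
    at a case-control discovery sample of ``discovery_n`` individuals
    (SE approx. ``2 / sqrt(N * 2p(1-p))``); the stored p-value is the
    two-sided normal tail of the resulting Wald z-statistic.
    """
    b = true_effects(genotypes, pathways, config)
    rng = _rng(config, "sumstats")
    maf = genotypes.snp_map["maf"].to_numpy()
    se = 2.0 / np.sqrt(config.discovery_n * 2.0 * maf * (1.0 - maf))
    bhat = b + rng.normal(0.0, se)
    z = bhat / se
    p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), 1e-300)
    out = pd.DataFrame(
        {
            "snp_id": genotypes.snp_map["snp_id"],
            "chrom": genotypes.snp_map["chrom"],
            "pos": genotypes.snp_map["pos"],
            "effect_allele": genotypes.snp_map["alt"],
            "other_allele": genotypes.snp_map["ref"],
            "odds_ratio": np.exp(bhat),
            "p_value": p,
        }
    )
    return validate_sumstats(out)


def _standardized_dosages(genotypes: GenotypeMatrix) -> np.ndarray:
    x = genotypes.dosages
    p = np.nanmean(x, axis=0) / 2.0
    sd = np.sqrt(2.0 * p * (1.0 - p))
    sd = np.where(sd > 0, sd, 1.0)
    return (np.nan_to_num(x, nan=0.0) - 2.0 * p) / sd


def _standardize(v: np.ndarray) -> np.ndarray:
    s = v.std()
    return (v - v.mean()) / s if s > 0 else np.zeros_like(v)


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    sumstats: pd.DataFrame,
    pathways: PathwayCollection,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Raw volumes, diagnosis, cohorts, and covariates for every sample.

    Each volume is cohort baseline + genetic component (scaled to
    ``h2_target`` of the core variance and correlated with the discovery
    risk score, positively for LV and negatively for CC) + covariate
    effects (age, sex, total brain volume, scanner offsets, ancestry
    components) + shared latent factors giving the LV-CC anticorrelation
    + Gaussian noise.  Cases are then shifted by ``case_shift_sd`` times
    the realized within-cohort control SD, so the post-harmonization
    case mean lands on the configured shift by construction.
    """
    config.validate()
    n = genotypes.n_samples
    if n != config.n_samples:
        raise ParameterError(
            f"genotype matrix has {n} samples but config implies {config.n_samples}"
        )
    rng = _rng(config, "phenotypes")

    cohort = np.repeat([f"cohort{c + 1}" for c in range(config.n_cohorts)], config.n_per_cohort)
    is_case = np.tile(
        np.r_[np.ones(config.n_cases_per_cohort, bool), np.zeros(config.n_controls_per_cohort, bool)],
        config.n_cohorts,
    )
    diagnosis = np.where(is_case, "case", "control")

    # Covariates; sex composition and age follow typical case-control demographics.
    sex = np.where(is_case, rng.random(n) < 0.29, rng.random(n) < 0.48).astype(int)  # 1 = female
    age = np.where(is_case, rng.normal(35.2, 11.8, n), rng.normal(35.9, 12.9, n)).clip(15, 90)
    tbv = rng.normal(1_250_000.0, 110_000.0, n) - 100_000.0 * sex
    if config.ancestry_from_genotypes:
        xs = _standardized_dosages(genotypes)
        u, s, _ = np.linalg.svd(xs - xs.mean(axis=0), full_matrices=False)
        anc = u[:, :4] * np.sqrt(n)
    else:
        anc = rng.standard_normal((n, 4))

    # One multi-scanner cohort exercises scanner dummies downstream.
    scanner = np.array([f"{c}_s1" for c in cohort], dtype=object)
    first = cohort == "cohort1"
    scanner[first & (rng.random(n) < 0.5)] = "cohort1_s2"
    scanner_names, scanner_codes = np.unique(scanner, return_inverse=True)
    scanner_offsets = rng.normal(0.0, 0.15, size=len(scanner_names))

    # Genetic components on the standardized scale.
    b = true_effects(genotypes, pathways, config)
    xs = _standardized_dosages(genotypes)
    g_risk = xs @ b
    g_risk = _standardize(g_risk) if g_risk.std() > 0 else np.zeros(n)

    h2 = config.h2_target
    rho_g = config.genetic_corr_with_risk
    age_z = (age - 36.0) / 12.0
    tbv_z = (tbv - 1_200_000.0) / 110_000.0
    u_shared = rng.standard_normal(n)   # LV-up / CC-down latent factor
    v_cc = rng.standard_normal(n)       # callosal common factor
    cohort_base = rng.normal(0.0, 0.2, size=config.n_cohorts)
    cohort_idx = np.repeat(np.arange(config.n_cohorts), config.n_per_cohort)

    table = pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "cohort": cohort,
            "diagnosis": diagnosis,
            "scanner": scanner,
            "age": age,
            "sex": sex,
            "tbv": tbv,
            "anc1": anc[:, 0],
            "anc2": anc[:, 1],
            "anc3": anc[:, 2],
            "anc4": anc[:, 3],
        }
    )

    for ph in VOLUME_PHENOTYPES:
        mean_ph, sigma_ph = _VOLUME_SCALE[ph]
        sign = 1.0 if ph == "LV" else -1.0
        g_ind = xs @ rng.normal(0.0, 1.0, size=genotypes.n_snps)
        g_ind = _standardize(g_ind) if g_ind.std() > 0 else np.zeros(n)
        g_ph = sign * rho_g * g_risk + np.sqrt(max(0.0, 1.0 - rho_g**2)) * g_ind

        if ph == "LV":
            noise = 0.5 * u_shared + np.sqrt(0.75) * rng.standard_normal(n)
            b_age, b_sex = 0.25, -0.3
        else:
            load_v = 0.5 if ph == "CC_total" else 0.4
            resid_var = max(0.05, 1.0 - 0.16 - load_v**2)
            noise = -0.4 * u_shared + load_v * v_cc + np.sqrt(resid_var) * rng.standard_normal(n)
            b_age, b_sex = -0.1, -0.2

        core = np.sqrt(h2) * g_ph + np.sqrt(1.0 - h2) * noise
        cscale = config.covariate_effect_scale
        z = core + cscale * (
            cohort_base[cohort_idx]
            + b_age * age_z
            + b_sex * sex
            + 0.3 * tbv_z
            + scanner_offsets[scanner_codes]
            + 0.05 * anc.sum(axis=1)
        )
        raw = mean_ph + sigma_ph * z

        shift = config.case_shift_sd.get(ph, 0.0)
        if shift != 0.0:
            for c in range(config.n_cohorts):
                ctrl = (cohort_idx == c) & ~is_case
                cas = (cohort_idx == c) & is_case
                sd_ctrl = raw[ctrl].std(ddof=1)
                raw[cas] += shift * sd_ctrl
        table[ph] = np.maximum(raw, 1.0)

    return table


def simulate_clinical(phenotypes: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Attach GAF, a PANSS-like symptom total, and IQ to the table.

    Each measure is built from a Gaussian copula on the van der Waerden
    scores of the CC:LV ratio at the configured rank correlation
    (``gaf_rho``, ``panss_rho``, ``iq_rho``), with mild age/sex
    confounding and a small diagnostic offset, then mapped monotonically
    onto its clinical scale.  Symptom totals are cases-only.
    """
    config.validate()
    for col in ("CC_total", "LV", "age", "sex", "diagnosis"):
        if col not in phenotypes.columns:
            raise ParameterError(f"phenotype table lacks required column {col!r}")
    rng = _rng(config, "clinical")
    out = phenotypes.copy()
    n = len(out)

    ratio = out["CC_total"].to_numpy() / out["LV"].to_numpy()
    ranks = stats.rankdata(ratio)
    z_ratio = stats.norm.ppf((ranks - 0.5) / n)
    age_z = (out["age"].to_numpy() - 36.0) / 12.0
    sex = out["sex"].to_numpy()
    case = (out["diagnosis"].to_numpy() == "case").astype(float)

    def latent(rho: float) -> np.ndarray:
        return rho * z_ratio + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)

    gaf = latent(config.gaf_rho) - 0.1 * age_z + 0.1 * sex - 0.3 * case
    out["GAF"] = np.round(1.0 + 99.0 * stats.norm.cdf(_standardize(gaf)), 1)

    panss = latent(config.panss_rho) + 0.1 * age_z - 0.3 * (out["GAF"].to_numpy() - 50.0) / 25.0
    panss_score = np.round(55.0 + 18.0 * _standardize(panss)).clip(30, 120)
    out["PANSS_total"] = np.where(case == 1.0, panss_score, np.nan)

    iq = latent(config.iq_rho) - 0.05 * age_z - 0.8 * case
    out["IQ"] = np.round(100.0 + 15.0 * iq).clip(40, 160)
    return out


def simulate_cohort(config: SimulationConfig):
    """Run the full generator; returns (genotypes, pathways, sumstats, phenotypes)."""
    genotypes = simulate_genotypes(config)
    pathways = simulate_pathways(config)
    sumstats = simulate_sumstats(genotypes, pathways, config)
    phenotypes = simulate_clinical(simulate_phenotypes(genotypes, sumstats, pathways, config), config)
    return genotypes, pathways, sumstats, phenotypes
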
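# pathprs

Pathway-restricted polygenic scoring and multi-cohort association
analysis for brain imaging endophenotypes.

`pathprs` is aimed at imaging-genetics analysts studying how polygenic
risk concentrated in specific biological pathways relates to volumetric
brain measures in case-control consortia — the motivating application
being schizophrenia, where enlarged lateral ventricles (LV), reduced
corpus callosum (CC) volumes, and their ratio behave as heritable
endophenotypes.  Because individual-level consortium data cannot be
shipped, the package includes a first-class synthetic multi-cohort
generator with the same statistical structure, so the entire pipeline is
testable end to end.

## What it computes

**Harmonization.** Raw volumes and their six CC:LV ratios are converted
per cohort to control-referenced Z-scores,

    Z_i = (x_i − M_HC) / SD_HC,

where `M_HC` and `SD_HC` are the cohort's control mean and sample SD.
Records with |Z| ≥ 6 are removed and remaining |Z| ≥ 4 winsorized to ±4.

**Pathway polygenic scores.** For each gene set (ephrin receptor
signaling, axonal guidance, long-term potentiation, PKA signaling,
MIR137 targets, the MIR137 gene alone, and an unrestricted genome-wide
set), SNPs within 20 kb of any member gene are selected at discovery
p-value thresholds t ∈ {5e-8, 1e-6, 1e-5, 1e-4, 1e-3, 0.05} and scored
as

    PRS_i = Σ_s  log(OR_s) · d_is,

with `d_is` the risk-allele dosage (0–2), after allele alignment to the
discovery effect allele (strand-ambiguous A/T and C/G SNPs dropped).

**Association and meta-analysis.** Per cohort, OLS of each harmonized
phenotype on the standardized PRS with covariates age, sex, age², age×sex,
age²×sex, total brain volume, scanner dummies, and 4 ancestry components;
variance explained is the incremental R² over the covariate-only model.
Cohort betas are pooled by fixed-effects inverse variance,
w_k = 1/SE_k², with Cochran's Q and I².  Multiple testing uses either a
declared 7 scores × 7 phenotypes Bonferroni family or the
eigenvalue-based effective number of tests (M_eff = Σ 1(λ_i ≥ 1) +
(λ_i − ⌊λ_i⌋)); the six thresholds of one pathway count as one test.

**SNP heritability.** From a genetic relationship matrix
K = XXᵀ/M on standardized dosages, h² of each covariate-projected
phenotype is estimated by Haseman–Elston regression of the phenotypic
cross-products y_i y_j on K_ij over pairs, with a delete-one-individual
jackknife SE, a permutation p-value, and an exact-likelihood grid search
as a cross-check estimator.

**Clinical correlates.** Spearman partial correlations (age- and
sex-adjusted) between harmonized phenotypes and functioning (GAF),
symptom, and IQ measures with Benjamini–Hochberg FDR, plus a
demographics-style group table (two-group ANOVA F from summary
statistics, Pearson χ² from counts).

## Worked example

```python
from pathprs import SimulationConfig, simulate_cohort
from pathprs.harmonize import harmonize_cohorts
from pathprs.scoring import compute_prs_profile
from pathprs.association import fit_cohort_associations, InverseVarianceMeta

cfg = SimulationConfig(n_cohorts=3, n_cases_per_cohort=150,
                       n_controls_per_cohort=180, n_snps=1000,
                       n_genes=40, seed=42)
genotypes, pathways, sumstats, phenotypes = simulate_cohort(cfg)
harmonized = harmonize_cohorts(phenotypes)
profile = compute_prs_profile(genotypes, sumstats, pathways, thresholds=(1e-4, 0.05))
assoc = fit_cohort_associations(harmonized, profile, phenotypes)
cell = assoc[(assoc.phenotype == "LV") & (assoc.pathway == "ephrin")
             & (assoc.threshold == 0.05)]
print(InverseVarianceMeta(cell["beta"], cell["se"]).fit().summary())
```

prints

```
Inverse-variance meta-analysis (fixed effects, k=3)
  pooled beta = 0.2840  SE = 0.0289  p = 7.46e-23
  95% CI = [0.2274, 0.3405]
  Q = 0.307  I2 = 0.0%
```

i.e. one SD of the ephrin-pathway score shifts lateral-ventricle volume
by 0.28 control-SD units, pooled over the three cohorts with no
detectable heterogeneity — recovering the risk-aligned ventricular
effect the generator planted.  Heritability of the same phenotype:

```
SNP-based heritability (Haseman-Elston regression)
  n = 990  SNPs = 1000
  h2 = 0.518 (unclipped 0.518)  SE = 0.091
  95% CI = [0.340, 0.696]
  permutation p = 0.005 (199 permutations)
```

A `pathprs` command-line interface exposes the same stages
(`simulate | harmonize | score | associate | meta | h2 | clinical |
describe | run`); `pathprs run --config pipeline.yaml` executes the
whole pipeline into a directory of TSV outputs whose headers record the
package version, seed, and configuration hash, and which are
byte-reproducible for a fixed seed.

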
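# Methods

This note documents the models, estimators, and numerical choices
behind `pathprs`, and what the synthetic generator does and does not
emulate.

## Phenotype harmonization

Volumes arrive on cohort-specific scales (scanner, sequence, site
demographics), so each cohort-phenotype cell is standardized against
that cohort's healthy controls: `Z_i = (x_i − M_HC)/SD_HC` with the
control *sample* SD (n−1 denominator; the conventional choice for
reference-group standardization).  Ratios are computed on raw volumes
before any standardization, since a ratio of Z-scores has no meaning.
Outlier handling is a single pass on the standardized scale — |Z| ≥ 6
removed, then remaining |Z| ≥ 4 set to sign(Z)·4 — with inclusive
boundaries and no re-referencing of `M_HC`/`SD_HC` after removal.  The
operation is idempotent and leaves |Z| ≤ 4.  Thresholds are read
against the control-referenced scale rather than the full-sample SD;
with a shifted case distribution the two differ, and the
control-referenced reading keeps the rule interpretable as "SD from the
healthy norm".  Raw volumes are never pooled across cohorts.
`residualize` provides covariate-adjusted values for descriptive means
and plots only; inferential models always carry the covariates inside
the regression.

## Pathway scores

Scores are **sums** of log(OR)-weighted risk-allele dosages (a per-SNP
averaging option exists for cross-threshold comparability, off by
default).  Gene windows are ±20 kb, inclusive at both flanks, on
1-based positions; BED input (0-based half-open) is converted on read.
A SNP covered by several genes of a set counts once.  Allele alignment
attaches the weight to the dosage-counted allele and reflects the
dosage (2 − d) when the discovery effect allele is the other allele;
A/T and C/G SNPs are dropped by default because strand cannot be
verified from the allele pair.  Missing dosages are imputed at twice
the target-sample allele frequency, which leaves the score expectation
unchanged.  The MIR137 single-gene score uses the same 20 kb window by
default; an `index_snp` mode keeps only the smallest-p SNP in the
window.  LD clumping (greedy, p-value ordered, r² and window
configurable) is available but off by default — the scoring contract
is defined on the full SNP set, and the simulator's default SNPs are
unlinked.

## Association and meta-analysis

Per cohort, OLS of the harmonized phenotype on the within-cohort
standardized PRS plus age, sex, age², age×sex, age²×sex, total brain
volume, scanner dummies (multi-scanner cohorts only), and four ancestry
components.  Age is centered before forming the quadratic and
interaction terms to keep the design conditioned; collinear columns are
pruned with a warning.  Listwise deletion per cell; cohorts below a
minimum complete-case count are skipped.  Standardizing the PRS within
cohort makes betas comparable across cohorts, which the pooling step
requires.  Variance explained is reported as incremental R² of the PRS
over the covariate-only model (full-model R² is also retained).

Pooling is fixed-effects inverse variance: w_k = 1/SE_k², pooled SE
(Σw)^(−1/2), p from the normal approximation, with Cochran's Q and I²
reported; DerSimonian–Laird random effects are available behind a flag
but are not the primary mode because no heterogeneity model is assumed.
Cases and controls are analyzed together in the primary mode.

Multiple-testing correction supports two families: a declared
7 scores × 7 phenotypes Bonferroni product, and an effective-count mode
dividing α by the product of eigenvalue-based effective numbers of
tests of the phenotype and score correlation matrices,
M_eff = Σ_i [1(λ_i ≥ 1) + (λ_i − ⌊λ_i⌋)], clipped to [1, M].
Eigenvalues are rounded to 10 decimals before flooring so that a
numerically perturbed integer eigenvalue (e.g. 3 − 1e−15) counts as the
integer.  The six thresholds of one pathway are one test: a
(phenotype, pathway) cell is flagged on its minimum pooled p.  The
ratio phenotypes are not counted as independent phenotypes in the
declared family (7, not 13); the effective mode measures the actual
redundancy instead.

## SNP heritability

The variance-component model is y = g + e with cov(g) = h²K,
cov(e) = (1−h²)I on the standardized, covariate-projected phenotype.
K = XXᵀ/M from dosages centered by 2p and scaled by √(2p(1−p)) using
sample allele frequencies; SNPs with MAF < 0.01 (configurable) and
monomorphic SNPs are excluded.  The point estimator is Haseman–Elston
regression — slope of y_i y_j on K_ij with intercept over the n(n−1)/2
unordered pairs — clipped to [0, 1] with the unclipped value retained.

Pairs sharing an individual are dependent, and the sample
standardization of y and the zero-row-sum structure of K couple the
pair products; a naive OLS standard error is anti-conservative by
roughly 5–10% in simulation.  The SE is therefore a delete-one-
individual jackknife over the slope, computed in O(n²) from row sums;
in null simulations at n = 2000 this yields mildly conservative 95%
intervals (empirical coverage ≈ 0.97–0.99).  Significance is a
permutation p, (1 + #{perm ≥ obs})/(1 + n_perm), permuting the
projected phenotype across individuals.

A cross-check estimator maximizes the exact Gaussian likelihood of the
standardized phenotype under σ²(h²K + (1−h²)I) over a grid
h² ∈ {0, 0.01, …, 1}, profiling σ² through the eigendecomposition of K.
Agreement between the two estimators is asserted on a small
related-sample design (25 duplicate-genotype pairs, M = 3000): with 50
*unrelated* individuals the GRM is numerically near the identity and h²
is weakly identified for any estimator, so the two estimates decouple;
relatedness concentrates the identifying signal and both estimators
track it to within 0.1.  Ratio phenotypes pass through exactly the same
estimation path as volumes.

## Clinical statistics

Partial Spearman correlation is operationalized as rank-transform
(average ranks for ties) → residualize each rank vector on the
covariates (age, sex) → Pearson correlation of residuals, with p from
the t approximation on n − 2 − k df.  It is invariant to strictly
monotone transforms of either variable.  Group contrasts reproducible
from printed summaries use the two-group ANOVA F from (n, mean, SD) —
identically the squared pooled-variance t — and the Pearson χ² on
counts without continuity correction.  Recomputation from printed
summaries matches published values only up to rounding of the printed
means/SDs (about 1%); counts-based χ² is exact.  The FDR family for
clinical correlations is all phenotype × measure pairs at once
(Benjamini–Hochberg).

## Synthetic cohort generator

The generator is the package's study-design stand-in for a multi-site
case-control consortium and defines the conditions under which the
pipeline is validated:

- **Structure.** Three cohorts by default (the smallest structure that
  exercises meta-analysis), ~0.8 case:control ratio, one cohort with
  two scanners.  Acceptance-scale runs use 1000 per arm per cohort.
- **Genotypes.** Hardy–Weinberg dosages at MAFs uniform on the
  configured range, independent SNPs by default; an optional
  block-exchangeable AR(1) copula induces within-block LD.  Ref/alt
  pairs are drawn non-ambiguous (simulated arrays are strand-aligned);
  ambiguous-SNP handling is exercised by constructed fixtures instead.
- **Discovery GWAS.** True log-ORs are zero-mean normal with a
  configurable fraction (default 0.5) of the squared-effect budget on
  SNPs inside the designated pathway's gene windows (default: ephrin).
  Observed log-ORs add sampling noise at SE ≈ 2/√(N·2p(1−p)) for the
  discovery sample size; p-values are the Wald two-sided normal tails.
  The normal effect-size law is a generic polygenic stand-in, not an
  inference about any particular discovery study.
- **Phenotypes.** Each volume is cohort baseline + genetic component
  (scaled to `h2_target` of the core variance; correlated with the
  discovery risk score, positively for LV and negatively for CC, so
  pathway scores associate with volumes in opposite directions) +
  age/sex/TBV/scanner/ancestry effects + shared latent factors giving
  the LV–CC anticorrelation + Gaussian noise.  Cases are then shifted
  by `case_shift_sd` (default +0.5 LV, −0.5 CC) times the *realized*
  within-cohort control SD, so the post-harmonization case mean lands
  on the target by construction.  Volumes are floored at 1 mm³.  The
  seven volumes are generated as seven calibrated phenotypes; additivity
  of CC subregions into the total is not enforced.
- **Demographics.** Sex composition differs by diagnosis (29% vs 48%
  female) and ages are near-identical across groups, mimicking typical
  consortium demographics.  This deliberately makes the *raw* case
  shift exceed the planted one (male-skewed cases have larger
  ventricles), which is why calibration is checked on the
  covariate-adjusted diagnosis contrast.
- **Clinical measures.** Gaussian copula on the van der Waerden scores
  of the CC:LV ratio at the configured rank correlation (GAF +0.3,
  symptoms −0.2, IQ +0.2 by default), mild age/sex confounding, a small
  diagnostic offset, then monotone mapping to clinical scales (GAF
  1–100, symptom total 30–120 cases-only, IQ 40–160).
- **Ancestry.** Four N(0,1) components by default; a flag derives them
  from genotype PCA instead.

What it does **not** emulate: realistic LD from reference panels,
genotype–diagnosis dependence (diagnosis is independent of genotype, so
case status is purely a phenotypic shift), family structure, non-Gaussian
volume distributions, site-specific missingness, or real MRI artifacts.
Passing tests therefore demonstrate the estimators' internal
correctness and calibration under a clean additive model, not
robustness to those real-data features.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to keep Monte
Carlo error small relative to the asserted tolerances: 2000 individuals
× 5000 SNPs and 50 replicates for heritability recovery (MC SE of the
mean ≈ 0.009 against a ±0.05 band); 2000 simulated three-cohort
meta-analyses for the null rejection rate (binomial SE ≈ 0.005 against
[0.04, 0.06]); 3 cohorts × 1000/arm for the case-shift calibration
(SE ≈ 0.02 against [0.4, 0.6]).  The demo pipeline (3 × 150 with 600
SNPs) is run twice and compared byte-for-byte; outputs carry no
timestamps or host information, all group-bys are sorted, and floats
are written at %.10g, so determinism is exact.  Degenerate inputs
(constant PRS, phenotype inside the covariate span, GRM with constant
off-diagonals, zero control SD) raise typed errors rather than
returning numbers.
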
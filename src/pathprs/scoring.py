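"""Pathway-restricted and genome-wide polygenic scoring.

A score for an individual is the sum over selected SNPs of the number of
risk alleles carried (0, 1, or 2, or an imputed dosage) weighted by the
log of the discovery-GWAS odds ratio for that allele.  SNP selection
combines (a) gene membership — every SNP within a window (default 20 kb)
of any gene in the pathway — and (b) a discovery p-value threshold grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, PathwayCollection, validate_sumstats
from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)

_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


def map_snps_to_pathway(snp_map: pd.DataFrame, genes: pd.DataFrame, window: int = 20_000) -> set[str]:
    """SNP ids lying within ``window`` bp of any gene in the set.

    Positions are 1-based; the window is inclusive on both flanks, so a
    SNP at exactly ``start - window`` or ``end + window`` is included.
    Each SNP appears once regardless of how many genes cover it.
    """
    if window < 0:
        raise ParameterError("window must be non-negative")
    if genes.empty:
        return set()
    snp_chrom = snp_map["chrom"].to_numpy()
    snp_pos = snp_map["pos"].to_numpy()
    if not np.isin(genes["chrom"].to_numpy(), snp_chrom).any():
        logger.warning("no gene chromosome matches the SNP map; empty pathway SNP set")
        return set()
    hit = np.zeros(len(snp_map), dtype=bool)
    for _, g in genes.iterrows():
        hit |= (snp_chrom == g["chrom"]) & (snp_pos >= g["start"] - window) & (snp_pos <= g["end"] + window)
    return set(snp_map.loc[hit, "snp_id"])


@dataclass
class AlignedWeights:
    """Per-SNP log-OR weights aligned to the dosage (alt) allele.

    ``table`` columns: ``snp_id, weight, flipped, p_value``; ``flipped``
    means the discovery effect allele is the dosage *ref* allele, so the
    weight applies to the complementary count ``2 - dosage``.
    """

    table: pd.DataFrame
    n_ambiguous_dropped: int
    n_mismatch_dropped: int
    n_unmatched: int


def align_alleles(
    genotypes: GenotypeMatrix, sumstats: pd.DataFrame, drop_ambiguous: bool = True
) -> AlignedWeights:
    """Attach log-odds-ratio weights to the dosage-counted allele.

    SNPs are matched by id; the allele pair must agree (in either
    orientation) with the dosage ref/alt pair.  Strand-ambiguous A/T and
    C/G SNPs are dropped by default because their orientation cannot be
    verified.  Irreconcilable allele pairs are dropped with a logged count.
    """
    validate_sumstats(sumstats)
    merged = genotypes.snp_map.merge(sumstats, on="snp_id", how="inner", suffixes=("", "_ss"))
    n_unmatched = len(genotypes.snp_map) - len(merged)

    pair_geno = [frozenset((r, a)) for r, a in zip(merged["ref"], merged["alt"])]
    ambiguous = np.array([p in _AMBIGUOUS for p in pair_geno])
    n_amb = 0
    if drop_ambiguous and ambiguous.any():
        n_amb = int(ambiguous.sum())
        logger.info("dropping %d strand-ambiguous SNPs", n_amb)
        merged = merged[~ambiguous].reset_index(drop=True)

    same = (merged["effect_allele"] == merged["alt"]) & (merged["other_allele"] == merged["ref"])
    flipped = (merged["effect_allele"] == merged["ref"]) & (merged["other_allele"] == merged["alt"])
    ok = same | flipped
    n_mismatch = int((~ok).sum())
    if n_mismatch:
        logger.warning("dropping %d SNPs with irreconcilable allele pairs", n_mismatch)
    merged = merged[ok].reset_index(drop=True)

    table = pd.DataFrame(
        {
            "snp_id": merged["snp_id"],
            "weight": np.log(merged["odds_ratio"].to_numpy()),
            "flipped": (merged["effect_allele"] == merged["ref"]).to_numpy(),
            "p_value": merged["p_value"].to_numpy(),
        }
    )
    return AlignedWeights(table, n_ambiguous_dropped=n_amb, n_mismatch_dropped=n_mismatch, n_unmatched=n_unmatched)


def select_by_threshold(sumstats: pd.DataFrame, threshold: float) -> set[str]:
    """SNP ids with discovery p-value at or below the threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ParameterError(f"threshold must lie in (0, 1], got {threshold!r}")
    return set(sumstats.loc[sumstats["p_value"] <= threshold, "snp_id"])


def compute_prs(
    genotypes: GenotypeMatrix,
    weights: AlignedWeights | pd.DataFrame,
    snp_set: set[str] | None = None,
    average: bool = False,
) -> tuple[np.ndarray, int]:
    """Per-individual weighted dosage score over a SNP set.

    ``score_i = sum_s w_s * d_is`` with ``d`` the risk-allele count
    (``2 - dosage`` for flipped SNPs).  Missing dosages are imputed as
    twice the target-sample allele frequency, which leaves the score
    expectation unchanged.  Returns the score vector and the number of
    SNPs used; raises :class:`DataError` if the set is empty.
    """
    table = weights.table if isinstance(weights, AlignedWeights) else weights
    if snp_set is not None:
        table = table[table["snp_id"].isin(snp_set)]
    if table.empty:
        raise DataError("no SNPs remain for this pathway/threshold after alignment")

    idx = genotypes.snp_map.set_index("snp_id").index.get_indexer(table["snp_id"])
    if (idx < 0).any():
        raise DataError("aligned weights reference SNPs absent from the genotype matrix")

    d = genotypes.dosages[:, idx]
    if np.isnan(d).any():
        freq = np.nanmean(d, axis=0)  # target-sample alt-allele frequency * 2 / 2
        d = np.where(np.isnan(d), freq, d)
    flipped = table["flipped"].to_numpy()
    d = np.where(flipped, 2.0 - d, d)
    w = table["weight"].to_numpy()
    scores = d @ w
    n_snps = len(table)
    if average:
        scores = scores / n_snps
    return scores, n_snps


def clump_by_ld(
    genotypes: GenotypeMatrix,
    weights: AlignedWeights,
    r2_max: float = 0.1,
    window: int = 250_000,
) -> AlignedWeights:
    """Greedy p-value-ordered LD clumping on the target genotypes.

    Walks SNPs from the smallest discovery p-value, keeping a SNP only
    if its squared dosage correlation with every already-kept SNP within
    ``window`` bp on the same chromosome is below ``r2_max``.  Off by
    default in the pipeline; provided for conventional PRS behavior.
    """
    table = weights.table.merge(genotypes.snp_map[["snp_id", "chrom", "pos"]], on="snp_id")
    table = table.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    col = genotypes.snp_map.set_index("snp_id").index.get_indexer(table["snp_id"])
    x = genotypes.dosages[:, col]
    x = np.nan_to_num(x - np.nanmean(x, axis=0), nan=0.0)
    norms = np.sqrt((x**2).sum(axis=0))
    norms[norms == 0] = 1.0

    kept: list[int] = []
    for i in range(len(table)):
        ok = True
        for j in kept:
            if table.at[i, "chrom"] != table.at[j, "chrom"]:
                continue
            if abs(table.at[i, "pos"] - table.at[j, "pos"]) > window:
                continue
            r = (x[:, i] @ x[:, j]) / (norms[i] * norms[j])
            if r * r >= r2_max:
                ok = False
                break
        if ok:
            kept.append(i)
    out = table.iloc[kept][["snp_id", "weight", "flipped", "p_value"]].reset_index(drop=True)
    return AlignedWeights(out, weights.n_ambiguous_dropped, weights.n_mismatch_dropped, weights.n_unmatched)


def compute_prs_profile(
    genotypes: GenotypeMatrix,
    sumstats: pd.DataFrame,
    pathways: PathwayCollection,
    thresholds: tuple[float, ...],
    average: bool = False,
    mir137_mode: str = "gene_window",
    clump: bool = False,
    r2_max: float = 0.1,
) -> pd.DataFrame:
    """Score every (pathway, threshold) cell for every individual.

    Returns a long table ``sample_id, pathway, threshold, score, n_snps``.
    Cells with no surviving SNPs are omitted (they are flagged and
    excluded from association).  ``mir137_mode`` chooses between the
    default 20 kb gene-window score and ``"index_snp"``, which keeps only
    the smallest-p SNP within the window.
    """
    if mir137_mode not in ("gene_window", "index_snp"):
        raise ParameterError(f"unknown mir137_mode {mir137_mode!r}")
    weights = align_alleles(genotypes, sumstats)
    if clump:
        weights = clump_by_ld(genotypes, weights, r2_max=r2_max)
    aligned_ids = set(weights.table["snp_id"])

    rows = []
    for name in pathways.sets:
        if name in pathways.all_snp_sets:
            in_set = aligned_ids
        else:
            in_set = map_snps_to_pathway(genotypes.snp_map, pathways.genes_of(name), pathways.window)
            in_set &= aligned_ids
        if name == "mir137_gene" and mir137_mode == "index_snp" and in_set:
            sub = weights.table[weights.table["snp_id"].isin(in_set)]
            in_set = {sub.loc[sub["p_value"].idxmin(), "snp_id"]}
        for thr in thresholds:
            selected = in_set & select_by_threshold(sumstats, thr)
            if not selected:
                logger.info("pathway %s at threshold %g: no SNPs, cell skipped", name, thr)
                continue
            scores, n_snps = compute_prs(genotypes, weights, selected, average=average)
            for sid, s in zip(genotypes.sample_ids, scores):
                rows.append((sid, name, thr, s, n_snps))
    return pd.DataFrame(rows, columns=["sample_id", "pathway", "threshold", "score", "n_snps"])
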
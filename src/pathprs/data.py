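"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Dosages count copies of the ``alt`` allele and live in ``[0, 2]``
  (hard calls in ``{0, 1, 2}``, imputed dosages anywhere in between).
* SNP positions are 1-based; gene intervals are stored 1-based inclusive
  (BED input is converted on read).
* The 13 analysis phenotypes are the 7 raw volumes (lateral ventricles,
  five corpus-callosum subregions, total corpus callosum) plus the 6
  CC:LV ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

#: Raw volumetric phenotypes (mm^3).
VOLUME_PHENOTYPES: tuple[str, ...] = (
    "LV",
    "CC_anterior",
    "CC_mid_anterior",
    "CC_central",
    "CC_mid_posterior",
    "CC_posterior",
    "CC_total",
)

#: Corpus-callosum measures (numerators of the ratio phenotypes).
CC_PHENOTYPES: tuple[str, ...] = VOLUME_PHENOTYPES[1:]

#: Dimensionless CC:LV ratio phenotypes.
RATIO_PHENOTYPES: tuple[str, ...] = tuple(f"{cc}_to_LV" for cc in CC_PHENOTYPES)

#: All 13 analysis phenotypes (7 volumes + 6 ratios).
ANALYSIS_PHENOTYPES: tuple[str, ...] = VOLUME_PHENOTYPES + RATIO_PHENOTYPES

#: Named pathway scores computed by default (5 gene-set pathways, the
#: single-gene MIR137 score, and the unrestricted genome-wide score).
PATHWAY_NAMES: tuple[str, ...] = (
    "ephrin",
    "axon_guidance",
    "LTP",
    "PKA",
    "mir137_targets",
    "mir137_gene",
    "genome_wide",
)

SNP_MAP_COLUMNS = ("snp_id", "chrom", "pos", "ref", "alt", "maf")
SUMSTATS_COLUMNS = ("snp_id", "chrom", "pos", "effect_allele", "other_allele", "odds_ratio", "p_value")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-dosage matrix with its SNP map.

    Parameters
    ----------
    dosages
        ``(n_samples, n_snps)`` float array of alt-allele dosages in
        ``[0, 2]``; ``NaN`` marks a missing call.
    snp_map
        One row per SNP with columns ``snp_id, chrom, pos, ref, alt, maf``,
        sorted by ``(chrom, pos)``.
    sample_ids
        Unique sample identifiers, one per dosage row.
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    sample_ids: list[str]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def validate(self) -> "GenotypeMatrix":
        if self.dosages.ndim != 2:
            raise DataError("dosages must be a 2-D array")
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_map)):
            raise DataError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.snp_map)} SNPs"
            )
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise DataError("dosages must lie in [0, 2]")
        missing = [c for c in SNP_MAP_COLUMNS if c not in self.snp_map.columns]
        if missing:
            raise DataError(f"snp_map missing columns: {missing}")
        if self.snp_map["snp_id"].duplicated().any():
            raise DataError("snp_map ids are not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("sample ids are not unique")
        key = self.snp_map[["chrom", "pos"]]
        if not key.equals(key.sort_values(["chrom", "pos"]).reset_index(drop=True)):
            raise DataError("snp_map must be sorted by (chrom, pos)")
        return self

    def empirical_maf(self) -> np.ndarray:
        """Alt-allele frequency per SNP from the sample, folded to <= 0.5."""
        p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)


def validate_sumstats(sumstats: pd.DataFrame) -> pd.DataFrame:
    """Check a discovery summary-statistics table in place.

    Requires columns ``snp_id, chrom, pos, effect_allele, other_allele,
    odds_ratio, p_value``, positive odds ratios, p-values in ``(0, 1]``,
    unique ids, and distinct allele pairs.
    """
    missing = [c for c in SUMSTATS_COLUMNS if c not in sumstats.columns]
    if missing:
        raise DataError(f"summary statistics missing columns: {missing}")
    if sumstats["snp_id"].duplicated().any():
        raise DataError("summary statistics ids are not unique")
    if (sumstats["odds_ratio"] <= 0).any():
        raise DataError("odds ratios must be positive")
    p = sumstats["p_value"]
    if ((p <= 0) | (p > 1)).any():
        raise DataError("p-values must lie in (0, 1]")
    if (sumstats["effect_allele"] == sumstats["other_allele"]).any():
        raise DataError("effect allele equals other allele for some SNPs")
    return sumstats


@dataclass
class PathwayCollection:
    """Named gene sets over a shared gene-coordinate table.

    ``gene_table`` holds one row per gene (``gene, chrom, start, end``;
    1-based inclusive intervals).  ``sets`` maps a pathway name to a tuple
    of gene names.  Set names listed in ``all_snp_sets`` (the genome-wide
    score) select every SNP rather than gene windows.
    """

    gene_table: pd.DataFrame
    sets: dict[str, tuple[str, ...]]
    window: int = 20_000
    all_snp_sets: frozenset[str] = field(default_factory=lambda: frozenset({"genome_wide"}))

    def validate(self) -> "PathwayCollection":
        for col in ("gene", "chrom", "start", "end"):
            if col not in self.gene_table.columns:
                raise DataError(f"gene table missing column {col!r}")
        if (self.gene_table["start"] >= self.gene_table["end"]).any():
            raise DataError("gene intervals must satisfy start < end")
        if self.gene_table["gene"].duplicated().any():
            raise DataError("gene names are not unique")
        known = set(self.gene_table["gene"])
        for name, genes in self.sets.items():
            unknown = set(genes) - known
            if unknown and name not in self.all_snp_sets:
                raise DataError(f"pathway {name!r} references unknown genes: {sorted(unknown)[:5]}")
        return self

    def genes_of(self, name: str) -> pd.DataFrame:
        """Coordinate records for the genes of one pathway."""
        if name not in self.sets:
            raise DataError(f"unknown pathway {name!r}")
        wanted = set(self.sets[name])
        return self.gene_table[self.gene_table["gene"].isin(wanted)].reset_index(drop=True)
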
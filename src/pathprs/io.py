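"""Readers and writers for the standard interchange formats.

Genotypes travel as VCF (DS dosage field, GT fallback on read) or as a
plain SNP-per-row dosage TSV; gene coordinates as BED (0-based
half-open, converted to the 1-based inclusive internal convention);
pathways as GMT; summary statistics and phenotypes as TSV.  Every output
table may carry ``# key=value`` metadata header lines, which the paired
readers skip; writer/reader pairs round-trip to equal in-memory objects.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, PathwayCollection, SUMSTATS_COLUMNS, validate_sumstats
from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


def _norm_chrom(value):
    try:
        return int(value)
    except (TypeError, ValueError):
        return str(value)


def _write_meta(fh, meta: dict | None) -> None:
    for key, value in (meta or {}).items():
        fh.write(f"# {key}={value}\n")


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a TSV with optional ``# key=value`` metadata header lines."""
    with open(path, "w") as fh:
        _write_meta(fh, meta)
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])


# ---------------------------------------------------------------- genotypes

def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path, meta: dict | None = None) -> None:
    """SNP-per-row dosage matrix: map columns then one column per sample."""
    df = genotypes.snp_map.copy()
    dos = pd.DataFrame(genotypes.dosages.T, columns=genotypes.sample_ids)
    write_table(pd.concat([df.reset_index(drop=True), dos], axis=1), path, meta)


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = read_table(path)
    map_cols = ["snp_id", "chrom", "pos", "ref", "alt", "maf"]
    missing = [c for c in map_cols if c not in df.columns]
    if missing:
        raise DataError(f"dosage TSV {path} missing columns {missing}")
    sample_ids = [c for c in df.columns if c not in map_cols]
    if not sample_ids:
        raise DataError(f"dosage TSV {path} has no sample columns")
    snp_map = df[map_cols].copy()
    snp_map["chrom"] = snp_map["chrom"].map(_norm_chrom)
    dosages = df[sample_ids].to_numpy(dtype=float).T
    return GenotypeMatrix(dosages=dosages, snp_map=snp_map, sample_ids=list(sample_ids)).validate()


def write_vcf(genotypes: GenotypeMatrix, path: str | Path, meta: dict | None = None) -> None:
    """Minimal VCF 4.2 with per-sample DS (alt-allele dosage) entries."""
    sm = genotypes.snp_map
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for key, value in (meta or {}).items():
            fh.write(f"##{key}={value}\n")
        for chrom in pd.unique(sm["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(genotypes.sample_ids) + "\n")
        for j in range(len(sm)):
            row = sm.iloc[j]
            ds = genotypes.dosages[:, j]
            vals = "\t".join("." if not np.isfinite(d) else _FLOAT_FMT % d for d in ds)
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t{row['ref']}\t{row['alt']}\t.\t.\t.\tDS\t{vals}\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read GT/DS genotypes with cyvcf2; multi-allelic records skipped."""
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on malformed input
        raise DataError(f"cannot open VCF {path}: {exc}") from None
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise DataError(f"VCF {path} has no sample columns")
    rows, dosage_cols = [], []
    n_multi = 0
    for i, variant in enumerate(vcf, start=1):
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        try:
            ds = variant.format("DS")
            if ds is not None:
                d = ds[:, 0].astype(float)
            else:
                g = np.array(variant.genotypes, dtype=object)
                a = np.array([[x[0], x[1]] for x in g], dtype=float)
                a[a < 0] = np.nan
                d = a.sum(axis=1)
        except Exception as exc:
            raise DataError(f"malformed record at {path} data line {i}: {exc}") from None
        rows.append((variant.ID or f"{variant.CHROM}:{variant.POS}", _norm_chrom(variant.CHROM), variant.POS, variant.REF, variant.ALT[0]))
        dosage_cols.append(d)
    if n_multi:
        logger.warning("skipped %d multi-allelic VCF records", n_multi)
    if not rows:
        raise DataError(f"VCF {path} holds no usable bi-allelic records")
    snp_map = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    dosages = np.column_stack(dosage_cols)
    p = np.nanmean(dosages, axis=0) / 2.0
    snp_map["maf"] = np.minimum(p, 1.0 - p)
    return GenotypeMatrix(dosages=dosages, snp_map=snp_map, sample_ids=sample_ids).validate()


def read_genotypes(path: str | Path, fmt: str | None = None) -> GenotypeMatrix:
    """Dispatch on format: ``vcf`` or ``dosage_tsv`` (inferred from suffix)."""
    if fmt is None:
        fmt = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "dosage_tsv"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "dosage_tsv":
        return read_dosage_tsv(path)
    raise ParameterError(f"unknown genotype format {fmt!r}")


# ------------------------------------------------------- summary statistics

_SUMSTAT_HEADER = {"SNP": "snp_id", "CHR": "chrom", "BP": "pos", "A1": "effect_allele", "A2": "other_allele", "OR": "odds_ratio", "P": "p_value"}


def write_sumstats(sumstats: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write the SNP/CHR/BP/A1/A2/OR/P summary-statistics TSV."""
    validate_sumstats(sumstats)
    out = sumstats[list(SUMSTATS_COLUMNS)].copy()
    out.columns = list(_SUMSTAT_HEADER)
    write_table(out, path, meta)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    missing = [c for c in _SUMSTAT_HEADER if c not in df.columns]
    if missing:
        raise DataError(f"summary statistics {path} missing columns {missing}")
    df = df.rename(columns=_SUMSTAT_HEADER)
    df["chrom"] = df["chrom"].map(_norm_chrom)
    return validate_sumstats(df)


# --------------------------------------------------------- genes & pathways

def write_bed(gene_table: pd.DataFrame, path: str | Path) -> None:
    """Genes as BED: 0-based half-open intervals, name in column 4."""
    with open(path, "w") as fh:
        for _, g in gene_table.iterrows():
            fh.write(f"{g['chrom']}\t{g['start'] - 1}\t{g['end']}\t{g['gene']}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read gene BED into the internal 1-based inclusive convention."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise DataError(f"{path} line {lineno}: BED needs chrom/start/end/name")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError:
                raise DataError(f"{path} line {lineno}: non-integer coordinates") from None
            if end0 <= start0:
                raise DataError(f"{path} line {lineno}: empty or inverted interval")
            rows.append((parts[3], _norm_chrom(parts[0]), start0 + 1, end0))
    if not rows:
        raise DataError(f"BED file {path} holds no intervals")
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def write_gmt(sets: dict[str, tuple[str, ...]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, tuple[str, ...]]:
    sets: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(f"{path} line {lineno}: GMT needs name, description, genes")
            sets[parts[0]] = tuple(g for g in parts[2:] if g)
    if not sets:
        raise DataError(f"GMT file {path} holds no gene sets")
    return sets


def read_gene_sets(
    gmt_path: str | Path,
    bed_path: str | Path,
    window: int = 20_000,
    all_snp_sets: tuple[str, ...] = ("genome_wide",),
    autosome_only_sets: tuple[str, ...] = ("mir137_targets",),
) -> PathwayCollection:
    """Resolve GMT set names against BED gene coordinates.

    Unresolved gene names are counted and logged; sets flagged
    autosome-only drop genes on non-numeric chromosomes or beyond 22.
    A set that resolves to nothing (and is not an all-SNP set) errors.
    """
    gene_table = read_bed(bed_path)
    known = set(gene_table["gene"])
    autosomal = {
        g["gene"]
        for _, g in gene_table.iterrows()
        if isinstance(g["chrom"], (int, np.integer)) and 1 <= g["chrom"] <= 22
    }
    raw_sets = read_gmt(gmt_path)
    sets: dict[str, tuple[str, ...]] = {}
    for name, genes in raw_sets.items():
        resolved = tuple(g for g in genes if g in known)
        n_unresolved = len(genes) - len(resolved)
        if n_unresolved:
            logger.warning("pathway %s: %d gene names unresolved against BED", name, n_unresolved)
        if name in autosome_only_sets:
            resolved = tuple(g for g in resolved if g in autosomal)
        if not resolved and name not in all_snp_sets:
            raise DataError(f"pathway {name!r} resolves to no genes")
        sets[name] = resolved
    return PathwayCollection(
        gene_table=gene_table, sets=sets, window=window, all_snp_sets=frozenset(all_snp_sets)
    ).validate()


# ---------------------------------------------------------------- phenotypes

def write_phenotypes(table: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    write_table(table, path, meta)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    for col in ("sample_id", "cohort", "diagnosis"):
        if col not in df.columns:
            raise DataError(f"phenotype table {path} missing column {col!r}")
    return df
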
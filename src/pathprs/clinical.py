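"""Clinical/cognitive correlations and group descriptive statistics.

Spearman partial correlations (adjusted for age and sex) relate the
harmonized imaging phenotypes to functioning, symptom, and IQ measures;
group contrasts reproducible from printed summary data use the Pearson
chi-squared test on counts and the two-group ANOVA F (the squared
pooled-variance t) on means/SDs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError, ParameterError
from .harmonize import prune_collinear


@dataclass
class ClinicalCorrelation:
    phenotype: str
    measure: str
    rho: float
    pvalue: float
    n: int


def spearman_partial(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> tuple[float, float, int]:
    """Spearman partial correlation of x and y given covariates.

    Both variables are rank-transformed (average ranks for ties), each
    rank vector is residualized on the covariates (plus intercept), and
    the Pearson correlation of the residuals is returned with a p-value
    from the t approximation on ``n - 2 - k`` degrees of freedom.
    Complete cases only; requires n >= 5; constant input is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        c = np.empty((len(x), 0))
    else:
        c = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(c).all(axis=1)
    x, y, c = x[ok], y[ok], c[ok]
    n = len(x)
    if n < 5:
        raise DataError(f"need >= 5 complete cases, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("constant variable; Spearman correlation undefined")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    design = prune_collinear(np.column_stack([np.ones(n), c]))
    k = design.shape[1] - 1
    hat = design @ np.linalg.lstsq(design, np.column_stack([rx, ry]), rcond=None)[0]
    ex, ey = rx - hat[:, 0], ry - hat[:, 1]
    denom = np.sqrt((ex @ ex) * (ey @ ey))
    if denom == 0:
        raise DataError("rank residuals are constant; correlation undefined")
    rho = float(np.clip((ex @ ey) / denom, -1.0, 1.0))
    dof = n - 2 - k
    if dof <= 0:
        raise DataError("not enough cases for the covariate set")
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(dof / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), dof))
    return rho, p, n


def clinical_correlation_table(
    harmonized: pd.DataFrame,
    phenotype_table: pd.DataFrame,
    measures: tuple[str, ...] = ("GAF", "PANSS_total", "IQ"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman partial correlations (age- and sex-adjusted) with BH-FDR flags.

    One FDR family over all phenotype x measure pairs.  Harmonized Z
    values are used for the imaging phenotypes.
    """
    z_wide = harmonized.pivot_table(index="sample_id", columns="phenotype", values="z")
    meta = phenotype_table.set_index("sample_id")
    z_wide = z_wide.reindex(meta.index)
    cov = meta[["age", "sex"]]

    rows = []
    for ph in z_wide.columns:
        for m in measures:
            if m not in meta.columns:
                continue
            try:
                rho, p, n = spearman_partial(z_wide[ph], meta[m], cov)
            except DataError:
                continue
            rows.append((ph, m, rho, p, n))
    out = pd.DataFrame(rows, columns=["phenotype", "measure", "rho", "p", "n"])
    if len(out):
        flags, p_adj = fdr_correct(out["p"].to_numpy(), alpha=alpha)
        out["p_fdr"] = p_adj
        out["significant"] = flags
    return out


def chi2_from_counts(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-squared test on a contingency table of counts.

    No continuity correction (df = 1 for 2x2).  All margins must be
    positive.  Returns ``(statistic, df, p)``.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise DataError("counts must form a 2-D table of non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DataError("all table margins must be positive")
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(dof), float(p)


def f_from_summary(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> tuple[float, tuple[int, int], float]:
    """Two-group one-way ANOVA F from summary statistics.

    Equals the square of the pooled-variance t statistic; df = (1,
    n1 + n2 - 2).  Returns ``(F, (df1, df2), p)``.
    """
    if n1 < 2 or n2 < 2:
        raise ParameterError("both groups need n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ParameterError("group SDs must be positive")
    df2 = n1 + n2 - 2
    pooled = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df2
    msb = (mean1 - mean2) ** 2 / (1.0 / n1 + 1.0 / n2)
    f = msb / pooled
    p = float(stats.f.sf(f, 1, df2))
    return float(f), (1, df2), p


def fdr_correct(pvalues: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over one family; returns (flags, adjusted p)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ParameterError("p-values must lie in [0, 1]")
    flags, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return flags, p_adj


def describe_groups(
    table: pd.DataFrame,
    continuous: tuple[str, ...] = ("age", "tbv", "GAF", "IQ"),
    categorical: tuple[str, ...] = ("sex",),
    group: str = "diagnosis",
    levels: tuple[str, str] = ("case", "control"),
) -> pd.DataFrame:
    """Two-group descriptive table with F (continuous) or chi2 (categorical).

    Mirrors a demographics table: per group N, mean +/- SD and range for
    continuous variables; level counts and a 2xL chi-squared for
    categorical ones.
    """
    a = table[table[group] == levels[0]]
    b = table[table[group] == levels[1]]
    rows = []
    for var in continuous:
        if var not in table.columns:
            continue
        va, vb = a[var].dropna(), b[var].dropna()
        if len(va) < 2 or len(vb) < 2 or va.std() == 0 or vb.std() == 0:
            rows.append((var, len(va), va.mean(), va.std(), len(vb), vb.mean(), vb.std(), np.nan, "", np.nan))
            continue
        f, (d1, d2), p = f_from_summary(len(va), va.mean(), va.std(ddof=1), len(vb), vb.mean(), vb.std(ddof=1))
        rows.append((var, len(va), va.mean(), va.std(ddof=1), len(vb), vb.mean(), vb.std(ddof=1), f, f"{d1},{d2}", p))
    out = pd.DataFrame(
        rows,
        columns=["variable", "n_case", "mean_case", "sd_case", "n_control", "mean_control", "sd_control", "statistic", "df", "p"],
    )
    cat_rows = []
    for var in categorical:
        if var not in table.columns:
            continue
        counts = pd.crosstab(table[group], table[var])
        counts = counts.reindex(list(levels)).dropna(how="any")
        try:
            chi2, dof, p = chi2_from_counts(counts.to_numpy())
        except DataError:
            continue
        cat_rows.append((f"{var} (chi2)", int(counts.iloc[0].sum()), np.nan, np.nan, int(counts.iloc[1].sum()), np.nan, np.nan, chi2, str(dof), p))
    if cat_rows:
        out = pd.concat([out, pd.DataFrame(cat_rows, columns=out.columns)], ignore_index=True)
    return out
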
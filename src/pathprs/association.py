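"""Per-cohort PRS association, inverse-variance meta-analysis, and
multiple-testing calibration.

The estimand per (cohort, phenotype, pathway, threshold) cell is the OLS
coefficient of the harmonized phenotype Z on the within-cohort
standardized PRS, adjusting for age, sex, age^2, age x sex, age^2 x sex,
total brain volume, scanner dummies, and four ancestry components.
Cohort estimates are pooled with fixed-effects inverse-variance weights;
variance explained is the incremental R^2 of the PRS over the
covariate-only model, averaged (unweighted) across cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DataError, ParameterError
from .harmonize import prune_collinear

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = ("age", "sex", "tbv", "anc1", "anc2", "anc3", "anc4")


def build_covariates(table: pd.DataFrame) -> pd.DataFrame:
    """Expand the covariate set: age terms, sex, TBV, scanner dummies, ancestry.

    Age is centered before forming age^2 and the sex interactions to
    keep the design well conditioned.  Scanner dummies are emitted only
    for multi-scanner tables (first level dropped).
    """
    missing = [c for c in COVARIATE_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"covariate columns missing: {missing}")
    age = table["age"].to_numpy(dtype=float)
    age_c = age - np.nanmean(age)
    sex = table["sex"].to_numpy(dtype=float)
    cov = pd.DataFrame(
        {
            "age": age_c,
            "age2": age_c**2,
            "age_sex": age_c * sex,
            "age2_sex": age_c**2 * sex,
            "sex": sex,
            "tbv": table["tbv"].to_numpy(dtype=float),
        },
        index=table.index,
    )
    for k in ("anc1", "anc2", "anc3", "anc4"):
        cov[k] = table[k].to_numpy(dtype=float)
    if "scanner" in table.columns and table["scanner"].nunique() > 1:
        dummies = pd.get_dummies(table["scanner"], prefix="scanner", drop_first=True, dtype=float)
        cov = pd.concat([cov, dummies], axis=1)
    return cov


@dataclass
class PRSAssociationResults:
    """Fitted per-cohort association of one phenotype with one score."""

    beta: float
    se: float
    pvalue: float
    r2_inc: float
    r2_full: float
    r2_cov: float
    n: int
    df_resid: int

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        t = stats.t.ppf(1.0 - alpha / 2.0, self.df_resid)
        return self.beta - t * self.se, self.beta + t * self.se

    def summary(self) -> str:
        lo, hi = self.conf_int()
        return (
            "PRS association (OLS)\n"
            f"  n = {self.n}\n"
            f"  beta = {self.beta:.4f}  SE = {self.se:.4f}  p = {self.pvalue:.3g}\n"
            f"  95% CI = [{lo:.4f}, {hi:.4f}]\n"
            f"  incremental R2 = {self.r2_inc:.4f} (full {self.r2_full:.4f}, covariates {self.r2_cov:.4f})"
        )


class PRSAssociation:
    """OLS model of a harmonized phenotype on a standardized PRS + covariates.

    Parameters
    ----------
    phenotype
        Harmonized Z values (NaN allowed; listwise deletion applies).
    prs
        Raw score vector; standardized to mean 0, SD 1 on the analysis
        sample before fitting unless ``standardize_prs=False``.
    covariates
        Covariate design (no intercept; one is added).  Collinear
        columns are dropped with a warning.
    """

    def __init__(
        self,
        phenotype: np.ndarray | pd.Series,
        prs: np.ndarray | pd.Series,
        covariates: pd.DataFrame | np.ndarray | None = None,
        standardize_prs: bool = True,
        min_n: int | None = None,
    ):
        self.y = np.asarray(phenotype, dtype=float)
        self.prs = np.asarray(prs, dtype=float)
        if covariates is None:
            self.x_cov = np.empty((len(self.y), 0))
        elif isinstance(covariates, pd.DataFrame):
            self.x_cov = covariates.to_numpy(dtype=float)
        else:
            self.x_cov = np.asarray(covariates, dtype=float)
            if self.x_cov.ndim == 1:
                self.x_cov = self.x_cov[:, None]
        if not len(self.y) == len(self.prs) == len(self.x_cov):
            raise DataError("phenotype, PRS, and covariates must have equal length")
        self.standardize_prs = standardize_prs
        self.min_n = min_n

    def fit(self) -> PRSAssociationResults:
        ok = np.isfinite(self.y) & np.isfinite(self.prs) & np.isfinite(self.x_cov).all(axis=1)
        y, s, xc = self.y[ok], self.prs[ok], self.x_cov[ok]
        n = int(ok.sum())
        n_params = 2 + xc.shape[1]
        min_n = self.min_n if self.min_n is not None else n_params + 1
        if n < max(min_n, n_params + 1):
            raise DataError(f"only {n} complete cases for {n_params} parameters")
        if self.standardize_prs:
            sd = s.std(ddof=1)
            if not sd > 0:
                raise DataError("PRS is constant; cannot standardize")
            s = (s - s.mean()) / sd

        x_cov = prune_collinear(np.column_stack([np.ones(n), xc]))
        x_full = np.column_stack([x_cov[:, :1], s, x_cov[:, 1:]])
        full = sm.OLS(y, x_full).fit()
        cov_only = sm.OLS(y, x_cov).fit()
        return PRSAssociationResults(
            beta=float(full.params[1]),
            se=float(full.bse[1]),
            pvalue=float(full.pvalues[1]),
            r2_inc=max(0.0, float(full.rsquared - cov_only.rsquared)),
            r2_full=float(full.rsquared),
            r2_cov=float(cov_only.rsquared),
            n=n,
            df_resid=int(full.df_resid),
        )


def fit_cohort_associations(
    harmonized: pd.DataFrame,
    prs_profile: pd.DataFrame,
    phenotype_table: pd.DataFrame,
    min_n: int = 30,
) -> pd.DataFrame:
    """Fit every (cohort, phenotype, pathway, threshold) cell.

    ``harmonized`` is the long output of :func:`~pathprs.harmonize.harmonize_cohorts`,
    ``prs_profile`` the long score table, and ``phenotype_table`` the
    wide per-sample table carrying the covariates.  Cohorts with fewer
    than ``min_n`` complete cases in a cell are skipped.  Returns a tidy
    results table.
    """
    cov_by_cohort = {}
    for cohort, grp in phenotype_table.groupby("cohort", sort=True):
        cov_by_cohort[cohort] = (grp["sample_id"].to_numpy(), build_covariates(grp))

    z_wide = harmonized.pivot_table(index="sample_id", columns="phenotype", values="z")
    score_wide = prs_profile.pivot_table(
        index="sample_id", columns=["pathway", "threshold"], values="score"
    )

    rows = []
    for cohort, (sids, cov) in cov_by_cohort.items():
        z_c = z_wide.reindex(sids)
        s_c = score_wide.reindex(sids)
        for ph in z_c.columns:
            for (pathway, thr) in s_c.columns:
                try:
                    res = PRSAssociation(
                        z_c[ph].to_numpy(), s_c[(pathway, thr)].to_numpy(), cov, min_n=min_n
                    ).fit()
                except DataError as exc:
                    logger.warning(
                        "cohort %s, %s ~ %s@%g skipped: %s", cohort, ph, pathway, thr, exc
                    )
                    continue
                rows.append(
                    (cohort, ph, pathway, thr, res.beta, res.se, res.pvalue, res.r2_inc, res.n)
                )
    return pd.DataFrame(
        rows,
        columns=["cohort", "phenotype", "pathway", "threshold", "beta", "se", "p", "r2_inc", "n"],
    )


@dataclass
class MetaResults:
    """Pooled fixed-effects (or DerSimonian-Laird) meta-analysis."""

    beta: float
    se: float
    pvalue: float
    q: float
    i2: float
    n_cohorts: int
    method: str = "fixed"
    tau2: float = 0.0

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
        return self.beta - zcrit * self.se, self.beta + zcrit * self.se

    def summary(self) -> str:
        lo, hi = self.conf_int()
        return (
            f"Inverse-variance meta-analysis ({self.method} effects, k={self.n_cohorts})\n"
            f"  pooled beta = {self.beta:.4f}  SE = {self.se:.4f}  p = {self.pvalue:.3g}\n"
            f"  95% CI = [{lo:.4f}, {hi:.4f}]\n"
            f"  Q = {self.q:.3f}  I2 = {100 * self.i2:.1f}%"
        )


class InverseVarianceMeta:
    """Pool per-cohort estimates with inverse-variance weights.

    Fixed-effects by default: ``w_k = 1/SE_k^2``, pooled beta the
    weighted mean, pooled SE ``(sum w)^(-1/2)``, p from the normal
    approximation.  ``method="random"`` uses DerSimonian-Laird weights.
    Cohorts with non-positive SE are excluded with a warning.
    """

    def __init__(self, betas, ses, method: str = "fixed"):
        if method not in ("fixed", "random"):
            raise ParameterError(f"unknown meta-analysis method {method!r}")
        betas = np.asarray(betas, dtype=float)
        ses = np.asarray(ses, dtype=float)
        if betas.shape != ses.shape or betas.ndim != 1:
            raise DataError("betas and ses must be 1-D arrays of equal length")
        ok = np.isfinite(betas) & np.isfinite(ses) & (ses > 0)
        if (~ok).any():
            logger.warning("excluding %d cohorts with invalid SE from meta-analysis", int((~ok).sum()))
        if not ok.any():
            raise DataError("no cohort with positive SE to pool")
        self.betas, self.ses, self.method = betas[ok], ses[ok], method

    def fit(self) -> MetaResults:
        w = 1.0 / self.ses**2
        beta_fe = float(np.sum(w * self.betas) / np.sum(w))
        k = len(self.betas)
        q = float(np.sum(w * (self.betas - beta_fe) ** 2))
        i2 = max(0.0, (q - (k - 1)) / q) if q > 0 and k > 1 else 0.0
        tau2 = 0.0
        if self.method == "random" and k > 1:
            c = np.sum(w) - np.sum(w**2) / np.sum(w)
            tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
            w = 1.0 / (self.ses**2 + tau2)
        beta = float(np.sum(w * self.betas) / np.sum(w))
        se = float(np.sum(w) ** -0.5)
        p = float(2.0 * stats.norm.sf(abs(beta) / se))
        return MetaResults(beta=beta, se=se, pvalue=p, q=q, i2=i2, n_cohorts=k, method=self.method, tau2=tau2)


def meta_analyze(cohort_results: pd.DataFrame, method: str = "fixed") -> pd.DataFrame:
    """Pool the tidy per-cohort table over cohorts, cell by cell.

    Adds the unweighted mean incremental R^2 across contributing cohorts
    ("average R^2"), heterogeneity Q and I^2, and the cohort count.
    Cell order and results are invariant to input row order.
    """
    rows = []
    keys = ["phenotype", "pathway", "threshold"]
    for (ph, pathway, thr), grp in cohort_results.groupby(keys, sort=True):
        try:
            res = InverseVarianceMeta(grp["beta"].to_numpy(), grp["se"].to_numpy(), method=method).fit()
        except DataError as exc:
            logger.warning("meta cell %s/%s@%g skipped: %s", ph, pathway, thr, exc)
            continue
        rows.append(
            (
                ph, pathway, thr, res.beta, res.se, res.pvalue,
                float(grp["r2_inc"].mean()), res.q, res.i2, res.n_cohorts, int(grp["n"].sum()),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "phenotype", "pathway", "threshold", "beta", "se", "p",
            "avg_r2", "q", "i2", "n_cohorts", "n_total",
        ],
    )


def effective_tests(correlation_matrix: np.ndarray | pd.DataFrame) -> float:
    """Effective number of independent tests from a correlation matrix.

    Eigenvalue-based count: ``M_eff = sum_i [ 1(lambda_i >= 1) +
    (lambda_i - floor(lambda_i)) ]`` over the eigenvalues of the
    correlation matrix, which equals M for independent tests and 1 for
    perfectly correlated ones.  Tiny negative eigenvalues from numerical
    noise are clipped to zero.
    """
    r = correlation_matrix.to_numpy() if isinstance(correlation_matrix, pd.DataFrame) else np.asarray(correlation_matrix, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise DataError("correlation matrix must be square")
    if not np.allclose(r, r.T, atol=1e-8):
        raise DataError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(r), 1.0, atol=1e-6):
        raise DataError("correlation matrix must have unit diagonal")
    lam = np.linalg.eigvalsh(r)
    if lam.min() < -1e-6:
        raise DataError("correlation matrix is not positive semidefinite")
    # round before flooring so an eigenvalue of k - eps counts as the integer k
    lam = np.round(np.clip(lam, 0.0, None), 10)
    m_eff = float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))
    return float(np.clip(m_eff, 1.0, len(lam)))


def correct_pvalues(
    meta_results: pd.DataFrame,
    alpha: float = 0.05,
    mode: str = "declared",
    declared_counts: tuple[int, int] = (7, 7),
    m_eff_phenotypes: float | None = None,
    m_eff_prs: float | None = None,
) -> pd.DataFrame:
    """Significance flags across the phenotype x score family.

    The six thresholds of one pathway count as a single test: a
    (phenotype, pathway) cell is significant when its smallest pooled p
    beats the family-wise threshold.  ``mode="declared"`` uses the fixed
    product of declared counts (default 7 scores x 7 phenotypes);
    ``mode="effective"`` uses the product of eigenvalue-based effective
    counts supplied by the caller.
    """
    if not 0.0 < alpha < 1.0:
        raise ParameterError("alpha must lie in (0, 1)")
    if mode == "declared":
        n_tests = declared_counts[0] * declared_counts[1]
    elif mode == "effective":
        if m_eff_phenotypes is None or m_eff_prs is None:
            raise ParameterError("effective mode needs m_eff_phenotypes and m_eff_prs")
        n_tests = m_eff_phenotypes * m_eff_prs
    else:
        raise ParameterError(f"unknown correction mode {mode!r}")
    threshold = alpha / n_tests

    rows = []
    for (ph, pathway), grp in meta_results.groupby(["phenotype", "pathway"], sort=True):
        i = grp["p"].idxmin()
        rows.append((ph, pathway, float(grp.loc[i, "p"]), float(grp.loc[i, "threshold"])))
    best = pd.DataFrame(rows, columns=["phenotype", "pathway", "min_p", "best_threshold"])
    best["alpha_corrected"] = threshold
    best["significant"] = best["min_p"] < threshold
    return best


def adjusted_diagnosis_contrast(
    harmonized: pd.DataFrame, phenotype_table: pd.DataFrame, phenotype: str
) -> float:
    """Covariate-adjusted case-control difference of harmonized Z means.

    Fits ``Z ~ diagnosis + covariates`` within each cohort and returns
    the unweighted mean of the diagnosis coefficients (in control-SD
    units), the descriptive statistic behind covariate-adjusted
    standardized group means.
    """
    sub = harmonized[harmonized["phenotype"] == phenotype]
    coefs = []
    for cohort, grp in phenotype_table.groupby("cohort", sort=True):
        z = sub.set_index("sample_id")["z"].reindex(grp["sample_id"]).to_numpy()
        case = (grp["diagnosis"] == "case").to_numpy(dtype=float)
        cov = build_covariates(grp).to_numpy(dtype=float)
        x = np.column_stack([np.ones(len(grp)), case, cov])
        ok = np.isfinite(z) & np.isfinite(x).all(axis=1)
        x_ok = prune_collinear(x[ok])
        fit = sm.OLS(z[ok], x_ok).fit()
        coefs.append(float(fit.params[1]))
    return float(np.mean(coefs))


def correlation_matrix(wide: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations of a wide value table."""
    return wide.corr(method="pearson")
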
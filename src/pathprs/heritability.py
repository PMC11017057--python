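"""SNP-based heritability from a genetic relationship matrix.

The variance-component model is ``y = g + e`` with
``cov(g) = h2 * K`` and ``cov(e) = (1 - h2) * I`` on the standardized,
covariate-projected phenotype, where ``K`` is the GRM built from
column-standardized dosages.  The default point estimator is
Haseman-Elston regression of phenotypic cross-products ``y_i y_j`` on
``K_ij`` over pairs ``i < j`` — a moment estimator whose slope equals h2
under the model — with an OLS sampling SE, clipping to [0, 1], a
permutation p-value, and an exact-likelihood grid search available as a
cross-check estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeMatrix
from .errors import DataError, ParameterError
from .harmonize import prune_collinear

logger = logging.getLogger(__name__)


@dataclass
class GRM:
    """Genetic relationship matrix ``K = X X' / M`` on standardized dosages."""

    matrix: np.ndarray
    n_snps: int
    sample_ids: list[str]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def compute_grm(genotypes: GenotypeMatrix, maf_min: float = 0.01) -> GRM:
    """Build the GRM from SNPs with sample MAF at or above ``maf_min``.

    Dosages are centered by twice the sample allele frequency and scaled
    by ``sqrt(2 p (1-p))``, so rows of K sum to ~0 and the diagonal mean
    is ~1.  Monomorphic SNPs are excluded; all-monomorphic input errors.
    """
    if genotypes.n_samples < 2:
        raise DataError("need at least two individuals for a GRM")
    x = genotypes.dosages
    p = np.nanmean(x, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= maf_min
    if not keep.any():
        raise DataError("no polymorphic SNP passes the MAF floor; cannot build GRM")
    p = p[keep]
    xk = np.nan_to_num(x[:, keep], nan=0.0)
    xs = (xk - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    m = int(keep.sum())
    k = (xs @ xs.T) / m
    return GRM(matrix=k, n_snps=m, sample_ids=list(genotypes.sample_ids))


def project_covariates(
    phenotype: np.ndarray | pd.Series, covariates: pd.DataFrame | np.ndarray | None
) -> tuple[np.ndarray, int]:
    """Residualize and standardize the phenotype against covariates.

    Projects onto the orthogonal complement of the covariate span
    (intercept always included; collinear columns pruned), then scales
    residuals to unit variance.  Returns ``(residuals, projection_rank)``.
    Refuses estimation when the phenotype is (numerically) inside the
    covariate span.
    """
    y = np.asarray(phenotype, dtype=float)
    if covariates is None:
        x = np.ones((len(y), 1))
    else:
        xc = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, dtype=float)
        if xc.ndim == 1:
            xc = xc[:, None]
        x = np.column_stack([np.ones(len(y)), xc])
    if not np.isfinite(y).all() or not np.isfinite(x).all():
        raise DataError("missing values: restrict to complete cases before projection")
    x = prune_collinear(x)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    scale = resid.std(ddof=1)
    if not scale > 1e-10 * max(1.0, np.abs(y).max()):
        raise DataError("phenotype lies in the covariate span; nothing to estimate")
    return resid / scale, x.shape[1]


@dataclass
class HeritabilityResults:
    """Point estimate with sampling SE, CI, and permutation significance."""

    h2: float
    h2_unclipped: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    n_snps: int
    p_perm: float | None = None
    n_perm: int = 0

    def summary(self) -> str:
        lines = [
            "SNP-based heritability (Haseman-Elston regression)",
            f"  n = {self.n}  SNPs = {self.n_snps}",
            f"  h2 = {self.h2:.3f} (unclipped {self.h2_unclipped:.3f})  SE = {self.se:.3f}",
            f"  95% CI = [{self.ci_low:.3f}, {self.ci_high:.3f}]",
        ]
        if self.p_perm is not None:
            lines.append(f"  permutation p = {self.p_perm:.4g} ({self.n_perm} permutations)")
        return "\n".join(lines)


class HasemanElston:
    """Moment estimator of SNP heritability from a GRM.

    Regresses ``y_i y_j`` on ``K_ij`` (with intercept) over the
    ``n(n-1)/2`` unordered pairs of a standardized phenotype.  Because
    pairs sharing an individual are not independent, the sampling SE is
    a delete-one-individual jackknife over the slope, which keeps the
    normal-theory CI calibrated; a degenerate GRM (near-constant
    off-diagonals) yields a wide-CI result with a warning.
    """

    def __init__(self, phenotype: np.ndarray, grm: GRM):
        y = np.asarray(phenotype, dtype=float)
        if len(y) != grm.n:
            raise DataError("phenotype and GRM must cover the same samples")
        if not np.isfinite(y).all():
            raise DataError("phenotype has missing values; restrict to complete cases")
        sd = y.std(ddof=1)
        if not sd > 0:
            raise DataError("phenotype is constant")
        self.y = (y - y.mean()) / sd
        self.grm = grm
        iu = np.triu_indices(grm.n, k=1)
        self._k_pairs = grm.matrix[iu]
        self._iu = iu

    def fit(self) -> HeritabilityResults:
        yy = np.outer(self.y, self.y)[self._iu]
        k = self._k_pairs
        kc = k - k.mean()
        denom = float(kc @ kc)
        if denom < 1e-12 * len(k):
            logger.warning("GRM off-diagonals nearly constant; heritability is weakly identified")
        if denom <= 0:
            raise DataError("GRM off-diagonals are constant; h2 not identifiable")
        slope = float(kc @ yy) / denom
        se = self._jackknife_se()
        ci = (slope - 1.96 * se, slope + 1.96 * se)
        return HeritabilityResults(
            h2=float(np.clip(slope, 0.0, 1.0)),
            h2_unclipped=slope,
            se=se,
            ci_low=ci[0],
            ci_high=ci[1],
            n=self.grm.n,
            n_snps=self.grm.n_snps,
        )

    def _jackknife_se(self) -> float:
        """Delete-one-individual jackknife SE of the HE slope.

        Removing individual i drops the n-1 pairs that contain it; all
        delete-one pair sums follow from per-individual row sums, so the
        whole jackknife costs O(n^2).
        """
        y = self.y
        k = self.grm.matrix
        n = self.grm.n
        diag = np.diag(k)
        y2 = y**2

        row_k = k.sum(axis=1) - diag
        row_k2 = (k**2).sum(axis=1) - diag**2
        ky = k @ y
        row_kyy = y * ky - diag * y2
        sy = y.sum()
        row_yy = y * sy - y2

        s_k = row_k.sum() / 2.0
        s_k2 = row_k2.sum() / 2.0
        s_kyy = row_kyy.sum() / 2.0
        s_yy = row_yy.sum() / 2.0
        npairs = n * (n - 1) // 2

        np_i = npairs - (n - 1)
        sk_i = s_k - row_k
        sk2_i = s_k2 - row_k2
        skyy_i = s_kyy - row_kyy
        syy_i = s_yy - row_yy
        denom_i = sk2_i - sk_i**2 / np_i
        with np.errstate(divide="ignore", invalid="ignore"):
            slopes = (skyy_i - sk_i * syy_i / np_i) / denom_i
        slopes = slopes[np.isfinite(slopes)]
        if len(slopes) < 3:
            return float("inf")
        m = len(slopes)
        return float(np.sqrt((m - 1) / m * ((slopes - slopes.mean()) ** 2).sum()))

    def permutation_pvalue(self, n_perm: int = 199, seed: int | np.random.Generator = 0) -> float:
        """One-sided permutation p for h2 > 0.

        Permutes the phenotype across individuals, which preserves its
        distribution while breaking the genotype link, and re-estimates
        the HE slope; ``p = (1 + #{perm >= observed}) / (1 + n_perm)``.
        """
        if n_perm < 100:
            raise ParameterError("n_perm must be >= 100")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        obs = self._slope(self.y)
        count = 0
        for _ in range(n_perm):
            if self._slope(rng.permutation(self.y)) >= obs:
                count += 1
        return (1.0 + count) / (1.0 + n_perm)

    def _slope(self, y: np.ndarray) -> float:
        # sum over i<j of K_ij y_i y_j via the quadratic form; O(n^2).
        k = self.grm.matrix
        s_kyy = 0.5 * (y @ k @ y - float(np.diag(k) @ (y**2)))
        sy = y.sum()
        s_yy = 0.5 * (sy**2 - float(y @ y))
        npairs = len(self._k_pairs)
        kc = self._k_pairs - self._k_pairs.mean()
        denom = float(kc @ kc)
        num = s_kyy - self._k_pairs.sum() * (s_yy / npairs)
        return num / denom


def fit_h2_ml_grid(phenotype: np.ndarray, grm: GRM, grid: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Exact-likelihood grid search for h2 (cross-check estimator).

    Maximizes the Gaussian log-likelihood of the standardized phenotype
    under ``sigma2 * (h2 K + (1-h2) I)`` over a grid of h2 values
    (default 0, 0.01, ..., 1), profiling sigma2 analytically via the
    eigendecomposition of K.  Returns ``(h2_hat, loglik_grid)``.
    """
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    y = np.asarray(phenotype, dtype=float)
    y = (y - y.mean()) / y.std(ddof=1)
    lam, u = np.linalg.eigh(grm.matrix)
    yt = u.T @ y
    n = len(y)
    ll = np.empty(len(grid))
    for i, h2 in enumerate(grid):
        v = h2 * lam + (1.0 - h2)
        v = np.maximum(v, 1e-10)
        sigma2 = float(np.mean(yt**2 / v))
        ll[i] = -0.5 * (np.sum(np.log(v)) + n * np.log(sigma2) + n)
    return float(grid[int(np.argmax(ll))]), ll


def estimate_h2(
    genotypes_or_grm: GenotypeMatrix | GRM,
    phenotype: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
    n_perm: int | None = 199,
    seed: int = 0,
    maf_min: float = 0.01,
) -> HeritabilityResults:
    """Covariate-projected Haseman-Elston heritability with permutation p."""
    grm = genotypes_or_grm if isinstance(genotypes_or_grm, GRM) else compute_grm(genotypes_or_grm, maf_min=maf_min)
    resid, _ = project_covariates(phenotype, covariates)
    model = HasemanElston(resid, grm)
    res = model.fit()
    if n_perm:
        res.p_perm = model.permutation_pvalue(n_perm=n_perm, seed=seed)
        res.n_perm = n_perm
    return res


def estimate_h2_table(
    grm: GRM,
    harmonized: pd.DataFrame,
    phenotype_table: pd.DataFrame,
    n_perm: int = 199,
    seed: int = 0,
) -> pd.DataFrame:
    """Heritability of every harmonized phenotype through one shared path.

    Volumes and ratios are treated identically.  Complete cases are
    taken per phenotype against the covariate set; the GRM is subset
    accordingly.
    """
    from .association import build_covariates

    cov_all = build_covariates(phenotype_table)
    sid_index = pd.Index(grm.sample_ids)
    rows = []
    for i, (ph, grp) in enumerate(harmonized.groupby("phenotype", sort=True)):
        z = grp.set_index("sample_id")["z"].reindex(sid_index)
        cov = cov_all.set_axis(phenotype_table["sample_id"]).reindex(sid_index)
        ok = np.isfinite(z.to_numpy()) & np.isfinite(cov.to_numpy(dtype=float)).all(axis=1)
        if ok.sum() < 50:
            logger.warning("phenotype %s: only %d complete cases, skipped", ph, int(ok.sum()))
            continue
        sub = GRM(grm.matrix[np.ix_(ok, ok)], grm.n_snps, list(sid_index[ok]))
        try:
            res = estimate_h2(sub, z.to_numpy()[ok], cov.to_numpy(dtype=float)[ok], n_perm=n_perm, seed=seed + i)
        except DataError as exc:
            logger.warning("phenotype %s skipped: %s", ph, exc)
            continue
        rows.append((ph, res.h2, res.h2_unclipped, res.se, res.ci_low, res.ci_high, res.p_perm, res.n, res.n_snps))
    return pd.DataFrame(
        rows,
        columns=["phenotype", "h2", "h2_unclipped", "se", "ci_low", "ci_high", "p_perm", "n", "n_snps"],
    )
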
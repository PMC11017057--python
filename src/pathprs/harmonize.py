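"""Cross-cohort phenotype harmonization.

Raw volumes (and their ratios, computed on the raw scale) are converted
to control-referenced Z-scores within each cohort,
``Z_i = (x_i - M_HC) / SD_HC``, where the mean and sample SD come from
that cohort's controls only.  Extreme values are then handled in one
pass: |Z| >= 6 removed, remaining |Z| >= 4 winsorized to +/-4.  Raw
volumes are never pooled across cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ANALYSIS_PHENOTYPES, CC_PHENOTYPES, RATIO_PHENOTYPES
from .errors import DataError

logger = logging.getLogger(__name__)

KEPT, WINSORIZED, REMOVED = "kept", "winsorized", "removed"


def compute_ratios(table: pd.DataFrame) -> pd.DataFrame:
    """Add the six CC:LV ratio columns, computed on raw volumes.

    Individuals with missing or non-positive LV are flagged via NaN
    ratios and excluded from ratio phenotypes downstream.
    """
    out = table.copy()
    lv = out["LV"].to_numpy(dtype=float)
    bad = ~(lv > 0)
    if bad.any():
        logger.warning("%d records with non-positive/missing LV excluded from ratios", int(bad.sum()))
    denom = np.where(bad, np.nan, lv)
    for cc in CC_PHENOTYPES:
        if cc in out.columns:
            out[f"{cc}_to_LV"] = out[cc].to_numpy(dtype=float) / denom
    return out


@dataclass
class HarmonizedVector:
    """Control-referenced Z-scores for one cohort-phenotype cell."""

    z: np.ndarray           # processed Z (NaN where removed or missing)
    z_raw: np.ndarray       # pre-filter Z
    status: np.ndarray      # kept / winsorized / removed ('' where missing)
    m_hc: float
    sd_hc: float


def zscore_within_cohort(values: np.ndarray, control_mask: np.ndarray) -> HarmonizedVector:
    """Z-score one phenotype against the cohort's controls.

    Uses the control mean and sample SD (n-1 denominator).  Requires at
    least two controls with data and a positive control SD.
    """
    values = np.asarray(values, dtype=float)
    control_mask = np.asarray(control_mask, dtype=bool)
    ctrl = values[control_mask & np.isfinite(values)]
    if len(ctrl) < 2:
        raise DataError("need >= 2 controls with non-missing values to standardize")
    m_hc = float(ctrl.mean())
    sd_hc = float(ctrl.std(ddof=1))
    if not sd_hc > 0:
        raise DataError("control SD is zero; cannot standardize")
    z = (values - m_hc) / sd_hc
    status = np.where(np.isfinite(z), KEPT, "")
    return HarmonizedVector(z=z.copy(), z_raw=z, status=status.astype(object), m_hc=m_hc, sd_hc=sd_hc)


def filter_and_winsorize(
    harmonized: HarmonizedVector, remove_sd: float = 6.0, winsorize_sd: float = 4.0
) -> HarmonizedVector:
    """Single-pass outlier handling on the Z scale (idempotent).

    |Z| >= ``remove_sd`` removed (Z set to NaN); remaining
    |Z| >= ``winsorize_sd`` set to the signed bound and flagged.
    Thresholds are inclusive.
    """
    z = harmonized.z.copy()
    status = harmonized.status.copy()
    finite = np.isfinite(z)
    remove = finite & (np.abs(z) >= remove_sd)
    z[remove] = np.nan
    status[remove] = REMOVED
    wins = np.isfinite(z) & (np.abs(z) >= winsorize_sd) & (status != WINSORIZED)
    z[wins] = np.sign(z[wins]) * winsorize_sd
    status[wins] = WINSORIZED
    return HarmonizedVector(z=z, z_raw=harmonized.z_raw, status=status, m_hc=harmonized.m_hc, sd_hc=harmonized.sd_hc)


def harmonize_cohorts(
    table: pd.DataFrame,
    phenotypes: tuple[str, ...] | None = None,
    remove_sd: float = 6.0,
    winsorize_sd: float = 4.0,
    control_label: str = "control",
) -> pd.DataFrame:
    """Harmonize every cohort-phenotype cell of a phenotype table.

    Ratios are added first if absent.  Returns a long table with columns
    ``sample_id, cohort, phenotype, z_raw, z, status, m_hc, sd_hc``;
    cells with too few controls or zero control SD are skipped with a
    logged warning.
    """
    if "cohort" not in table.columns or "diagnosis" not in table.columns:
        raise DataError("phenotype table needs 'cohort' and 'diagnosis' columns")
    if any(r not in table.columns for r in RATIO_PHENOTYPES):
        table = compute_ratios(table)
    if phenotypes is None:
        phenotypes = tuple(p for p in ANALYSIS_PHENOTYPES if p in table.columns)

    frames = []
    for cohort, grp in table.groupby("cohort", sort=True):
        ctrl_mask = (grp["diagnosis"] == control_label).to_numpy()
        for ph in phenotypes:
            try:
                hv = zscore_within_cohort(grp[ph].to_numpy(dtype=float), ctrl_mask)
            except DataError as exc:
                logger.warning("cohort %s phenotype %s skipped: %s", cohort, ph, exc)
                continue
            hv = filter_and_winsorize(hv, remove_sd=remove_sd, winsorize_sd=winsorize_sd)
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": grp["sample_id"].to_numpy(),
                        "cohort": cohort,
                        "phenotype": ph,
                        "z_raw": hv.z_raw,
                        "z": hv.z,
                        "status": hv.status,
                        "m_hc": hv.m_hc,
                        "sd_hc": hv.sd_hc,
                    }
                )
            )
    if not frames:
        raise DataError("no cohort-phenotype cell could be harmonized")
    return pd.concat(frames, ignore_index=True)


def residualize(z: np.ndarray, covariates: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Least-squares residuals of Z on a covariate design (plus intercept).

    Used for descriptive covariate-adjusted means and plots only; the
    association models include covariates directly.  Collinear columns
    are dropped with a warning.  Rows with missing values propagate NaN.
    """
    z = np.asarray(z, dtype=float)
    x = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    x = np.column_stack([np.ones(len(z)), x])
    ok = np.isfinite(z) & np.isfinite(x).all(axis=1)
    x_ok = prune_collinear(x[ok])
    beta, *_ = np.linalg.lstsq(x_ok, z[ok], rcond=None)
    resid = np.full_like(z, np.nan)
    resid[ok] = z[ok] - x_ok @ beta
    return resid


def prune_collinear(x: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Drop columns that add no rank, scanning left to right."""
    keep: list[int] = []
    for j in range(x.shape[1]):
        cand = x[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=tol * max(x.shape)) > len(keep):
            keep.append(j)
    if len(keep) < x.shape[1]:
        logger.warning("dropped %d collinear design columns", x.shape[1] - len(keep))
    return x[:, keep]
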
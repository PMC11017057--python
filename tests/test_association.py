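"""Per-cohort OLS, inverse-variance pooling, effective tests, correction."""

import numpy as np
import pandas as pd
import pytest

from pathprs.association import (
    InverseVarianceMeta,
    PRSAssociation,
    build_covariates,
    correct_pvalues,
    effective_tests,
    fit_cohort_associations,
    meta_analyze,
)
from pathprs.errors import DataError, ParameterError


class TestPRSAssociation:
    def test_matches_normal_equations_bruteforce(self):
        rng = np.random.default_rng(0)
        n, p = 200, 12
        cov = rng.standard_normal((n, p - 2))
        prs = rng.standard_normal(n)
        y = 0.4 * prs + cov @ rng.normal(0, 0.2, p - 2) + rng.standard_normal(n)
        res = PRSAssociation(y, prs, cov, standardize_prs=False).fit()
        x = np.column_stack([np.ones(n), prs, cov])
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        resid = y - x @ beta
        sigma2 = resid @ resid / (n - x.shape[1])
        se = np.sqrt(sigma2 * np.linalg.inv(x.T @ x)[1, 1])
        assert res.beta == pytest.approx(beta[1], abs=1e-10)
        assert res.se == pytest.approx(se, abs=1e-10)

    def test_known_effect_and_incremental_r2(self):
        rng = np.random.default_rng(1)
        n = 5000
        prs = rng.standard_normal(n)
        y = 0.3 * prs + rng.standard_normal(n)
        res = PRSAssociation(y, prs, covariates=None).fit()
        assert 0.26 <= res.beta <= 0.34
        assert 0.06 <= res.r2_inc <= 0.10  # theory: 0.09/1.09 ~ 0.083

    def test_null_beta_within_bounds(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(100):
            y = rng.standard_normal(2000)
            prs = rng.standard_normal(2000)
            res = PRSAssociation(y, prs).fit()
            if abs(res.beta) >= 2.6 * res.se:
                hits += 1
        assert hits <= 3  # |beta| < 2.6 SE in >= 99% of null replicates (expect ~1%)

    def test_perfect_fit_r2(self):
        rng = np.random.default_rng(3)
        n = 300
        cov = rng.standard_normal((n, 2))
        prs = rng.standard_normal(n)
        res = PRSAssociation(prs.copy(), prs, cov).fit()
        assert res.r2_full == pytest.approx(1.0, abs=1e-10)
        assert res.r2_inc == pytest.approx(1.0 - res.r2_cov, abs=1e-10)

    def test_constant_prs_rejected(self):
        with pytest.raises(DataError):
            PRSAssociation(np.arange(50.0), np.ones(50)).fit()

    def test_summary_is_printable(self):
        rng = np.random.default_rng(4)
        res = PRSAssociation(rng.standard_normal(100), rng.standard_normal(100)).fit()
        assert "incremental R2" in res.summary()


class TestMeta:
    def test_single_cohort_identity(self):
        res = InverseVarianceMeta([0.25], [0.1]).fit()
        assert res.beta == pytest.approx(0.25)
        assert res.se == pytest.approx(0.1)

    def test_two_cohort_closed_form(self):
        res = InverseVarianceMeta([0.2, 0.4], [0.1, 0.1]).fit()
        assert res.beta == pytest.approx(0.3, abs=1e-12)
        assert res.se == pytest.approx(0.1 / np.sqrt(2), abs=1e-12)

    def test_order_invariance(self):
        a = InverseVarianceMeta([0.1, 0.3, -0.2], [0.05, 0.08, 0.11]).fit()
        b = InverseVarianceMeta([-0.2, 0.1, 0.3], [0.11, 0.05, 0.08]).fit()
        assert a.beta == pytest.approx(b.beta, abs=1e-14)
        assert a.q == pytest.approx(b.q, abs=1e-12)

    def test_pooled_se_below_every_cohort_se(self):
        rng = np.random.default_rng(5)
        ses = rng.uniform(0.05, 0.3, 4)
        res = InverseVarianceMeta(rng.normal(0, 0.1, 4), ses).fit()
        assert res.se < ses.min()

    def test_invalid_se_excluded(self):
        res = InverseVarianceMeta([0.2, 0.4], [0.1, -1.0]).fit()
        assert res.n_cohorts == 1
        assert res.beta == pytest.approx(0.2)

    def test_random_effects_widens_under_heterogeneity(self):
        fe = InverseVarianceMeta([0.0, 0.8], [0.05, 0.05], method="fixed").fit()
        re = InverseVarianceMeta([0.0, 0.8], [0.05, 0.05], method="random").fit()
        assert re.se > fe.se
        assert fe.i2 > 0.9


class TestEffectiveTests:
    def test_identity_counts_all(self):
        assert effective_tests(np.eye(7)) == pytest.approx(7.0, abs=1e-9)

    def test_rank_one_counts_one(self):
        assert effective_tests(np.ones((3, 3))) == pytest.approx(1.0, abs=1e-9)

    def test_two_by_two_half_correlation(self):
        r = np.array([[1.0, 0.5], [0.5, 1.0]])  # eigenvalues 1.5, 0.5
        assert effective_tests(r) == pytest.approx(2.0, abs=1e-9)

    def test_bounds_on_random_correlation_matrices(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            x = rng.standard_normal((60, 9))
            r = np.corrcoef(x.T)
            m_eff = effective_tests(r)
            assert 1.0 <= m_eff <= 9.0

    def test_non_symmetric_rejected(self):
        bad = np.array([[1.0, 0.2], [0.5, 1.0]])
        with pytest.raises(DataError):
            effective_tests(bad)


class TestCorrection:
    def _meta_df(self):
        return pd.DataFrame(
            {
                "phenotype": ["LV", "LV", "CC_total", "CC_total"],
                "pathway": ["ephrin", "ephrin", "ephrin", "ephrin"],
                "threshold": [1e-4, 0.05, 1e-4, 0.05],
                "p": [2e-4, 0.5, 0.9, 0.04],
            }
        )

    def test_declared_mode_threshold(self):
        flags = correct_pvalues(self._meta_df(), alpha=0.05, mode="declared")
        assert flags["alpha_corrected"].iloc[0] == pytest.approx(0.05 / 49)
        lv = flags[flags.phenotype == "LV"].iloc[0]
        assert lv["significant"] and lv["best_threshold"] == pytest.approx(1e-4)

    def test_thresholds_collapse_to_one_test(self):
        flags = correct_pvalues(self._meta_df(), alpha=0.05, mode="declared")
        assert len(flags) == 2  # one row per (phenotype, pathway)

    def test_effective_mode_limits(self):
        flags = correct_pvalues(
            self._meta_df(), alpha=0.05, mode="effective", m_eff_phenotypes=13.0, m_eff_prs=7.0
        )
        assert flags["alpha_corrected"].iloc[0] == pytest.approx(0.05 / 91)
        flags = correct_pvalues(
            self._meta_df(), alpha=0.05, mode="effective", m_eff_phenotypes=1.0, m_eff_prs=1.0
        )
        assert flags["alpha_corrected"].iloc[0] == pytest.approx(0.05)

    def test_alpha_validated(self):
        with pytest.raises(ParameterError):
            correct_pvalues(self._meta_df(), alpha=1.5)


class TestEndToEndAssociation:
    def test_cohort_fits_and_pooling_recover_signal(self, small_cohort):
        g, pw, ss, ph = small_cohort
        from pathprs.harmonize import harmonize_cohorts
        from pathprs.scoring import compute_prs_profile

        h = harmonize_cohorts(ph)
        prof = compute_prs_profile(g, ss, pw, (0.05,))
        assoc = fit_cohort_associations(h, prof, ph)
        assert set(assoc["cohort"]) == {"cohort1", "cohort2", "cohort3"}
        pooled = meta_analyze(assoc)
        assert (pooled["se"] > 0).all()
        # the risk-aligned score must associate positively with LV volume
        lv = pooled[(pooled.phenotype == "LV") & (pooled.pathway == "genome_wide")]
        assert lv["beta"].iloc[0] > 0
        assert lv["p"].iloc[0] < 0.05

    def test_scanner_dummies_built_for_multiscanner_cohort(self, small_cohort):
        _, _, _, ph = small_cohort
        c1 = ph[ph.cohort == "cohort1"]
        cov = build_covariates(c1)
        assert any(c.startswith("scanner_") for c in cov.columns)
        c2 = ph[ph.cohort == "cohort2"]
        assert not any(c.startswith("scanner_") for c in build_covariates(c2).columns)
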
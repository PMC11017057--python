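"""Gene-window SNP mapping, allele alignment, and PRS arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pathprs.data import GenotypeMatrix
from pathprs.errors import DataError
from pathprs.scoring import (
    align_alleles,
    clump_by_ld,
    compute_prs,
    compute_prs_profile,
    map_snps_to_pathway,
    select_by_threshold,
)
from .conftest import toy_sumstats


def brute_force_prs(dosages, weights, flipped):
    """Independent oracle: explicit double loop over (individual, SNP)."""
    n, m = dosages.shape
    scores = np.zeros(n)
    for i in range(n):
        for s in range(m):
            d = dosages[i, s]
            if flipped[s]:
                d = 2.0 - d
            scores[i] += weights[s] * d
    return scores


class TestMapping:
    def _snp_map(self, positions):
        return pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(len(positions))],
                "chrom": 1,
                "pos": positions,
                "ref": "A",
                "alt": "G",
                "maf": 0.2,
            }
        )

    def test_window_boundaries_inclusive(self):
        genes = pd.DataFrame({"gene": ["g"], "chrom": [1], "start": [50_000], "end": [60_000]})
        snps = self._snp_map([30_000, 29_999, 80_000, 80_001])
        got = map_snps_to_pathway(snps, genes, window=20_000)
        assert got == {"s0", "s2"}

    def test_union_over_overlapping_genes(self):
        genes = pd.DataFrame(
            {"gene": ["g1", "g2", "g3"], "chrom": [1, 1, 1], "start": [100, 150, 900], "end": [200, 260, 950]}
        )
        snps = self._snp_map([180, 500, 930])
        got = map_snps_to_pathway(snps, genes, window=0)
        assert got == {"s0", "s2"}  # shared SNP counted once

    def test_chromosome_mismatch_gives_empty_set(self):
        genes = pd.DataFrame({"gene": ["g"], "chrom": [9], "start": [100], "end": [200]})
        assert map_snps_to_pathway(self._snp_map([150]), genes, 0) == set()


class TestAlignment:
    def test_log_or_weight_on_matching_allele(self, toy_genotypes):
        ss = toy_sumstats(ors=(2.0, 1.0, 1.0))
        aligned = align_alleles(toy_genotypes, ss)
        w = aligned.table.set_index("snp_id")
        assert w.loc["s1", "weight"] == pytest.approx(np.log(2.0))
        assert not w.loc["s1", "flipped"]

    def test_flipped_allele_reflects_dosage(self, toy_genotypes):
        ss = toy_sumstats(ors=(2.0, 1.0, 1.0), flip=(True, False, False))
        aligned = align_alleles(toy_genotypes, ss)
        scores, n = compute_prs(toy_genotypes, aligned, {"s1"})
        # individual 2 has dosage 0 -> carries 2 copies of the effect (ref) allele
        assert scores[1] == pytest.approx(2 * np.log(2.0))
        assert scores[0] == pytest.approx(0.0)

    def test_strand_ambiguous_snps_dropped_with_count(self, toy_genotypes):
        gm = toy_genotypes
        gm.snp_map.loc[0, ["ref", "alt"]] = ["A", "T"]
        ss = toy_sumstats()
        ss.loc[0, ["effect_allele", "other_allele"]] = ["T", "A"]
        aligned = align_alleles(gm, ss)
        assert aligned.n_ambiguous_dropped == 1
        assert "s1" not in set(aligned.table["snp_id"])

    def test_irreconcilable_pair_dropped(self, toy_genotypes):
        ss = toy_sumstats()
        ss.loc[1, ["effect_allele", "other_allele"]] = ["A", "G"]  # genotype pair is C/T
        aligned = align_alleles(toy_genotypes, ss)
        assert aligned.n_mismatch_dropped == 1


class TestThreshold:
    def test_counts_and_nesting(self):
        ss = toy_sumstats(ps=(1e-9, 2e-5, 0.01)).assign(p_value=[1e-9, 2e-5, 0.01])
        extra = toy_sumstats().iloc[:1].assign(snp_id=["s4"], pos=[400], p_value=[0.2])
        ss = pd.concat([ss, extra], ignore_index=True)
        assert len(select_by_threshold(ss, 1e-4)) == 2
        assert select_by_threshold(ss, 1.0) == set(ss["snp_id"])
        s1 = select_by_threshold(ss, 5e-8)
        s2 = select_by_threshold(ss, 1e-4)
        s3 = select_by_threshold(ss, 0.05)
        assert s1 <= s2 <= s3


class TestPRS:
    def test_zero_dosage_zero_score(self, toy_genotypes):
        aligned = align_alleles(toy_genotypes, toy_sumstats(ors=(1.5, 1.3, 1.2)))
        scores, _ = compute_prs(toy_genotypes, aligned)
        assert scores[1] == 0.0

    def test_hand_computed_sum(self, toy_genotypes):
        aligned = align_alleles(toy_genotypes, toy_sumstats(ors=(1.5, 0.8, 1.2)))
        scores, n = compute_prs(toy_genotypes, aligned)
        assert n == 3
        assert scores[0] == pytest.approx(2 * np.log(1.5) + np.log(0.8), abs=1e-12)

    def test_single_snp_homozygote(self, toy_genotypes):
        aligned = align_alleles(toy_genotypes, toy_sumstats(ors=(2.0, 1.0, 1.0)))
        scores, _ = compute_prs(toy_genotypes, aligned, {"s1"})
        assert scores[0] == pytest.approx(2 * np.log(2.0))

    def test_empty_set_is_an_error(self, toy_genotypes):
        aligned = align_alleles(toy_genotypes, toy_sumstats())
        with pytest.raises(DataError):
            compute_prs(toy_genotypes, aligned, set())

    def test_missing_dosage_imputed_at_twice_sample_frequency(self, toy_genotypes):
        gm = toy_genotypes
        gm.dosages[0, 0] = np.nan
        aligned = align_alleles(gm, toy_sumstats(ors=(2.0, 1.0, 1.0)))
        scores, _ = compute_prs(gm, aligned, {"s1"})
        # remaining sample has dosage 0 -> imputed value 0 -> both scores 0
        assert scores[0] == pytest.approx(0.0)

    def test_matches_bruteforce_on_random_instance(self):
        rng = np.random.default_rng(42)
        n, m = 50, 200
        gm, ss = _random_instance(rng, n, m)
        aligned = align_alleles(gm, ss)
        scores, _ = compute_prs(gm, aligned)
        w = aligned.table["weight"].to_numpy()
        flipped = aligned.table["flipped"].to_numpy()
        expected = brute_force_prs(gm.dosages, w, flipped)
        np.testing.assert_allclose(scores, expected, atol=1e-10)


def _random_instance(rng, n, m):
    maf = rng.uniform(0.05, 0.5, m)
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(m)],
            "chrom": 1,
            "pos": np.arange(1, m + 1) * 1000,
            "ref": "A",
            "alt": "G",
            "maf": maf,
        }
    )
    dosages = rng.binomial(2, maf, size=(n, m)).astype(float)
    gm = GenotypeMatrix(dosages, snp_map, [f"i{j}" for j in range(n)]).validate()
    flip = rng.random(m) < 0.5
    ss = pd.DataFrame(
        {
            "snp_id": snp_map["snp_id"],
            "chrom": 1,
            "pos": snp_map["pos"],
            "effect_allele": np.where(flip, "A", "G"),
            "other_allele": np.where(flip, "G", "A"),
            "odds_ratio": np.exp(rng.normal(0, 0.1, m)),
            "p_value": rng.uniform(1e-10, 1.0, m),
        }
    )
    return gm, ss


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_allele_recoding_invariance(seed):
    """Recoding ref/alt and reflecting dosage leaves every score unchanged."""
    rng = np.random.default_rng(seed)
    gm, ss = _random_instance(rng, 8, 6)
    scores1, _ = compute_prs(gm, align_alleles(gm, ss))
    j = int(rng.integers(0, 6))
    gm.snp_map.loc[j, ["ref", "alt"]] = gm.snp_map.loc[j, ["alt", "ref"]].to_numpy()
    gm.dosages[:, j] = 2.0 - gm.dosages[:, j]
    scores2, _ = compute_prs(gm, align_alleles(gm, ss))
    np.testing.assert_allclose(scores1, scores2, atol=1e-10)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_threshold_nestedness_and_score_difference(seed):
    rng = np.random.default_rng(seed)
    gm, ss = _random_instance(rng, 8, 12)
    aligned = align_alleles(gm, ss)
    t1, t2 = sorted(rng.uniform(0.01, 1.0, 2))
    set1 = select_by_threshold(ss, t1)
    set2 = select_by_threshold(ss, t2)
    assert set1 <= set2
    if set1 and set2 > set1:
        s1, _ = compute_prs(gm, aligned, set1)
        s2, _ = compute_prs(gm, aligned, set2)
        diff, _ = compute_prs(gm, aligned, set2 - set1)
        np.testing.assert_allclose(s2 - s1, diff, atol=1e-10)


def test_doubling_weights_doubles_scores(toy_genotypes):
    aligned = align_alleles(toy_genotypes, toy_sumstats(ors=(1.5, 0.8, 1.2)))
    scores1, _ = compute_prs(toy_genotypes, aligned)
    doubled = aligned.table.assign(weight=aligned.table["weight"] * 2)
    scores2, _ = compute_prs(toy_genotypes, doubled)
    np.testing.assert_allclose(scores2, 2 * scores1, atol=1e-12)


def test_profile_nested_snp_counts(small_cohort):
    g, pw, ss, _ = small_cohort
    prof = compute_prs_profile(g, ss, pw, (1e-4, 1e-2, 1.0))
    for (_, path), grp in prof.groupby(["sample_id", "pathway"]):
        n = grp.sort_values("threshold")["n_snps"].to_numpy()
        assert (np.diff(n) >= 0).all()


def test_average_mode_divides_by_snp_count(toy_genotypes):
    aligned = align_alleles(toy_genotypes, toy_sumstats(ors=(1.5, 0.8, 1.2)))
    total, n = compute_prs(toy_genotypes, aligned)
    avg, _ = compute_prs(toy_genotypes, aligned, average=True)
    np.testing.assert_allclose(avg, total / n, atol=1e-12)


def test_clumping_keeps_best_of_correlated_pair():
    rng = np.random.default_rng(5)
    maf = np.array([0.3, 0.3, 0.3])
    base = rng.binomial(2, 0.3, size=(400,)).astype(float)
    dosages = np.column_stack([base, base, rng.binomial(2, 0.3, 400)])
    snp_map = pd.DataFrame(
        {"snp_id": ["a", "b", "c"], "chrom": 1, "pos": [1000, 2000, 500_000], "ref": "A", "alt": "G", "maf": maf}
    )
    gm = GenotypeMatrix(dosages, snp_map, [f"i{j}" for j in range(400)]).validate()
    ss = pd.DataFrame(
        {
            "snp_id": ["a", "b", "c"],
            "chrom": 1,
            "pos": [1000, 2000, 500_000],
            "effect_allele": "G",
            "other_allele": "A",
            "odds_ratio": [1.2, 1.3, 1.1],
            "p_value": [1e-4, 1e-6, 0.01],
        }
    )
    clumped = clump_by_ld(gm, align_alleles(gm, ss), r2_max=0.5)
    kept = set(clumped.table["snp_id"])
    assert kept == {"b", "c"}  # 'a' is a perfect proxy of the better 'b'
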
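import numpy as np
import pandas as pd
import pytest

from pathprs import SimulationConfig
from pathprs.simulate import simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_cohorts=3,
        n_cases_per_cohort=60,
        n_controls_per_cohort=70,
        n_snps=400,
        n_genes=24,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """One small end-to-end dataset shared across tests (read-only)."""
    return simulate_cohort(small_config)


@pytest.fixture
def toy_genotypes():
    """Hand-sized genotype matrix for exact scoring arithmetic."""
    from pathprs.data import GenotypeMatrix

    snp_map = pd.DataFrame(
        {
            "snp_id": ["s1", "s2", "s3"],
            "chrom": [1, 1, 1],
            "pos": [100, 200, 300],
            "ref": ["A", "C", "G"],
            "alt": ["G", "T", "A"],
            "maf": [0.2, 0.3, 0.4],
        }
    )
    dosages = np.array([[2.0, 1.0, 0.0], [0.0, 0.0, 0.0]])
    return GenotypeMatrix(dosages=dosages, snp_map=snp_map, sample_ids=["i1", "i2"]).validate()


def toy_sumstats(ors=(1.5, 0.8, 1.2), ps=(1e-9, 2e-5, 0.01), flip=(False, False, False)):
    ref = ["A", "C", "G"]
    alt = ["G", "T", "A"]
    eff = [r if f else a for r, a, f in zip(ref, alt, flip)]
    oth = [a if f else r for r, a, f in zip(ref, alt, flip)]
    return pd.DataFrame(
        {
            "snp_id": ["s1", "s2", "s3"],
            "chrom": [1, 1, 1],
            "pos": [100, 200, 300],
            "effect_allele": eff,
            "other_allele": oth,
            "odds_ratio": list(ors),
            "p_value": list(ps),
        }
    )
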
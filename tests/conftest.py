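import numpy as np
import pandas as pd
import pytest
from scipy import stats

from memoscore.dataio import GenotypePanel
from memoscore.synthcohort import SimConfig, simulate_cohort


def toy_panel(n=6, m=4, seed=0, maf=0.3):
    """Small hand-checkable genotype panel with unambiguous alleles."""
    rng = np.random.default_rng(seed)
    dos = rng.binomial(2, maf, size=(n, m)).astype(float)
    variants = pd.DataFrame(
        {"variant_id": [f"v{j + 1}" for j in range(m)],
         "chrom": "1", "pos": np.arange(1, m + 1) * 100,
         "effect_allele": ["A", "C", "G", "T"][:m],
         "other_allele": ["G", "T", "A", "C"][:m]}
    )
    return GenotypePanel(np.array([f"s{i}" for i in range(n)], dtype=object),
                         variants, dos)


@pytest.fixture
def small_panel():
    return toy_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared by read-only tests."""
    cfg = SimConfig(n_samples=400, n_variants=200, n_blocks=10,
                    n_causal_variants=8, n_metabolites=30,
                    n_causal_metabolites=5, n_external_cohorts=2,
                    external_n_per_cohort=200, seed=11)
    panel, cohort, truth = simulate_cohort(cfg)
    return cfg, panel, cohort, truth


def thresholded_ar_corr_oracle(rho, maf, n_draws=1_000_000, seed=123):
    """Monte-Carlo oracle: dosage correlation of two adjacent variants whose
    latent liabilities have correlation rho and are thresholded at the MAF.

    Haplotype alleles are Bernoulli indicators of correlated Gaussians; the
    dosage (sum of two independent haplotypes) has the same correlation as
    a single haplotype pair.
    """
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n_draws)
    z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n_draws)
    t = stats.norm.ppf(maf)
    a1, a2 = z1 < t, z2 < t
    return np.corrcoef(a1, a2)[0, 1]
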
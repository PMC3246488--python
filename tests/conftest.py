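import numpy as np
import pandas as pd
import pytest

import pgskit


@pytest.fixture(scope="session")
def small_cohort():
    """A small family cohort with genotypes and a simulated height."""
    cfg = pgskit.SimConfig(n_families=30, n_related=100, n_unrelated=60,
                           n_male=80, n_snps=300, rng_seed=11)
    samples = pgskit.simulate_pedigrees(cfg)
    gm = pgskit.drop_genotypes(samples, cfg)
    truth = pgskit.make_true_panel(gm, 40, 0.10, rng_seed=11)
    samples = pgskit.simulate_phenotype(gm, samples, truth, rng_seed=11)
    return {"config": cfg, "samples": samples, "genotypes": gm,
            "truth": truth}


@pytest.fixture(scope="session")
def small_model(small_cohort):
    return pgskit.adjust_phenotype(small_cohort["samples"])


def random_genotype_matrix(rng, n_samples, n_snps, missing_rate=0.0,
                           chrom="1", spacing=10_000):
    """Ad-hoc genotype fixture with HWE draws at random frequencies."""
    p = rng.uniform(0.05, 0.95, size=n_snps)
    dosage = rng.binomial(2, p, size=(n_samples, n_snps)).astype(float)
    if missing_rate > 0:
        mask = rng.random(dosage.shape) < missing_rate
        dosage[mask] = np.nan
    snps = pd.DataFrame({
        "snp_id": [f"m{j}" for j in range(n_snps)],
        "chrom": chrom,
        "pos": spacing * np.arange(1, n_snps + 1),
        "counted_allele": "A",
        "other_allele": "G",
    })
    return pgskit.GenotypeMatrix(dosage, snps,
                                 [f"s{i}" for i in range(n_samples)])
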
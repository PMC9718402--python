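import numpy as np
import pandas as pd
import pytest

from prstack import GenotypeMatrix, SimConfig
from prstack import synthetic


def random_genotypes(rng: np.random.Generator, n: int, m: int,
                     missing_rate: float = 0.0,
                     n_chrom: int = 1) -> GenotypeMatrix:
    """Small random genotype matrix with plain (non-ambiguous) alleles."""
    dosages = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random((n, m)) < missing_rate
        dosages[mask] = -1
    per_chrom = m // n_chrom
    chrom = np.repeat(np.arange(1, n_chrom + 1), per_chrom)[:m]
    pos = np.tile(np.arange(1, per_chrom + 1) * 1000, n_chrom)[:m]
    alleles = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G")]
    pick = rng.integers(0, 4, size=m)
    variants = pd.DataFrame({
        "chrom": chrom,
        "rsid": [f"rs{i + 1}" for i in range(m)],
        "pos": pos,
        "a1": [alleles[k][0] for k in pick],
        "a2": [alleles[k][1] for k in pick],
    })
    samples = [f"s{i + 1}" for i in range(n)]
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A fast 2-chromosome study used by several end-to-end tests."""
    return SimConfig(n_ind=2_000, n_chrom=2, snps_per_chrom=100,
                     block_size=20, gwas_n=4_000, n_causal=20, h2=0.3,
                     seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    """Genotypes, cohort, effects and sumstats for the small study."""
    model = synthetic.variant_model(small_config)
    geno = synthetic.simulate_genotypes(small_config, model=model)
    cohort, effects = synthetic.simulate_phenotypes(geno, small_config)
    sumstats = synthetic.simulate_sumstats(small_config, effects, model=model)
    return {"config": small_config, "model": model, "genotypes": geno,
            "cohort": cohort, "effects": effects, "sumstats": sumstats}
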
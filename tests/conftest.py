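"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from keelgen.dataio import GenotypeMatrix
from keelgen.pheno import log_transform
from keelgen.simulate import SimConfig, simulate_genotypes, simulate_phenotypes


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_sires=10,
        dams_per_sire=12,
        offspring_per_dam=1,
        n_chromosomes=2,
        snps_per_chromosome=100,
        n_qtl=5,
        h2_liability=0.3,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """120 hens x 200 SNPs with phenotypes; enough for most unit tests."""
    geno, pedigree = simulate_genotypes(small_config)
    samples, truth = simulate_phenotypes(geno, pedigree, small_config)
    samples = log_transform(samples)
    return geno, pedigree, samples, truth


@pytest.fixture()
def tiny_geno():
    """Hand-built 3 individuals x 4 SNPs matrix with one missing call."""
    dosages = np.array(
        [
            [0.0, 1.0, 2.0, np.nan],
            [1.0, 1.0, 0.0, 2.0],
            [2.0, 0.0, 1.0, 0.0],
        ]
    )
    snp_info = pd.DataFrame(
        {
            "snp_id": ["s1", "s2", "s3", "s4"],
            "chrom": ["1", "1", "2", "2"],
            "pos": [100, 200, 100, 5000],
            "allele1": ["A", "G", "T", "C"],
            "allele2": ["B", "C", "A", "G"],
        }
    )
    return GenotypeMatrix(dosages=dosages, snp_info=snp_info, sample_ids=["i1", "i2", "i3"])


def random_genotype_matrix(rng: np.random.Generator, n: int, m: int, miss: float = 0.05) -> GenotypeMatrix:
    d = rng.integers(0, 3, size=(n, m)).astype(float)
    d[rng.random((n, m)) < miss] = np.nan
    snp_info = pd.DataFrame(
        {
            "snp_id": [f"snp{j}" for j in range(m)],
            "chrom": ["1"] * m,
            "pos": np.sort(rng.choice(np.arange(1, 10_000_000), size=m, replace=False)),
            "allele1": ["A"] * m,
            "allele2": ["B"] * m,
        }
    )
    return GenotypeMatrix(dosages=d, snp_info=snp_info, sample_ids=[f"i{i}" for i in range(n)])
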
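import numpy as np
import pytest

from segmeta.genotype_io import MISSING, Cohort, SnpRecord


def random_cohort(rng, n_individuals=20, n_snps=50, missing_rate=0.05,
                  chroms=(1, 2), cohort_id="rand"):
    """Random valid cohort: sorted map, dosages with missingness, both classes."""
    per = n_snps // len(chroms)
    snps = []
    for ci, chrom in enumerate(chroms):
        n = per if ci < len(chroms) - 1 else n_snps - per * (len(chroms) - 1)
        pos = np.sort(rng.choice(np.arange(1, 10_000_000, 1000), size=n, replace=False))
        snps.extend(SnpRecord(f"rs{chrom}_{k}", chrom, int(p)) for k, p in enumerate(pos))
    geno = rng.integers(0, 3, size=(n_individuals, n_snps)).astype(np.int8)
    miss = rng.random((n_individuals, n_snps)) < missing_rate
    geno[miss] = MISSING
    pheno = rng.integers(0, 2, size=n_individuals).astype(np.int8)
    pheno[0], pheno[1] = 0, 1  # guarantee both classes
    return Cohort(snps=snps, genotypes=geno, phenotype=pheno, cohort_id=cohort_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_cohort(rng):
    return random_cohort(rng)


def make_cohort_from_dosages(dosages, phenotype, spacing=1_000_000, chrom=1):
    dosages = np.asarray(dosages, dtype=np.int8)
    snps = [SnpRecord(f"s{j}", chrom, (j + 1) * spacing) for j in range(dosages.shape[1])]
    return Cohort(snps=snps, genotypes=dosages,
                  phenotype=np.asarray(phenotype, dtype=np.int8))
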
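import numpy as np
import pandas as pd
import pytest

from gweiskit.io_genetics import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def make_genotypes(dosages, bp=None, chrom="1", sample_prefix="S", a1="A", a2="G"):
    """Small genotype matrix straight from a dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    snps = pd.DataFrame({
        "id": [f"snp{j + 1}" for j in range(m)],
        "chr": chrom,
        "bp": bp if bp is not None else 1_000_000 + np.arange(m) * 10_000,
        "a1": a1,
        "a2": a2,
    })
    ids = np.array([f"{sample_prefix}{i + 1}" for i in range(n)], dtype=object)
    return GenotypeMatrix(ids, dosages, snps)


@pytest.fixture
def small_genotypes(rng):
    return make_genotypes(rng.integers(0, 3, size=(20, 6)).astype(float))
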
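import numpy as np
import pytest

from stockpriority.genotype_io import Collection, GenotypeDataset, Locus


def make_collection(genotypes, river="X", year=2010):
    """Collection from a nested list (n_individuals, n_loci, 2) of allele codes."""
    return Collection(river, year, np.asarray(genotypes, dtype=np.int32))


def make_dataset(pops: dict, n_loci=None):
    """Dataset from {river: genotype nested list}."""
    cols = [make_collection(g, river=r) for r, g in pops.items()]
    L = cols[0].genotypes.shape[1]
    loci = [Locus(f"L{j+1}") for j in range(L)]
    return GenotypeDataset(loci, cols)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def structured_dataset():
    """3 stocks x 5 rivers x 10 individuals, strong stock / weak river divergence."""
    from stockpriority.synthetic_data import GenotypeSimSpec, simulate_genotypes

    spec = GenotypeSimSpec(
        n_stocks=3,
        rivers_per_stock=5,
        individuals_per_river=10,
        n_loci=12,
        alleles_per_locus=8,
        f_stock=0.10,
        f_river=0.01,
        missing_rate=0.02,
        seed=3,
    )
    return simulate_genotypes(spec)
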
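import numpy as np
import pytest

from rerepop import GenotypeDataset, HaplotypeAlignment, IslandModelParams, simulate_island_model


def make_dataset(genotype_rows, populations, loci=None):
    """Build a GenotypeDataset from nested [[a, b], ...] per-individual rows."""
    geno = np.array(genotype_rows, dtype=np.int64)
    n, L = geno.shape[0], geno.shape[1]
    loci = loci or [f"L{j + 1}" for j in range(L)]
    return GenotypeDataset([f"i{k}" for k in range(n)], list(populations), loci, geno)


@pytest.fixture
def two_pop_ds():
    """Two populations x three individuals, two loci, one missing genotype."""
    return make_dataset(
        [
            [[1, 2], [3, 3]],
            [[1, 1], [3, 4]],
            [[2, 2], [0, 0]],
            [[5, 6], [4, 4]],
            [[5, 5], [3, 4]],
            [[6, 6], [4, 4]],
        ],
        ["A", "A", "A", "B", "B", "B"],
    )


@pytest.fixture
def island_ds():
    p = IslandModelParams(D=3, N=20, m=0.02, L=6, mu=1e-3, G=60, missing_rate=0.05, seed=11)
    ds, truth = simulate_island_model(p)
    return ds, truth


@pytest.fixture
def small_alignment():
    return HaplotypeAlignment(
        ["s1", "s2", "s3", "s4", "s5", "s6"],
        ["AAAA", "AAAT", "AAAT", "CCCC", "CCCC", "CCCC"],
        ["wild", "wild", "wild", "wild", "captive", "captive"],
    )
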
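import numpy as np
import pytest

from plantmating.geno_io import GenotypeMatrix, PopMeta


@pytest.fixture
def toy_pop():
    """4 individuals x 3 loci with one missing call; hand-checkable."""
    calls = np.array([
        [[1, 2], [3, 3], [1, 1]],
        [[1, 1], [3, 4], [0, 0]],
        [[2, 2], [4, 4], [1, 2]],
        [[1, 2], [3, 4], [2, 2]],
    ])
    return GenotypeMatrix([f"i{k}" for k in range(4)], ["L1", "L2", "L3"],
                          calls, PopMeta(population="toy"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_matrix(rng, n=6, L=4, n_alleles=4, missing_rate=0.1,
                  population="p"):
    calls = rng.integers(1, n_alleles + 1, size=(n, L, 2))
    miss = rng.random((n, L)) < missing_rate
    calls[miss] = 0
    return GenotypeMatrix([f"{population}_i{k}" for k in range(n)],
                          [f"loc{j}" for j in range(L)], calls,
                          PopMeta(population=population))
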
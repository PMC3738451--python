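import numpy as np
import pytest

from essbvs import DataBundle, GenotypeMatrix, TraitMatrix, make_size_prior
from essbvs.priors import GPriorSpec


def genotype_column(n0: int, n1: int, n2: int) -> np.ndarray:
    """A genotype column with exact genotype counts (n0, n1, n2)."""
    return np.concatenate([np.zeros(n0), np.ones(n1), np.full(n2, 2.0)])


@pytest.fixture
def small_genotypes() -> GenotypeMatrix:
    rng = np.random.default_rng(7)
    n, p = 120, 12
    G = rng.binomial(2, rng.uniform(0.15, 0.5, size=p), size=(n, p)).astype(float)
    # guard against monomorphic columns in the fixture itself
    for j in range(p):
        if len(np.unique(G[:, j])) == 1:
            G[0, j] = 1.0 - G[0, j]
    return GenotypeMatrix(G, [f"rs{j}" for j in range(p)])


@pytest.fixture
def toy_bundle():
    """n=40, p=6, q=2 dataset with two real effects, plus its priors."""
    rng = np.random.default_rng(0)
    n, p, q = 40, 6, 2
    X = rng.standard_normal((n, p))
    beta = np.zeros((p, q))
    beta[1, 0] = 0.8
    beta[4, 1] = 0.6
    beta[1, 1] = 0.3
    Y = X @ beta + rng.standard_normal((n, q))
    data = DataBundle(Y - Y.mean(0), X, c_eff=1)
    size_prior = make_size_prior(1.5, 2.0, 3.0, p)
    g_prior = GPriorSpec(n)
    return data, size_prior, g_prior
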
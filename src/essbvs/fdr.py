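"""Permutation-based empirical FDR calibration of MPPI.

The null distribution of the MPPI is generated by re-running the whole
analysis on datasets in which the rows (subjects) of the trait matrix
are permuted together — breaking every trait-genotype link while
preserving the between-trait correlation — and pooling the resulting
MPPI values, optionally across trait groups of equal cardinality so the
tail is well estimated. The significance threshold m* is then the
smallest observed MPPI value at which

    (# null MPPI >= m* / K) / (# observed MPPI >= m*)  <=  alpha,

i.e. the expected per-dataset count of null exceedances relative to the
observed count is at most the FDR level; K is the number of permuted
datasets contributing to the pool, so the numerator is a per-dataset
expectation and the estimate does not scale with K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import TraitMatrix

__all__ = [
    "FdrConfig",
    "NullPool",
    "permute_traits",
    "mppi_threshold",
    "declare_significant",
]


@dataclass
class FdrConfig:
    K: int = 3
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("need at least one permutation")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class NullPool:
    """Pooled null MPPI values for trait groups of one cardinality."""

    cardinality: int
    mppi_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_source_runs: int = 0

    def add(self, mppi: np.ndarray) -> None:
        self.mppi_values = np.concatenate([self.mppi_values, np.asarray(mppi, float)])
        self.n_source_runs += 1

    @property
    def size(self) -> int:
        return self.mppi_values.size


def permute_traits(Y: TraitMatrix, K: int, seed: int) -> list[TraitMatrix]:
    """K row-permuted copies of Y (all traits permuted together).

    Permutations are distinct from the identity and reproducible from
    the seed.
    """
    if Y.n < 2:
        raise ValueError("need at least two rows to permute")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(K):
        perm = rng.permutation(Y.n)
        while (perm == np.arange(Y.n)).all():
            perm = rng.permutation(Y.n)
        out.append(TraitMatrix(Y.values[perm], list(Y.trait_names)))
    return out


def mppi_threshold(
    observed: np.ndarray, pool: NullPool, alpha: float, K: int | None = None
) -> float:
    """Smallest observed MPPI m* with estimated FDR <= alpha; +inf when no
    observed value qualifies (nothing declared).

    Candidate thresholds are the positive observed MPPI values
    themselves (the declared set only changes there), giving the least
    conservative valid step.
    """
    if pool.size == 0:
        raise ValueError("empty null pool")
    K = K if K is not None else max(pool.n_source_runs, 1)
    observed = np.asarray(observed, dtype=float)
    null = np.sort(pool.mppi_values)
    obs_sorted = np.sort(observed)
    best = np.inf
    for m in np.unique(observed[observed > 0]):
        n_obs = observed.size - np.searchsorted(obs_sorted, m, side="left")
        n_null = null.size - np.searchsorted(null, m, side="left")
        if n_obs == 0:
            continue
        if (n_null / K) / n_obs <= alpha:
            best = min(best, float(m))
    return best


def declare_significant(observed: np.ndarray, m_star: float) -> np.ndarray:
    """Boolean flags: MPPI >= m* (all False when m* is +inf)."""
    observed = np.asarray(observed, dtype=float)
    if not np.isfinite(m_star):
        return np.zeros(observed.size, dtype=bool)
    return observed >= m_star
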
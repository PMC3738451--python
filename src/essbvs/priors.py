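"""Priors on the model space and on the selection coefficient g.

Sparsity is parameterised through natural quantities: the a-priori
expected model size E and its standard deviation S. These are moment-
matched to a beta-binomial distribution on the number of included SNPs
(binomial inclusion with a Beta(a, b) mixing probability), which is the
only exchangeable-inclusion family that can carry the overdispersion
S >> sqrt(E) such parameterisations imply. The prior is hard-truncated
at T = floor(E + F*S): models above T get zero prior mass, which the
sampler realises by rejecting any proposal beyond T. For F >= 3 the
untruncated mass above T is ~1 - Phi(F), i.e. negligible.

The selection (shrinkage) coefficient g carries an inverse-gamma
(1/2, n/2) hyper-prior — the Zellner-Siow choice, which makes the
implied coefficient prior heavy-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, inf, lgamma, log

import numpy as np
from scipy import special

__all__ = [
    "ModelSizePrior",
    "GPriorSpec",
    "ModelIndicator",
    "make_size_prior",
    "log_prior_model",
    "model_space_size",
    "log_prior_g",
]


@dataclass(frozen=True)
class ModelIndicator:
    """A sparse model: the sorted tuple of included SNP column indices."""

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(sorted(int(i) for i in self.indices))
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate indices in model")
        if idx and idx[0] < 0:
            raise ValueError("negative SNP index")
        object.__setattr__(self, "indices", idx)

    @property
    def size(self) -> int:
        return len(self.indices)

    def with_flip(self, j: int) -> "ModelIndicator":
        s = set(self.indices)
        s.symmetric_difference_update({j})
        return ModelIndicator(tuple(s))


@dataclass(frozen=True)
class ModelSizePrior:
    E: float
    S: float
    F: float
    p: int
    T: int
    a: float  # Beta hyper-parameters of the per-SNP inclusion probability;
    b: float  # a = b = inf marks the zero-overdispersion (plain binomial) limit
    pi_avg: float

    @property
    def likely_range(self) -> tuple[float, float]:
        """The 'likely' prior model-size range reported to users: [0, E+3S]."""
        return (0.0, self.E + 3.0 * self.S)

    @property
    def is_binomial(self) -> bool:
        return not np.isfinite(self.a)


def make_size_prior(E: float, S: float, F: float, p: int) -> ModelSizePrior:
    """Moment-match (E, S) to a truncated beta-binomial model-size prior.

    With pi ~ Beta(a, b), c = a + b and pibar = E/p, the model size
    k ~ BetaBinomial(p, a, b) has mean p*pibar and variance
    p*pibar*(1-pibar)*(p+c)/(1+c); solving the variance equation for c
    gives the unique overdispersed match. S^2 must exceed the binomial
    variance E(1-E/p); equality falls back to the plain-binomial prior
    with pi = E/p, and anything below is infeasible.
    """
    if not 0 < E < p:
        raise ValueError("need 0 < E < p")
    if S <= 0:
        raise ValueError("S must be positive")
    if F < 0:
        raise ValueError("F must be non-negative")
    pibar = E / p
    binom_var = p * pibar * (1 - pibar)
    T = int(np.floor(E + F * S))
    if T < 1:
        raise ValueError("truncation T < 1: increase E or F*S")
    if S**2 < binom_var * (1.0 - 1e-9):
        raise ValueError(
            f"S^2 = {S**2:.4g} below the binomial variance {binom_var:.4g}: "
            "no beta-binomial matches; use the plain-binomial mode (S^2 = E(1-E/p))"
        )
    if S**2 <= binom_var * (1.0 + 1e-9):
        # zero-overdispersion limit: Beta collapses to a point mass at pibar
        return ModelSizePrior(E, S, F, p, T, inf, inf, pibar)
    c = (p**2 * pibar * (1 - pibar) - S**2) / (S**2 - binom_var)
    if c <= 0:
        raise ValueError("S too large: implied Beta concentration non-positive")
    return ModelSizePrior(E, S, F, p, T, pibar * c, (1 - pibar) * c, pibar)


def _log_betabinom_pmf_over_choose(k: int, prior: ModelSizePrior) -> float:
    """log[ f(k) / C(p, k) ] for the (untruncated) model-size pmf f."""
    if prior.is_binomial:
        return k * log(prior.pi_avg) + (prior.p - k) * log(1 - prior.pi_avg)
    a, b, p = prior.a, prior.b, prior.p
    return float(
        special.betaln(k + a, p - k + b) - special.betaln(a, b)
    )


def log_prior_model(gamma: ModelIndicator, prior: ModelSizePrior) -> float:
    """Unnormalised log prior of one model; -inf beyond the truncation.

    Per-model mass is f(p_gamma)/C(p, p_gamma) — models of equal size are
    exchangeable. The truncation's renormalising constant is omitted: it
    cancels in every MH acceptance ratio.
    """
    k = gamma.size
    if k > prior.T:
        return -inf
    if gamma.indices and gamma.indices[-1] >= prior.p:
        raise ValueError("model index beyond panel size")
    return _log_betabinom_pmf_over_choose(k, prior)


def model_space_size(p: int, T: int) -> int:
    """Number of models of size <= T among p SNPs: sum_{k<=T} C(p, k), exact."""
    if not 0 <= T <= p:
        raise ValueError("need 0 <= T <= p")
    return sum(comb(p, k) for k in range(T + 1))


@dataclass(frozen=True)
class GPriorSpec:
    """Inverse-gamma(shape=1/2, rate=n/2) hyper-prior on g (Zellner-Siow)."""

    n: int
    shape: float = 0.5

    @property
    def rate(self) -> float:
        return self.n / 2.0

    @property
    def mode(self) -> float:
        return self.rate / (self.shape + 1.0)


def log_prior_g(g: float, spec: GPriorSpec) -> float:
    """Log density of InverseGamma(1/2, n/2) at g."""
    if g <= 0:
        raise ValueError("g must be positive")
    a, b = spec.shape, spec.rate
    return a * log(b) - lgamma(a) - (a + 1.0) * log(g) - b / g
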
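"""Conjugate multi-response marginal likelihood and the log-posterior.

The regression model for a candidate SNP set gamma is

    Y = X_gamma B + E,   rows of E ~ N_q(0, Sigma),

with the g-prior B ~ MN(0, g (X_gamma' X_gamma)^-1, Sigma) — the
coefficient prior replicates the covariance geometry of the likelihood —
and the Jeffreys-style improper prior |Sigma|^-(q+1)/2 on the residual
covariance. Integrating B and Sigma out analytically gives, up to one
additive constant shared by every (gamma, g) on a dataset,

    log p(Y | gamma, g) = -(k q / 2) log(1 + g)
                          - ((n - c_eff)/2) log det S(gamma, g),

    S(gamma, g) = Y'Y - (g/(1+g)) Y' H_gamma Y,

where k = rank(X_gamma), H_gamma is the orthogonal projector onto
col(X_gamma), and c_eff counts the covariate columns (plus intercept)
projected out upstream — the degrees-of-freedom bookkeeping that makes
projection equivalent to carrying the covariates as always-in
regressors. H_gamma is obtained from a column-pivoted QR factorisation
of X_gamma, which both stabilises the computation and determines k when
columns are collinear (duplicated SNPs leave the value unchanged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .priors import GPriorSpec, ModelIndicator, ModelSizePrior, log_prior_g, log_prior_model

__all__ = ["DataBundle", "LogPosterior", "log_marginal_likelihood", "log_posterior"]


@dataclass
class DataBundle:
    """Covariate-projected data plus the cached cross-products the
    sampler's fast path needs."""

    Ytilde: np.ndarray  # n x q
    Xtilde: np.ndarray  # n x p, column-centred
    c_eff: int
    gram_cache_limit: int = 2000  # precompute X'X when p is at most this

    def __post_init__(self) -> None:
        self.Ytilde = np.atleast_2d(np.asarray(self.Ytilde, dtype=float))
        if self.Ytilde.shape[0] == 1 and self.Ytilde.shape[1] > 1:
            self.Ytilde = self.Ytilde.T
        self.Xtilde = np.asarray(self.Xtilde, dtype=float)
        # centring is idempotent: the upstream projection removes the
        # intercept, but raw matrices are accepted too
        self.Xtilde = self.Xtilde - self.Xtilde.mean(axis=0)
        self.YtY = self.Ytilde.T @ self.Ytilde
        self.XtY = self.Xtilde.T @ self.Ytilde
        self.x_sq = np.einsum("ij,ij->j", self.Xtilde, self.Xtilde)
        # full Gram cache: turns the sampler's per-proposal inner products
        # into O(p) table lookups when the panel is small enough
        self.gram = (
            self.Xtilde.T @ self.Xtilde
            if self.Xtilde.shape[1] <= self.gram_cache_limit
            else None
        )
        sign, ld = np.linalg.slogdet(self.YtY)
        if sign <= 0:
            raise ValueError("Y'Y is singular: traits are collinear after projection")
        self.logdet_YtY = float(ld)

    @property
    def n(self) -> int:
        return self.Ytilde.shape[0]

    @property
    def q(self) -> int:
        return self.Ytilde.shape[1]

    @property
    def p(self) -> int:
        return self.Xtilde.shape[1]

    @property
    def df(self) -> float:
        return self.n - self.c_eff


def _logdet_S(data: DataBundle, A: np.ndarray, g: float) -> float:
    """log det of S = Y'Y - (g/(1+g)) A, Cholesky with a clipped-eigenvalue
    fallback for near-singular S."""
    h = g / (1.0 + g)
    S = data.YtY - h * A
    try:
        L = np.linalg.cholesky(S)
        return 2.0 * float(np.log(np.diag(L)).sum())
    except np.linalg.LinAlgError:
        w = np.linalg.eigvalsh(S)
        floor = 1e-12 * float(np.trace(S))
        if floor <= 0 or w[-1] <= 0:
            raise ValueError(
                "residual cross-product S is not positive definite: "
                "collinearity beyond QR rank handling"
            )
        warnings.warn("near-singular residual cross-product; clipping eigenvalues")
        return float(np.log(np.clip(w, floor, None)).sum())


def model_projection_stats(data: DataBundle, gamma: ModelIndicator) -> tuple[int, np.ndarray]:
    """(rank k, A = Y' H_gamma Y) via column-pivoted QR of X_gamma."""
    if gamma.size == 0:
        return 0, np.zeros((data.q, data.q))
    Xg = data.Xtilde[:, list(gamma.indices)]
    Q, R, _ = linalg.qr(Xg, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    tol = max(Xg.shape) * np.finfo(float).eps * (d[0] if d.size else 0.0)
    k = int((d > tol).sum())
    if k == 0:
        return 0, np.zeros((data.q, data.q))
    Z = Q[:, :k].T @ data.Ytilde
    return k, Z.T @ Z


def log_marginal_likelihood(data: DataBundle, gamma: ModelIndicator, g: float) -> float:
    """QR-based log marginal likelihood, up to a per-dataset constant.

    The empty model's value is g-free; the g -> 0 limit of any model
    recovers it (zero shrinkage towards the data is total shrinkage of
    the coefficients towards zero).
    """
    if g <= 0:
        raise ValueError("g must be positive")
    if gamma.size >= data.n - data.c_eff:
        raise ValueError("model size reaches the residual degrees of freedom")
    k, A = model_projection_stats(data, gamma)
    return -0.5 * k * data.q * np.log1p(g) - 0.5 * data.df * _logdet_S(data, A, g)


@dataclass(frozen=True)
class LogPosterior:
    value: float
    logML: float
    log_prior_gamma: float
    log_prior_g: float


def log_posterior(
    data: DataBundle,
    gamma: ModelIndicator,
    g: float,
    size_prior: ModelSizePrior,
    g_prior: GPriorSpec,
) -> LogPosterior:
    """Assemble logML + log prior(gamma) + log prior(g); -inf propagates
    from the model-size truncation."""
    lp_gamma = log_prior_model(gamma, size_prior)
    if lp_gamma == -np.inf:
        return LogPosterior(-np.inf, np.nan, -np.inf, np.nan)
    lml = log_marginal_likelihood(data, gamma, g)
    lp_g = log_prior_g(g, g_prior)
    return LogPosterior(lml + lp_gamma + lp_g, lml, lp_gamma, lp_g)
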
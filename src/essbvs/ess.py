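"""Evolutionary stochastic search over sparse multi-SNP models.

Several Markov chains run in parallel, chain l targeting the posterior
raised to the power 1/t_l on a geometric temperature ladder t_l =
b^(l-1) (chain 1 is the cold, untempered chain whose history feeds all
downstream summaries). Each sweep applies, per chain, a local
Fast-Scan Metropolis-Hastings pass of single-SNP add/delete flips, then
one global move — a uniform crossover of two chains' inclusion vectors
or a state exchange between temperature-adjacent chains — and finally a
random-walk update of the shrinkage coefficient g on the log scale.
Proposal probabilities never depend on the chain temperature, and any
proposal whose model size would exceed the prior truncation T is
rejected outright. The ladder base and the g step size adapt during
burn-in only (exchange acceptance steered into [0.2, 0.6], g acceptance
towards 0.35); both freeze afterwards so the post-burn-in kernel
satisfies detailed balance.

Implementation note: the local scan walks a random permutation of the
scanned SNP subset fixed before the scan, so each index is flip-proposed
at most once per sweep and the composed kernel is a valid systematic
scan. All candidate log-posterior increments (rank-one Cholesky updates
for adds, inverse-downdates for deletes) are computed in a handful of
BLAS calls against the current model's factors; because a rejected flip
leaves the state (and hence every other candidate's increment)
unchanged, the scan jumps directly to the first accepted candidate and
only then refreshes. The incremental quantities are rebuilt from
scratch at a fixed stride and the recorded log-posteriors are
reproducible from (gamma, g) by the likelihood module to tight
tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, inf, log, sqrt

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import gammaln, logsumexp

from .likelihood import DataBundle
from .priors import (
    GPriorSpec,
    ModelIndicator,
    ModelSizePrior,
    _log_betabinom_pmf_over_choose,
    log_prior_g,
)

__all__ = [
    "SamplerConfig",
    "ChainState",
    "McmcOutput",
    "SamplerState",
    "init_sampler",
    "fsmh_sweep",
    "crossover_move",
    "exchange_move",
    "update_g",
    "tune_temperature_ladder",
    "run",
]

_REBUILD_STRIDE = 100  # sweeps between from-scratch cache rebuilds
_RANK_RTOL = 1e-9  # relative tolerance declaring a candidate column dependent


@dataclass
class SamplerConfig:
    n_sweeps: int = 110_000
    burn_in: int = 10_000
    n_chains: int = 3
    seed: int = 0
    p_crossover: float = 0.5  # global move mix: crossover vs exchange
    g_step: float = 1.0  # initial RW sd on log g
    ladder_base: float = 1.5  # initial geometric ladder base b
    scan_fraction: float | None = None  # None: all SNPs if p<=1e4 else 0.25
    adapt_interval: int = 100

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_sweeps:
            raise ValueError("need 0 <= burn_in < n_sweeps")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.ladder_base <= 1:
            raise ValueError("ladder base must exceed 1")


class ChainState:
    """One tempered chain: model gamma, shrinkage g, temperature, and the
    Cholesky cache of the current model's independent columns."""

    def __init__(
        self,
        data: DataBundle,
        size_prior: ModelSizePrior,
        g_prior: GPriorSpec,
        indices: tuple[int, ...],
        g: float,
        temperature: float,
    ) -> None:
        self.data = data
        self.size_prior = size_prior
        self.g_prior = g_prior
        self.order: list[int] = list(indices)
        self.g = float(g)
        self.temperature = float(temperature)
        self.g_step = 1.0
        self.rebuild()

    # -- cached model quantities ------------------------------------------

    def rebuild(self) -> None:
        """Recompute basis Cholesky L, W = L^-1 Xb'Y and A = Y'H Y from
        scratch for the current column order.

        Fast path: one block Cholesky of the model's Gram matrix; falls
        back to column-by-column pivoted extension when the Gram is
        singular (collinear model columns)."""
        data = self.data
        q = data.q
        k = len(self.order)
        self.member = np.zeros(data.p, dtype=bool)
        if k:
            self.member[self.order] = True
        if k:
            if data.gram is not None:
                M = data.gram[np.ix_(self.order, self.order)]
            else:
                Xo = data.Xtilde[:, self.order]
                M = Xo.T @ Xo
            try:
                L = np.linalg.cholesky(M)
                if float(np.min(np.diag(L)) ** 2) > _RANK_RTOL * float(np.max(np.diag(M))):
                    self.L = L
                    self.W = solve_triangular(L, data.XtY[self.order], lower=True, check_finite=False)
                    self.basis = list(self.order)
                    self.A = self.W.T @ self.W
                    self._refresh_scores()
                    return
            except np.linalg.LinAlgError:
                pass
        self.basis = []
        self.L = np.zeros((0, 0))
        self.W = np.zeros((0, q))
        for j in self.order:
            self._try_extend_basis(j)
        self.A = self.W.T @ self.W
        self._refresh_scores()

    def _try_extend_basis(self, j: int) -> bool:
        data = self.data
        if self.basis:
            if data.gram is not None:
                v = data.gram[self.basis, j]
            else:
                v = data.Xtilde[:, self.basis].T @ data.Xtilde[:, j]
            l = solve_triangular(self.L, v, lower=True, check_finite=False)
            d2 = data.x_sq[j] - float(l @ l)
        else:
            l = np.zeros(0)
            d2 = data.x_sq[j]
        if d2 <= _RANK_RTOL * data.x_sq[j]:
            return False
        d = sqrt(d2)
        r = len(self.basis)
        L = np.zeros((r + 1, r + 1))
        L[:r, :r] = self.L
        L[r, :r] = l
        L[r, r] = d
        w = (data.XtY[j] - l @ self.W) / d
        self.L = L
        self.W = np.vstack([self.W, w[None, :]])
        self.basis.append(j)
        return True

    def _refresh_scores(self) -> None:
        """Recompute logML / log priors / tempered log-posterior from the
        cached (rank, A) and current g."""
        data = self.data
        h = self.g / (1.0 + self.g)
        S = data.YtY - h * self.A
        L_S = np.linalg.cholesky(S)  # LinAlgError signals a non-PD S
        logdet_S = 2.0 * float(np.log(np.diag(L_S)).sum())
        self._Sinv = np.linalg.inv(S)
        self.lml = -0.5 * self.rank * data.q * np.log1p(self.g) - 0.5 * data.df * logdet_S
        self.lp_gamma = _log_betabinom_pmf_over_choose(self.size, self.size_prior)
        self.lp_g = log_prior_g(self.g, self.g_prior)

    @property
    def rank(self) -> int:
        return len(self.basis)

    @property
    def size(self) -> int:
        return len(self.order)

    @property
    def log_posterior(self) -> float:
        return self.lml + self.lp_gamma + self.lp_g

    @property
    def gamma(self) -> ModelIndicator:
        return ModelIndicator(tuple(self.order))

    def set_model(self, indices: tuple[int, ...]) -> None:
        self.order = list(indices)
        self.rebuild()

    def set_g(self, g: float) -> None:
        self.g = float(g)
        self._refresh_scores()

    def _apply_add(self, j: int, l: np.ndarray, d2: float, w: np.ndarray | None) -> None:
        self.order.append(j)
        self.member[j] = True
        if w is not None:  # independent column: extend the basis
            d = sqrt(d2)
            r = len(self.basis)
            L = np.zeros((r + 1, r + 1))
            L[:r, :r] = self.L
            L[r, :r] = l
            L[r, r] = d
            self.L = L
            self.W = np.vstack([self.W, w[None, :]])
            self.basis.append(j)
            self.A = self.A + np.outer(w, w)
        self._refresh_scores()


def _size_log_pmf(size_prior: ModelSizePrior, k_max: int) -> np.ndarray:
    """Log pmf of the truncated model-size distribution on 0..k_max."""
    p = size_prior.p
    ks = np.arange(k_max + 1)
    log_choose = gammaln(p + 1) - gammaln(ks + 1) - gammaln(p - ks + 1)
    lw = np.array(
        [log_choose[k] + _log_betabinom_pmf_over_choose(int(k), size_prior) for k in ks]
    )
    return lw - logsumexp(lw)


@dataclass
class SamplerState:
    data: DataBundle
    size_prior: ModelSizePrior
    g_prior: GPriorSpec
    cfg: SamplerConfig
    chains: list[ChainState]
    chain_rngs: list[np.random.Generator]
    global_rng: np.random.Generator
    ladder_base: float
    counters: dict[str, int] = field(default_factory=dict)
    _window: dict[str, int] = field(default_factory=dict)
    adapting: bool = True

    def bump(self, key: str, accepted: bool) -> None:
        self.counters[f"{key}_proposed"] = self.counters.get(f"{key}_proposed", 0) + 1
        self._window[f"{key}_proposed"] = self._window.get(f"{key}_proposed", 0) + 1
        if accepted:
            self.counters[f"{key}_accepted"] = self.counters.get(f"{key}_accepted", 0) + 1
            self._window[f"{key}_accepted"] = self._window.get(f"{key}_accepted", 0) + 1

    def window_rate(self, key: str) -> float | None:
        prop = self._window.get(f"{key}_proposed", 0)
        if prop == 0:
            return None
        return self._window.get(f"{key}_accepted", 0) / prop

    def reset_window(self) -> None:
        self._window.clear()

    @property
    def temperatures(self) -> list[float]:
        return [c.temperature for c in self.chains]


def init_sampler(
    cfg: SamplerConfig,
    data: DataBundle,
    size_prior: ModelSizePrior,
    g_prior: GPriorSpec | None = None,
) -> SamplerState:
    """Initialise L chains with gamma drawn from the truncated size prior
    (then a uniform subset of that size) and g drawn from its prior."""
    g_prior = g_prior or GPriorSpec(data.n)
    k_cap = min(size_prior.T, data.n - data.c_eff - data.q - 1)
    if k_cap < 0 or size_prior.T >= data.n - data.c_eff - data.q:
        raise ValueError(
            "truncation T reaches the residual degrees of freedom: "
            "the marginal likelihood is undefined at permitted model sizes"
        )
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_chains + 2)
    chain_rngs = [np.random.default_rng(s) for s in children[: cfg.n_chains]]
    global_rng = np.random.default_rng(children[cfg.n_chains])
    init_rng = np.random.default_rng(children[cfg.n_chains + 1])

    log_pmf = _size_log_pmf(size_prior, size_prior.T)
    pmf = np.exp(log_pmf)
    chains = []
    for l in range(cfg.n_chains):
        k = int(init_rng.choice(size_prior.T + 1, p=pmf))
        k = min(k, k_cap)
        idx = tuple(sorted(init_rng.choice(data.p, size=k, replace=False)))
        g = 1.0 / init_rng.gamma(g_prior.shape, 1.0 / g_prior.rate)
        t = cfg.ladder_base ** l
        chains.append(ChainState(data, size_prior, g_prior, idx, g, t))
    for c in chains:
        c.g_step = cfg.g_step
    return SamplerState(
        data, size_prior, g_prior, cfg, chains, chain_rngs, global_rng, cfg.ladder_base
    )


# ---------------------------------------------------------------------------
# local moves


def _add_candidate_deltas(
    chain: ChainState, cand: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (delta log posterior numerator, independence flag) for
    adding each candidate column to the current model."""
    data = chain.data
    g, h = chain.g, chain.g / (1.0 + chain.g)
    if chain.rank:
        if data.gram is not None:
            V = data.gram[np.ix_(chain.basis, cand)]
        else:
            V = data.Xtilde[:, chain.basis].T @ data.Xtilde[:, cand]
        Lc = solve_triangular(chain.L, V, lower=True, check_finite=False)
        d2 = data.x_sq[cand] - np.einsum("ij,ij->j", Lc, Lc)
        U = data.XtY[cand] - Lc.T @ chain.W
    else:
        d2 = data.x_sq[cand].copy()
        U = data.XtY[cand].copy()
    indep = d2 > _RANK_RTOL * data.x_sq[cand]
    num = np.einsum("mq,mq->m", U @ chain._Sinv, U)
    u = np.zeros(len(cand))
    u[indep] = num[indep] / d2[indep]
    dlml = np.where(
        indep,
        -0.5 * data.q * np.log1p(g)
        - 0.5 * data.df * np.log(np.maximum(1.0 - h * u, 1e-300)),
        0.0,
    )
    k = chain.size
    if k + 1 > chain.size_prior.T or k + 1 >= data.n - data.c_eff:
        dlp = -inf
    else:
        dlp = _log_betabinom_pmf_over_choose(k + 1, chain.size_prior) - chain.lp_gamma
    return dlml + dlp, indep


def _delete_candidate_deltas(chain: ChainState) -> np.ndarray:
    """Vectorised delta log posterior numerator for deleting each model
    column, indexed by position in chain.basis (requires a full-rank
    model, basis == order).

    Uses the inverse-downdate identity: removing column c changes
    A = B'M^-1 B by -a_c a_c'/P_cc with P = M^-1, a_c = (P B)_c, so
    log det S increases by log(1 + h a_c' S^-1 a_c / P_cc).
    """
    data = chain.data
    g, h = chain.g, chain.g / (1.0 + chain.g)
    k = chain.rank
    Linv = solve_triangular(chain.L, np.eye(k), lower=True, check_finite=False)
    diagP = np.einsum("ij,ij->j", Linv, Linv)
    PB = Linv.T @ chain.W  # k x q rows a_c
    num = np.einsum("kq,kq->k", PB @ chain._Sinv, PB)
    dlml = 0.5 * data.q * np.log1p(g) - 0.5 * data.df * np.log1p(h * num / diagP)
    dlp = _log_betabinom_pmf_over_choose(chain.size - 1, chain.size_prior) - chain.lp_gamma
    return dlml + dlp


def _apply_add(state: SamplerState, ci: int, j: int) -> None:
    """Apply an accepted add of column j to chain ci's cache."""
    chain = state.chains[ci]
    data = state.data
    if chain.rank:
        if data.gram is not None:
            v = data.gram[chain.basis, j]
        else:
            v = data.Xtilde[:, chain.basis].T @ data.Xtilde[:, j]
        l = solve_triangular(chain.L, v, lower=True, check_finite=False)
        d2 = data.x_sq[j] - float(l @ l)
    else:
        l = np.zeros(0)
        d2 = data.x_sq[j]
    if d2 > _RANK_RTOL * data.x_sq[j]:
        w = (data.XtY[j] - l @ chain.W) / sqrt(d2)
        chain._apply_add(j, l, d2, w)
    else:
        chain._apply_add(j, np.zeros(0), 0.0, None)


def fsmh_sweep(state: SamplerState, ci: int) -> None:
    """One Fast-Scan MH pass over chain `ci`.

    A random permutation of the scanned SNP subset is fixed before the
    scan (independently of the chain state — a systematic scan, so the
    composed kernel preserves the tempered target); each index is then
    flip-proposed at most once: an add if currently excluded, a delete
    if included. Add acceptance probabilities are computed for the whole
    remaining scan in one vectorised pass and stay exact until the first
    acceptance, where the state (and the probabilities) are refreshed.
    """
    cfg = state.cfg
    data = state.data
    rng = state.chain_rngs[ci]
    chain = state.chains[ci]
    frac = cfg.scan_fraction
    if frac is None:
        frac = 1.0 if data.p <= 10_000 else 0.25
    idx = np.arange(data.p)
    if frac < 1.0:
        idx = idx[rng.random(data.p) < frac]
    perm = rng.permutation(idx)
    pos = 0
    while pos < perm.size:
        rest = perm[pos:]
        member = chain.member[rest]
        alpha = np.empty(rest.size)
        add_cand = rest[~member]
        if add_cand.size:
            delta_add, _ = _add_candidate_deltas(chain, add_cand)
            with np.errstate(over="ignore"):
                alpha[~member] = np.exp(np.minimum(delta_add / chain.temperature, 0.0))
        mem_pos = np.where(member)[0]
        if mem_pos.size:
            if chain.size == chain.rank:
                d_del = _delete_candidate_deltas(chain)
                for i in mem_pos:
                    c = chain.basis.index(int(rest[i]))
                    alpha[i] = exp(min(d_del[c] / chain.temperature, 0.0))
            else:  # redundant columns present: per-column probe fallback
                for i in mem_pos:
                    trial = list(chain.order)
                    trial.remove(int(rest[i]))
                    probe = ChainState(
                        data, state.size_prior, state.g_prior, tuple(trial),
                        chain.g, chain.temperature,
                    )
                    delta = (probe.lml - chain.lml) + (probe.lp_gamma - chain.lp_gamma)
                    alpha[i] = exp(min(delta / chain.temperature, 0.0))
        hits = rng.random(rest.size) < alpha
        if not hits.any():
            _count_scan(state, member, member.size)
            break
        i = int(np.argmax(hits))
        _count_scan(state, member, i)
        if member[i]:
            state.bump("delete", True)
            trial = list(chain.order)
            trial.remove(int(rest[i]))
            probe = ChainState(
                data, state.size_prior, state.g_prior, tuple(trial),
                chain.g, chain.temperature,
            )
            probe.g_step = chain.g_step
            state.chains[ci] = probe
            chain = probe
        else:
            state.bump("add", True)
            _apply_add(state, ci, int(rest[i]))
        pos += i + 1


def _count_scan(state: SamplerState, member: np.ndarray, upto: int) -> None:
    """Book-keep the rejected proposals preceding the first acceptance."""
    n_del = int(member[:upto].sum())
    state.counters["delete_proposed"] = state.counters.get("delete_proposed", 0) + n_del
    state.counters["add_proposed"] = state.counters.get("add_proposed", 0) + (upto - n_del)


# ---------------------------------------------------------------------------
# global moves


def _tempered_logpost(chain: ChainState) -> float:
    return chain.log_posterior / chain.temperature


def crossover_move(state: SamplerState) -> None:
    """Uniform crossover of two chains' inclusion vectors, accepted jointly
    under the two tempered targets (g stays with its chain)."""
    L = len(state.chains)
    if L < 2:
        return
    rng = state.global_rng
    i, j = sorted(rng.choice(L, size=2, replace=False))
    ci, cj = state.chains[i], state.chains[j]
    set_i, set_j = set(ci.order), set(cj.order)
    shared = set_i & set_j
    diff = sorted(set_i ^ set_j)
    mask = rng.random(len(diff)) < 0.5
    child_i, child_j = set(shared), set(shared)
    for take_i, idx in zip(mask, diff):
        (child_i if take_i else child_j).add(idx)
    o1, o2 = tuple(sorted(child_i)), tuple(sorted(child_j))
    T = state.size_prior.T
    cap = state.data.n - state.data.c_eff - 1
    if len(o1) > min(T, cap) or len(o2) > min(T, cap):
        state.bump("crossover", False)
        return
    p1 = ChainState(state.data, state.size_prior, state.g_prior, o1, ci.g, ci.temperature)
    p2 = ChainState(state.data, state.size_prior, state.g_prior, o2, cj.g, cj.temperature)
    delta = (
        _tempered_logpost(p1)
        + _tempered_logpost(p2)
        - _tempered_logpost(ci)
        - _tempered_logpost(cj)
    )
    accepted = log(rng.random()) < delta
    state.bump("crossover", accepted)
    if accepted:
        p1.g_step, p2.g_step = ci.g_step, cj.g_step
        state.chains[i], state.chains[j] = p1, p2


def exchange_move(state: SamplerState) -> None:
    """Swap the full (gamma, g) states of a temperature-adjacent chain pair
    with the standard parallel-tempering acceptance ratio."""
    L = len(state.chains)
    if L < 2:
        return
    rng = state.global_rng
    i = int(rng.integers(L - 1))
    j = i + 1
    ci, cj = state.chains[i], state.chains[j]
    delta = (1.0 / ci.temperature - 1.0 / cj.temperature) * (
        cj.log_posterior - ci.log_posterior
    )
    accepted = log(rng.random()) < delta
    state.bump("exchange", accepted)
    if accepted:
        ci.temperature, cj.temperature = cj.temperature, ci.temperature
        ci.g_step, cj.g_step = cj.g_step, ci.g_step
        state.chains[i], state.chains[j] = cj, ci
        # tempered scores are temperature-free caches; nothing to refresh


def update_g(state: SamplerState, ci: int) -> None:
    """Random-walk MH on log g for chain `ci`.

    The target is the tempered [marginal likelihood x inverse-gamma
    prior]; the log-scale proposal contributes the untempered Jacobian
    factor g'/g.
    """
    chain = state.chains[ci]
    rng = state.chain_rngs[ci]
    x = log(chain.g)
    x_new = x + chain.g_step * rng.standard_normal()
    if abs(x_new) > 700.0:  # overflow guard; such g has essentially zero density
        state.bump("g", False)
        return
    g_new = exp(x_new)
    h_new = g_new / (1.0 + g_new)
    S_new = state.data.YtY - h_new * chain.A
    sign, logdet_new = np.linalg.slogdet(S_new)
    if sign <= 0:
        state.bump("g", False)
        return
    lml_new = (
        -0.5 * chain.rank * state.data.q * np.log1p(g_new)
        - 0.5 * state.data.df * logdet_new
    )
    lp_g_new = log_prior_g(g_new, state.g_prior)
    delta = ((lml_new + lp_g_new) - (chain.lml + chain.lp_g)) / chain.temperature + (
        x_new - x
    )
    accepted = log(rng.random()) < delta
    state.bump("g", accepted)
    if accepted:
        chain.set_g(g_new)


def tune_temperature_ladder(state: SamplerState) -> None:
    """During burn-in, steer the geometric ladder base so the exchange
    acceptance rate lands in [0.2, 0.6]; no-op for a single chain."""
    if len(state.chains) < 2 or not state.adapting:
        return
    rate = state.window_rate("exchange")
    if rate is None:
        return
    b = state.ladder_base
    if rate < 0.2:
        b = max(1.0005, b ** (1.0 / 1.25))  # compress the ladder
    elif rate > 0.6:
        b = b ** 1.25
    state.ladder_base = b
    order = np.argsort([c.temperature for c in state.chains])
    for rank_pos, idx in enumerate(order):
        state.chains[idx].temperature = b ** rank_pos


def _tune_g_steps(state: SamplerState) -> None:
    rate = state.window_rate("g")
    if rate is None:
        return
    factor = exp(min(max(rate - 0.35, -0.25), 0.25))
    for c in state.chains:
        c.g_step = float(np.clip(c.g_step * factor, 1e-3, 10.0))


# ---------------------------------------------------------------------------
# driver


@dataclass
class McmcOutput:
    """Recorded history. Model-level records (`models`, `log_posteriors`,
    `g_values`, `sweeps`) cover every post-burn-in sweep of the cold
    chain; `traces` carries per-sweep log-posterior / model-size / g for
    all chains over the whole run."""

    models: list[tuple[int, ...]]
    log_posteriors: np.ndarray
    g_values: np.ndarray
    sweeps: np.ndarray
    traces: dict[str, np.ndarray]
    counters: dict[str, int]
    ladder: list[float]
    burn_in: int
    p: int
    snp_ids: list[str] | None = None

    @property
    def n_retained(self) -> int:
        return len(self.models)


def run(
    cfg: SamplerConfig,
    data: DataBundle,
    size_prior: ModelSizePrior,
    g_prior: GPriorSpec | None = None,
    snp_ids: list[str] | None = None,
) -> McmcOutput:
    """Run the full sampler and record history; deterministic given cfg.seed."""
    state = init_sampler(cfg, data, size_prior, g_prior)
    L = cfg.n_chains
    n_sw = cfg.n_sweeps
    tr_lp = np.empty((n_sw, L))
    tr_size = np.empty((n_sw, L), dtype=int)
    tr_g = np.empty((n_sw, L))
    models: list[tuple[int, ...]] = []
    lps: list[float] = []
    gs: list[float] = []
    sweeps: list[int] = []

    for sweep in range(n_sw):
        if sweep == cfg.burn_in:
            state.adapting = False
        for ci in range(L):
            fsmh_sweep(state, ci)
        if L >= 2:
            if state.global_rng.random() < cfg.p_crossover:
                crossover_move(state)
            else:
                exchange_move(state)
        for ci in range(L):
            update_g(state, ci)

        if state.adapting and (sweep + 1) % cfg.adapt_interval == 0:
            tune_temperature_ladder(state)
            _tune_g_steps(state)
            state.reset_window()
        if (sweep + 1) % _REBUILD_STRIDE == 0:
            for c in state.chains:
                c.rebuild()

        cold = min(range(L), key=lambda i: state.chains[i].temperature)
        for ci in range(L):
            tr_lp[sweep, ci] = state.chains[ci].log_posterior
            tr_size[sweep, ci] = state.chains[ci].size
            tr_g[sweep, ci] = state.chains[ci].g
        if sweep >= cfg.burn_in:
            c = state.chains[cold]
            models.append(tuple(sorted(c.order)))
            lps.append(c.log_posterior)
            gs.append(c.g)
            sweeps.append(sweep)

    return McmcOutput(
        models=models,
        log_posteriors=np.array(lps),
        g_values=np.array(gs),
        sweeps=np.array(sweeps, dtype=int),
        traces={"log_posterior": tr_lp, "model_size": tr_size, "g": tr_g},
        counters=dict(state.counters),
        ladder=sorted(c.temperature for c in state.chains),
        burn_in=cfg.burn_in,
        p=data.p,
        snp_ids=snp_ids,
    )
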
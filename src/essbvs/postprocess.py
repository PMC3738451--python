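"""Posterior summaries from the sampler history.

Two complementary views of the cold-chain history are produced: the
Best Models Visited (BMV) — unique models ranked by their renormalised
posterior mass (MPP) — and the per-SNP Marginal Posterior Probability
of Inclusion (MPPI), the model-averaged evidence that a single SNP
belongs in the regression. MPPI converts to a Bayes factor by dividing
the posterior inclusion odds by the prior odds pi/(1-pi) with
pi = E/p; dividing each SNP's BF by the group's BF at its empirical-FDR
MPPI threshold gives the Ratio of Bayes Factors (RBF), a baseline-
standardised measure comparable across trait groups that preserves the
within-group ranking exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .ess import McmcOutput

__all__ = [
    "BestModels",
    "MarginalSummary",
    "best_models",
    "compute_mppi",
    "bayes_factor_from_mppi",
    "bf_threshold",
    "rbf",
    "rank_groups_by_rbf",
    "diagnostics",
]


@dataclass
class BestModels:
    """Unique visited models ranked by MPP (descending; ties broken by
    lexicographic model), with cumulative mass."""

    table: pd.DataFrame  # columns: model, size, log_posterior, mpp, cum_mpp

    def top(self, k: int = 5) -> pd.DataFrame:
        return self.table.head(k)


def best_models(output: McmcOutput) -> BestModels:
    """Deduplicate the cold-chain history and renormalise.

    A model visited at several g values is scored by the largest
    recorded log-posterior (the MPP attaches to the model, not to a
    (model, g) pair); MPP_i = exp(score_i - logsumexp(scores)) over the
    unique visited models, so the MPPs sum to one by construction.
    """
    if output.n_retained == 0:
        raise ValueError("empty post-burn-in history")
    scores: dict[tuple[int, ...], float] = {}
    for gamma, lp in zip(output.models, output.log_posteriors):
        prev = scores.get(gamma)
        if prev is None or lp > prev:
            scores[gamma] = lp
    gammas = list(scores)
    lps = np.array([scores[g] for g in gammas])
    mpp = np.exp(lps - logsumexp(lps))
    order = sorted(range(len(gammas)), key=lambda i: (-mpp[i], gammas[i]))
    df = pd.DataFrame(
        {
            "model": [gammas[i] for i in order],
            "size": [len(gammas[i]) for i in order],
            "log_posterior": lps[order],
            "mpp": mpp[order],
        }
    )
    df["cum_mpp"] = df["mpp"].cumsum()
    return BestModels(df)


def compute_mppi(output: McmcOutput) -> np.ndarray:
    """MPPI_j = fraction of retained cold-chain sweeps whose model
    contains SNP j (empirical inclusion frequency, no Rao-
    Blackwellisation)."""
    if output.n_retained == 0:
        raise ValueError("empty post-burn-in history")
    counts = np.zeros(output.p)
    for gamma in output.models:
        counts[list(gamma)] += 1
    return counts / output.n_retained


def bayes_factor_from_mppi(
    mppi: np.ndarray | float, pi_avg: float, eps: float
) -> tuple[np.ndarray, np.ndarray]:
    """BF = posterior inclusion odds / prior odds.

    The MPPI m is clipped to [eps, 1-eps] before forming the odds so
    that SNPs included in every (or no) retained sweep get a finite BF;
    eps should be the resolution of the frequency estimator,
    1/(10 * retained sweeps). Returns (BF, log10 BF); display layers
    conventionally truncate log10 BF at 20 for readability.
    """
    if not 0 < pi_avg < 1:
        raise ValueError("pi_avg must lie in (0, 1)")
    m = np.clip(np.asarray(mppi, dtype=float), eps, 1.0 - eps)
    bf = (m / (1.0 - m)) / (pi_avg / (1.0 - pi_avg))
    return bf, np.log10(bf)


def bf_threshold(mppi_threshold: float, pi_avg: float) -> float:
    """The group's empirical-FDR MPPI threshold mapped onto the BF scale
    by the same odds-ratio transform (no clipping: the threshold is an
    observed MPPI value in (0, 1))."""
    m = mppi_threshold
    if not 0 < m < 1:
        raise ValueError("mppi_threshold must lie in (0, 1)")
    return (m / (1.0 - m)) / (pi_avg / (1.0 - pi_avg))


def rbf(bf: np.ndarray | float, bf_thr: float) -> np.ndarray | float:
    """Ratio of Bayes Factors: BF rescaled by the group's FDR baseline.

    RBF >= 1 exactly for SNPs declared significant (their MPPI, hence
    BF, is at or above the group threshold), and the transform is a
    positive scalar multiple so within-group BF ranks are untouched.
    """
    if bf_thr <= 0:
        raise ValueError("bf_threshold must be positive")
    return np.asarray(bf, dtype=float) / bf_thr if np.ndim(bf) else bf / bf_thr


@dataclass
class MarginalSummary:
    """Per-SNP marginal summary for one trait group."""

    group: str
    snp_ids: list[str]
    mppi: np.ndarray
    bf: np.ndarray
    log10_bf: np.ndarray
    mppi_threshold: float  # +inf when nothing is declarable at the FDR level
    bf_thr: float  # +inf likewise
    rbf: np.ndarray
    significant: np.ndarray
    cardinality: int = 1

    @classmethod
    def from_mppi(
        cls,
        group: str,
        snp_ids: list[str],
        mppi: np.ndarray,
        pi_avg: float,
        n_retained: int,
        mppi_threshold: float,
        cardinality: int = 1,
    ) -> "MarginalSummary":
        eps = 1.0 / (10.0 * n_retained)
        bf, l10 = bayes_factor_from_mppi(mppi, pi_avg, eps)
        if np.isfinite(mppi_threshold):
            thr = bf_threshold(min(mppi_threshold, 1.0 - eps), pi_avg)
            rb = np.asarray(rbf(bf, thr))
            sig = mppi >= mppi_threshold
        else:
            thr = np.inf
            rb = np.zeros_like(bf)
            sig = np.zeros(len(bf), dtype=bool)
        return cls(group, list(snp_ids), mppi, bf, l10, mppi_threshold, thr, rb, sig, cardinality)

    def to_frame(self, snp_map: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "mppi": self.mppi,
                "log10_bf": self.log10_bf,
                "log10_rbf": np.where(self.rbf > 0, np.log10(np.maximum(self.rbf, 1e-300)), -np.inf),
                "significant": self.significant,
            }
        )
        if snp_map is not None:
            df.insert(1, "chromosome", snp_map.reindex(self.snp_ids)["chromosome"].to_numpy())
            df.insert(2, "position", snp_map.reindex(self.snp_ids)["position"].to_numpy())
        return df


def rank_groups_by_rbf(
    snp_id: str, summaries: list[MarginalSummary]
) -> list[tuple[str, float]]:
    """Order trait groups by their RBF for one SNP, strongest first.

    Ties break by larger group cardinality, then by group name. Groups
    whose panel lacks the SNP are skipped with a warning.
    """
    import warnings

    rows = []
    for s in summaries:
        if snp_id not in s.snp_ids:
            warnings.warn(f"SNP {snp_id} absent from group {s.group}; omitted")
            continue
        j = s.snp_ids.index(snp_id)
        rows.append((s.group, float(np.asarray(s.rbf)[j]), s.cardinality))
    rows.sort(key=lambda r: (-r[1], -r[2], r[0]))
    return [(g, v) for g, v, _ in rows]


def diagnostics(output: McmcOutput) -> dict[str, pd.DataFrame]:
    """Trace tables for convergence checks: log-posterior, model size and
    g (plus the shrinkage factor g/(1+g)) for every chain and sweep,
    the burn-in boundary, and the first-visit sweep of each top model."""
    n_sw, L = output.traces["log_posterior"].shape
    frames: dict[str, pd.DataFrame] = {}
    for key in ("log_posterior", "model_size", "g"):
        frames[key] = pd.DataFrame(
            output.traces[key], columns=[f"chain{l+1}" for l in range(L)]
        )
        frames[key].index.name = "sweep"
    shr = output.traces["g"] / (1.0 + output.traces["g"])
    frames["shrinkage"] = pd.DataFrame(
        shr, columns=[f"chain{l+1}" for l in range(L)]
    )
    frames["shrinkage"].index.name = "sweep"

    bm = best_models(output)
    first_visit = {}
    for gamma in bm.table["model"].head(5):
        for sw, g2 in zip(output.sweeps, output.models):
            if g2 == gamma:
                first_visit[gamma] = int(sw)
                break
    frames["first_visit"] = pd.DataFrame(
        {
            "model": list(first_visit),
            "first_visit_sweep": list(first_visit.values()),
            "burn_in": output.burn_in,
        }
    )
    return frames
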
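"""End-to-end analysis drivers.

These functions tie the pieces together the way a study would run them:
`run_analysis` takes a genotype panel, one trait group and covariates
through preprocessing, the stochastic search and posterior summaries;
`run_fdr_calibration` adds the trait-permutation null runs and the
empirical-FDR threshold; `run_tree` analyses every branch of a trait-
group tree (all non-empty subsets by default), pools null MPPI across
branches of equal cardinality, and assembles the combined summary table
(top-model MPP, cumulative top-5 MPP, per-SNP log10 RBF, significance
and best-model flags per branch). Everything is seeded and a manifest
captures enough to re-execute a run bit-identically.
"""

from __future__ import annotations

import hashlib
import itertools
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_io import (
    CovariateMatrix,
    GenotypeMatrix,
    TraitMatrix,
    adjust_for_covariates,
    inverse_normal_transform,
)
from .ess import McmcOutput, SamplerConfig, run
from .fdr import FdrConfig, NullPool, declare_significant, mppi_threshold, permute_traits
from .likelihood import DataBundle
from .postprocess import BestModels, MarginalSummary, best_models, compute_mppi
from .priors import GPriorSpec, ModelSizePrior, make_size_prior

__all__ = [
    "PriorConfig",
    "AnalysisResult",
    "prepare_bundle",
    "run_analysis",
    "run_fdr_calibration",
    "run_tree",
    "TreeResult",
    "write_replicates",
]


@dataclass
class PriorConfig:
    E: float = 2.0
    S: float = 2.0
    F: float = 7.0

    def build(self, p: int) -> ModelSizePrior:
        return make_size_prior(self.E, self.S, self.F, p)


def prepare_bundle(
    G: GenotypeMatrix,
    Y: TraitMatrix,
    C: CovariateMatrix | None = None,
    quantile_transform: bool = True,
) -> DataBundle:
    """Inverse-normal transform each trait, project out [1, C], bundle."""
    vals = Y.values
    if quantile_transform:
        vals = np.column_stack([inverse_normal_transform(vals[:, t]) for t in range(Y.q)])
        Y = TraitMatrix(vals, list(Y.trait_names))
    Ytil, Xtil, c_eff = adjust_for_covariates(Y, G, C)
    return DataBundle(Ytil, Xtil, c_eff)


@dataclass
class AnalysisResult:
    group: str
    output: McmcOutput
    bmv: BestModels
    mppi: np.ndarray
    size_prior: ModelSizePrior
    snp_ids: list[str]
    manifest: dict = field(default_factory=dict)

    def summary(self, m_star: float = np.inf, cardinality: int = 1) -> MarginalSummary:
        return MarginalSummary.from_mppi(
            self.group,
            self.snp_ids,
            self.mppi,
            self.size_prior.pi_avg,
            self.output.n_retained,
            m_star,
            cardinality,
        )


def _checksum(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def run_analysis(
    G: GenotypeMatrix,
    Y: TraitMatrix,
    C: CovariateMatrix | None = None,
    prior: PriorConfig | None = None,
    sampler: SamplerConfig | None = None,
    group: str | None = None,
    quantile_transform: bool = True,
    out_dir: str | Path | None = None,
) -> AnalysisResult:
    """Preprocess -> stochastic search -> posterior summaries for one
    trait group; optionally writes history / BMV / MPPI tables."""
    t0 = time.time()
    prior = prior or PriorConfig()
    sampler = sampler or SamplerConfig()
    group = group or "-".join(Y.trait_names)
    data = prepare_bundle(G, Y, C, quantile_transform)
    size_prior = prior.build(data.p)
    output = run(sampler, data, size_prior, GPriorSpec(data.n), snp_ids=G.snp_ids)
    bmv = best_models(output)
    mppi = compute_mppi(output)
    manifest = {
        "group": group,
        "seed": sampler.seed,
        "n": data.n,
        "p": data.p,
        "q": data.q,
        "c_eff": data.c_eff,
        "prior": {"E": prior.E, "S": prior.S, "F": prior.F, "T": size_prior.T},
        "sampler": {
            "n_sweeps": sampler.n_sweeps,
            "burn_in": sampler.burn_in,
            "n_chains": sampler.n_chains,
        },
        "version": __version__,
        "input_checksum": _checksum(G.imputed(), Y.values),
        "wall_clock_s": None,
    }
    manifest["wall_clock_s"] = round(time.time() - t0, 3)
    result = AnalysisResult(group, output, bmv, mppi, size_prior, list(G.snp_ids), manifest)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: AnalysisResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    out = result.output
    hist = pd.DataFrame(
        {
            "sweep": out.sweeps,
            "chain": 1,
            "temperature": 1.0,
            "model_size": [len(m) for m in out.models],
            "log_posterior": out.log_posteriors,
            "g": out.g_values,
            "model": [" ".join(result.snp_ids[j] for j in m) for m in out.models],
        }
    )
    hist.to_csv(out_dir / f"{result.group}_history.tsv", sep="\t", index=False)
    bmv = result.bmv.table.copy()
    bmv["model"] = bmv["model"].map(lambda m: " ".join(result.snp_ids[j] for j in m))
    bmv.to_csv(out_dir / f"{result.group}_bmv.tsv", sep="\t", index=False)
    result.summary().to_frame().to_csv(
        out_dir / f"{result.group}_mppi.tsv", sep="\t", index=False
    )
    pd.Series(result.manifest).to_json(out_dir / f"{result.group}_manifest.json")


def run_fdr_calibration(
    G: GenotypeMatrix,
    Y: TraitMatrix,
    C: CovariateMatrix | None = None,
    prior: PriorConfig | None = None,
    sampler: SamplerConfig | None = None,
    fdr: FdrConfig | None = None,
    quantile_transform: bool = True,
) -> tuple[AnalysisResult, MarginalSummary, NullPool]:
    """Observed run plus K trait-permuted null runs and the empirical-FDR
    MPPI threshold for one trait group."""
    fdr = fdr or FdrConfig()
    sampler = sampler or SamplerConfig()
    observed = run_analysis(G, Y, C, prior, sampler, quantile_transform=quantile_transform)
    pool = NullPool(cardinality=Y.q)
    for k, Yp in enumerate(permute_traits(Y, fdr.K, fdr.seed)):
        null_sampler = SamplerConfig(
            n_sweeps=sampler.n_sweeps,
            burn_in=sampler.burn_in,
            n_chains=sampler.n_chains,
            seed=sampler.seed + 1_000_003 * (k + 1),
            p_crossover=sampler.p_crossover,
            g_step=sampler.g_step,
            ladder_base=sampler.ladder_base,
            scan_fraction=sampler.scan_fraction,
            adapt_interval=sampler.adapt_interval,
        )
        null_res = run_analysis(G, Yp, C, prior, null_sampler,
                                quantile_transform=quantile_transform)
        pool.add(null_res.mppi)
    m_star = mppi_threshold(observed.mppi, pool, fdr.alpha)
    summary = observed.summary(m_star, cardinality=Y.q)
    return observed, summary, pool


@dataclass
class TreeResult:
    branches: dict[str, AnalysisResult]
    summaries: dict[str, MarginalSummary]
    pools: dict[int, NullPool]
    thresholds: dict[str, float]
    table: pd.DataFrame  # combined per-branch summary
    fdr_report: pd.DataFrame


def _all_subsets(names: list[str]) -> list[tuple[str, ...]]:
    out = []
    for r in range(1, len(names) + 1):
        out.extend(itertools.combinations(names, r))
    return out


def run_tree(
    G: GenotypeMatrix,
    Y: TraitMatrix,
    C: CovariateMatrix | None = None,
    groups: list[tuple[str, ...]] | None = None,
    prior: PriorConfig | None = None,
    sampler: SamplerConfig | None = None,
    fdr: FdrConfig | None = None,
    pool_by_cardinality: bool = True,
    quantile_transform: bool = True,
) -> TreeResult:
    """Analyse every branch of a trait-group tree with pooled empirical-
    FDR calibration.

    `groups` defaults to all non-empty subsets of the traits (the full
    top-down tree: q singletons, pairs, ..., one q-tuple). Null MPPI
    are pooled across branches of the same cardinality before the
    threshold search, which is how the tail of the null gets enough
    mass to be estimated.
    """
    fdr = fdr or FdrConfig()
    sampler = sampler or SamplerConfig()
    if groups is None:
        groups = _all_subsets(list(Y.trait_names))
    for grp in groups:
        unknown = set(grp) - set(Y.trait_names)
        if unknown:
            raise ValueError(f"unknown trait name(s): {sorted(unknown)}")

    branches: dict[str, AnalysisResult] = {}
    null_mppi: dict[str, list[np.ndarray]] = {}
    for gi, grp in enumerate(groups):
        name = "-".join(grp)
        Yg = Y.subset(list(grp))
        br_sampler = SamplerConfig(
            n_sweeps=sampler.n_sweeps, burn_in=sampler.burn_in,
            n_chains=sampler.n_chains, seed=sampler.seed + 7919 * gi,
            p_crossover=sampler.p_crossover, g_step=sampler.g_step,
            ladder_base=sampler.ladder_base, scan_fraction=sampler.scan_fraction,
            adapt_interval=sampler.adapt_interval,
        )
        branches[name] = run_analysis(G, Yg, C, prior, br_sampler, group=name,
                                      quantile_transform=quantile_transform)
        nulls = []
        for k, Yp in enumerate(permute_traits(Yg, fdr.K, fdr.seed + gi)):
            null_sampler = SamplerConfig(
                n_sweeps=sampler.n_sweeps, burn_in=sampler.burn_in,
                n_chains=sampler.n_chains,
                seed=sampler.seed + 7919 * gi + 1_000_003 * (k + 1),
                p_crossover=sampler.p_crossover, g_step=sampler.g_step,
                ladder_base=sampler.ladder_base, scan_fraction=sampler.scan_fraction,
                adapt_interval=sampler.adapt_interval,
            )
            nulls.append(
                run_analysis(G, Yp, C, prior, null_sampler,
                             quantile_transform=quantile_transform).mppi
            )
        null_mppi[name] = nulls

    pools: dict[int, NullPool] = {}
    for grp in groups:
        name = "-".join(grp)
        card = len(grp)
        key = card if pool_by_cardinality else name
        if key not in pools:
            pools[key] = NullPool(cardinality=card)
        for m in null_mppi[name]:
            pools[key].add(m)

    summaries: dict[str, MarginalSummary] = {}
    thresholds: dict[str, float] = {}
    fdr_rows = []
    for grp in groups:
        name = "-".join(grp)
        card = len(grp)
        pool = pools[card if pool_by_cardinality else name]
        m_star = mppi_threshold(branches[name].mppi, pool, fdr.alpha, K=pool.n_source_runs)
        thresholds[name] = m_star
        summaries[name] = branches[name].summary(m_star, cardinality=card)
        fdr_rows.append(
            {
                "group": name,
                "cardinality": card,
                "null_pool_size": pool.size,
                "mppi_threshold": m_star,
                "n_significant": int(declare_significant(branches[name].mppi, m_star).sum()),
            }
        )

    rows = []
    for grp in groups:
        name = "-".join(grp)
        res, summ = branches[name], summaries[name]
        top = res.bmv.table
        top_model = set(top["model"].iloc[0])
        row = {
            "group": name,
            "cardinality": len(grp),
            "top_bmv_mpp": float(top["mpp"].iloc[0]),
            "cum_top5_mpp": float(top["mpp"].head(5).sum()),
        }
        for j, sid in enumerate(res.snp_ids):
            if summ.significant[j]:
                l10 = float(np.log10(max(summ.rbf[j], 1e-300)))
                row[f"log10_rbf:{sid}"] = min(l10, 20.0)  # display truncation
                row[f"in_top_bmv:{sid}"] = j in top_model
        rows.append(row)
    table = pd.DataFrame(rows)
    return TreeResult(branches, summaries, pools, thresholds, table, pd.DataFrame(fdr_rows))


def write_replicates(scenario, out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write a scenario's replicates to disk in the package's text
    formats (genotypes, phenotypes, map, truth table)."""
    from .simulate import make_replicate

    out_dir = Path(out_dir)
    paths = []
    for r in range(scenario.n_replicates):
        rep = make_replicate(scenario, seed=seed + r)
        d = out_dir / f"{scenario.name}_rep{r+1:02d}"
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(rep.G.values, columns=rep.G.snp_ids).to_csv(
            d / "genotypes.tsv", sep="\t", index=False
        )
        pd.DataFrame(rep.Y.values, columns=rep.Y.trait_names).to_csv(
            d / "phenotypes.tsv", sep="\t", index=False
        )
        rep.G.map.reset_index().to_csv(d / "map.tsv", sep="\t", index=False, header=False)
        truth = pd.DataFrame(
            [
                {"snp_id": rep.G.snp_ids[j], "trait": rep.Y.trait_names[t],
                 "effect": rep.B[i, t]}
                for i, j in enumerate(rep.truth)
                for t in range(rep.B.shape[1])
            ]
        )
        truth.to_csv(d / "truth.tsv", sep="\t", index=False)
        paths.append(d)
    return paths
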
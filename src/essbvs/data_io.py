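"""Genotype/phenotype containers, file readers and preprocessing.

Preprocessing mirrors the standard GWAS pipeline for a multi-trait
Bayesian variable-selection run: marker quality control (minor allele
frequency and Hardy-Weinberg filters), greedy tag-SNP selection at an
r-squared threshold, per-trait inverse-normal (Blom) quantile
transformation, and removal of fixed covariates by orthogonal projection
so the search itself only ever sees covariate-adjusted residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "TraitMatrix",
    "CovariateMatrix",
    "QCConfig",
    "QCReport",
    "qc_filter",
    "greedy_tag",
    "inverse_normal_transform",
    "adjust_for_covariates",
    "read_genotypes",
    "read_plink_raw",
    "read_table",
    "read_snp_map",
]


@dataclass
class GenotypeMatrix:
    """n x p additive-coded genotypes (0/1/2 copies of the minor allele).

    Missing entries are ``nan``. ``map`` is an optional DataFrame indexed
    by SNP id with columns ``chromosome`` and ``position`` (1-based bp).
    """

    values: np.ndarray
    snp_ids: list[str]
    map: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D (individuals x SNPs)")
        if len(self.snp_ids) != self.values.shape[1]:
            raise ValueError("snp_ids length does not match number of columns")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing genotypes must be coded 0/1/2")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def subset(self, cols: Sequence[int]) -> "GenotypeMatrix":
        cols = list(cols)
        ids = [self.snp_ids[j] for j in cols]
        m = self.map.loc[ids] if self.map is not None else None
        return GenotypeMatrix(self.values[:, cols], ids, m)

    def imputed(self) -> np.ndarray:
        """Values with missing entries replaced by the per-SNP mean.

        The original code base phased/imputed missing calls upstream;
        mean imputation is the desk-scale fallback. A warning reports the
        imputed fraction when any entry is missing.
        """
        vals = self.values
        miss = ~np.isfinite(vals)
        if not miss.any():
            return vals.copy()
        frac = miss.mean()
        warnings.warn(
            f"mean-imputing {frac:.2%} missing genotype entries", stacklevel=2
        )
        out = vals.copy()
        col_mean = np.nanmean(vals, axis=0)
        idx = np.where(miss)
        out[idx] = col_mean[idx[1]]
        return out


@dataclass
class TraitMatrix:
    """n x q continuous phenotypes for one trait group."""

    values: np.ndarray
    trait_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if len(self.trait_names) != self.values.shape[1]:
            raise ValueError("trait_names length does not match columns")
        if self.values.shape[1] < 1:
            raise ValueError("need at least one trait")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return self.values.shape[1]

    def subset(self, names: Sequence[str]) -> "TraitMatrix":
        cols = [self.trait_names.index(nm) for nm in names]
        return TraitMatrix(self.values[:, cols], list(names))


@dataclass
class CovariateMatrix:
    """n x c fixed covariates (e.g. sex, age, body mass index)."""

    values: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            self.values = self.values.reshape(self.values.shape[0], 0)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if not self.names:
            self.names = [f"cov{i+1}" for i in range(self.values.shape[1])]

    @property
    def c(self) -> int:
        return self.values.shape[1]


@dataclass
class QCConfig:
    maf_min: float = 0.01
    hwe_p_min: float = 1e-4
    tag_r2: float = 0.80

    def __post_init__(self) -> None:
        if not 0 < self.maf_min < 0.5:
            raise ValueError("maf_min must lie in (0, 0.5)")
        if not 0 < self.hwe_p_min < 1:
            raise ValueError("hwe_p_min must lie in (0, 1)")
        if not 0 < self.tag_r2 <= 1:
            raise ValueError("tag_r2 must lie in (0, 1]")


@dataclass
class QCReport:
    kept: list[str]
    dropped: dict[str, str]  # snp_id -> reason


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    ok = col[np.isfinite(col)]
    return int((ok == 0).sum()), int((ok == 1).sum()), int((ok == 2).sum())


def hwe_chisq_p(n0: int, n1: int, n2: int) -> float:
    """One-degree-of-freedom chi-square Hardy-Weinberg test p-value.

    Expected genotype counts under HWE are derived from the observed
    allele frequency; no continuity correction.
    """
    n = n0 + n1 + n2
    if n == 0:
        return np.nan
    f = (2 * n2 + n1) / (2 * n)  # minor-allele-2 frequency
    exp = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2]) * n
    obs = np.array([n0, n1, n2], dtype=float)
    mask = exp > 0
    chi2 = float(((obs[mask] - exp[mask]) ** 2 / exp[mask]).sum())
    return float(stats.chi2.sf(chi2, df=1))


def qc_filter(G: GenotypeMatrix, cfg: QCConfig | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Drop SNPs with MAF < maf_min, HWE p < hwe_p_min, or monomorphic.

    Exclusion is strict (< threshold), so a SNP sitting exactly on the
    printed MAF cutoff is retained. Missing genotypes are ignored in the
    counts. Column order of the retained panel is preserved.
    """
    cfg = cfg or QCConfig()
    keep: list[int] = []
    dropped: dict[str, str] = {}
    for j in range(G.p):
        n0, n1, n2 = _genotype_counts(G.values[:, j])
        n = n0 + n1 + n2
        if n == 0:
            dropped[G.snp_ids[j]] = "all missing"
            continue
        f = (2 * n2 + n1) / (2 * n)
        maf = min(f, 1 - f)
        if maf == 0:
            dropped[G.snp_ids[j]] = "monomorphic"
            continue
        if maf < cfg.maf_min:
            dropped[G.snp_ids[j]] = f"MAF {maf:.4g} < {cfg.maf_min}"
            continue
        p_hwe = hwe_chisq_p(n0, n1, n2)
        if p_hwe < cfg.hwe_p_min:
            dropped[G.snp_ids[j]] = f"HWE p {p_hwe:.3g} < {cfg.hwe_p_min}"
            continue
        keep.append(j)
    if not keep:
        raise ValueError("empty panel: quality control dropped every SNP")
    kept_ids = [G.snp_ids[j] for j in keep]
    return G.subset(keep), QCReport(kept_ids, dropped)


def greedy_tag(
    G: GenotypeMatrix, r2: float = 0.80
) -> tuple[GenotypeMatrix, dict[str, str]]:
    """Greedy maximum-coverage tag-SNP selection at squared correlation > r2.

    Repeatedly picks the SNP covering the largest number of yet-uncovered
    SNPs (a SNP covers itself and every SNP correlated with it at
    r-squared strictly above the threshold), ties broken by lower column
    index. Returns the retained tag panel plus a map from every input SNP
    id to its assigned tag.
    """
    X = G.imputed()
    p = G.p
    sd = X.std(axis=0)
    if (sd == 0).any():
        raise ValueError("constant genotype column: run qc_filter first")
    Z = (X - X.mean(axis=0)) / sd
    R2 = (Z.T @ Z / G.n) ** 2
    covers = R2 > r2
    np.fill_diagonal(covers, True)

    uncovered = np.ones(p, dtype=bool)
    tags: list[int] = []
    assignment: dict[str, str] = {}
    while uncovered.any():
        gain = (covers & uncovered[None, :]).sum(axis=1)
        t = int(np.argmax(gain))  # argmax takes the lowest index on ties
        tags.append(t)
        newly = covers[t] & uncovered
        for j in np.where(newly)[0]:
            assignment[G.snp_ids[j]] = G.snp_ids[t]
        uncovered &= ~newly
    tags.sort()
    return G.subset(tags), assignment


def inverse_normal_transform(y: np.ndarray) -> np.ndarray:
    """Blom-offset normal quantile transform: Phi^-1((rank - 3/8)/(n + 1/4)).

    Ties receive average ranks; the output is strictly monotone in the
    input ranks. Raises for all-equal input, where the transform is
    undefined.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("expected a 1-D trait vector")
    n = y.size
    if n < 2:
        raise ValueError("need at least two observations")
    if np.all(y == y[0]):
        raise ValueError("all-equal input: quantile transform undefined")
    ranks = stats.rankdata(y, method="average")
    return stats.norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))


def adjust_for_covariates(
    Y: TraitMatrix, G: GenotypeMatrix, C: CovariateMatrix | None = None
) -> tuple[np.ndarray, np.ndarray, int]:
    """Project traits and genotypes onto the orthogonal complement of [1, C].

    Returns (Ytilde, Xtilde, c_eff) where c_eff = 1 + c counts the
    projected-out columns; it must be carried into the marginal
    likelihood's degrees of freedom so that results match the
    formulation with always-included covariates exactly.
    """
    n = Y.n
    if G.n != n:
        raise ValueError("genotype and trait row counts differ")
    cov = C.values if C is not None else np.empty((n, 0))
    if cov.shape[0] != n:
        raise ValueError("covariate row count differs from traits")
    D = np.column_stack([np.ones(n), cov])
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        names = ["intercept"] + (C.names if C is not None else [])
        bad = []
        for j in range(1, D.shape[1]):
            if np.linalg.matrix_rank(D[:, : j + 1]) <= np.linalg.matrix_rank(D[:, :j]):
                bad.append(names[j])
        raise ValueError(f"collinear covariate columns: {bad}")
    Q, _ = np.linalg.qr(D)
    X = G.imputed()
    Ytil = Y.values - Q @ (Q.T @ Y.values)
    Xtil = X - Q @ (Q.T @ X)
    return Ytil, Xtil, D.shape[1]


# ---------------------------------------------------------------------------
# readers


def read_genotypes(path, map_path=None) -> GenotypeMatrix:
    """Whitespace/tab-delimited genotypes: header of SNP ids, one row per
    individual, NA for missing."""
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    snp_map = read_snp_map(map_path) if map_path is not None else None
    return GenotypeMatrix(df.to_numpy(dtype=float), list(df.columns), snp_map)


_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_plink_raw(path, map_path=None) -> GenotypeMatrix:
    """PLINK RAW additive dialect (``--recode A``-style columns)."""
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    missing = [c for c in _PLINK_META if c not in df.columns]
    if missing:
        raise ValueError(f"not PLINK RAW: missing columns {missing}")
    snp_cols = [c for c in df.columns if c not in _PLINK_META]
    # SNP columns are named id_allele; strip the counted-allele suffix
    ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    snp_map = read_snp_map(map_path) if map_path is not None else None
    return GenotypeMatrix(df[snp_cols].to_numpy(dtype=float), ids, snp_map)


def read_table(path, kind: str = "trait") -> TraitMatrix | CovariateMatrix:
    """Tab-delimited phenotype or covariate table with a header row."""
    df = pd.read_csv(path, sep=r"\s+")
    if kind == "trait":
        return TraitMatrix(df.to_numpy(dtype=float), list(df.columns))
    if kind == "covariate":
        return CovariateMatrix(df.to_numpy(dtype=float), list(df.columns))
    raise ValueError("kind must be 'trait' or 'covariate'")


def read_snp_map(path) -> pd.DataFrame:
    """Three-column tab-delimited map: snp_id, chromosome, position (1-based)."""
    df = pd.read_csv(
        path, sep=r"\s+", header=None, names=["snp_id", "chromosome", "position"]
    )
    return df.set_index("snp_id")
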
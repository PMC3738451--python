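"""Permutation-calibrated significance for inclusion probabilities.

Runs the observed analysis plus K=3 trait-row-permuted null analyses,
pools the null MPPI values, and derives the MPPI threshold whose
estimated false discovery rate is at most 5%.
"""

import numpy as np

from essbvs import (
    FdrConfig,
    PriorConfig,
    run_fdr_calibration,
    simulate_genotypes,
    simulate_traits,
)
from essbvs.ess import SamplerConfig

G = simulate_genotypes(n=250, p=80, seed=11)
B = np.array([[0.6, 0.5], [0.5, 0.6]])
R = np.array([[1.0, 0.5], [0.5, 1.0]])
Y = simulate_traits(G, causal=[5, 30], B=B, R=R, sigma=np.ones(2), seed=12)

observed, summary, pool = run_fdr_calibration(
    G,
    Y,
    prior=PriorConfig(E=2, S=2, F=7),
    sampler=SamplerConfig(n_sweeps=2500, burn_in=400, n_chains=3, seed=13),
    fdr=FdrConfig(K=3, alpha=0.01, seed=14),
)

print(f"null pool size          : {pool.size} ({pool.n_source_runs} permuted runs)")
print(f"MPPI threshold m*       : {summary.mppi_threshold:.4f}")
print(f"BF threshold            : {summary.bf_thr:.1f}")
print(f"SNPs declared at 1% FDR : {int(summary.significant.sum())}")
for j in np.where(summary.significant)[0]:
    print(
        f"  {summary.snp_ids[j]:>10s}  MPPI {summary.mppi[j]:.3f}  "
        f"log10 BF {summary.log10_bf[j]:6.2f}  RBF {summary.rbf[j]:8.1f}"
    )

print(
    "\nDeclared SNPs have MPPI above the smallest level at which permuted "
    "traits produce at most 1% as many exceedances per dataset as the "
    "observed traits; their RBF >= 1 by construction. The two causal SNPs "
    "(snp000006, snp000031) should lead; on a panel this small the noise "
    "floor of the MPPI makes an occasional borderline declaration "
    "unavoidable — the production design calibrates on 273k SNPs."
)
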
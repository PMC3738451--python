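"""Analysing a tree of trait groups and ranking them per SNP.

Every non-empty subset of three traits (7 branches: 3 singletons,
3 pairs, 1 triplet) is analysed separately; null MPPI values are pooled
across branches of equal cardinality for the FDR calibration, and the
Ratio of Bayes Factors makes the strength of one SNP's association
comparable across branches.
"""

import numpy as np

from essbvs import (
    FdrConfig,
    PriorConfig,
    rank_groups_by_rbf,
    run_tree,
    simulate_genotypes,
    simulate_traits,
)
from essbvs.ess import SamplerConfig

G = simulate_genotypes(n=250, p=30, seed=21)
# one SNP drives traits 1 and 2; a second drives trait 3 only
B = np.array([[0.6, 0.5, 0.0], [0.0, 0.0, 0.6]])
R = np.array([[1.0, 0.6, 0.3], [0.6, 1.0, 0.3], [0.3, 0.3, 1.0]])
Y = simulate_traits(
    G, causal=[4, 20], B=B, R=R, sigma=np.ones(3), seed=22,
    trait_names=["TG", "HDL", "LDL"],
)

tree = run_tree(
    G,
    Y,
    prior=PriorConfig(E=2, S=2, F=7),
    sampler=SamplerConfig(n_sweeps=1500, burn_in=300, n_chains=2, seed=23),
    fdr=FdrConfig(K=2, alpha=0.05, seed=24),
)

print(tree.fdr_report.to_string(index=False))

snp = G.snp_ids[4]
ranked = rank_groups_by_rbf(snp, list(tree.summaries.values()))
print(f"\nbranches ranked by RBF for {snp} (the TG/HDL-driving SNP):")
for group, value in ranked[:4]:
    print(f"  {group:12s} RBF {value:10.2f}")

print(
    "\nRBF divides each branch's Bayes factor by that branch's own "
    "FDR-baseline BF, so branches are compared on how far above their own "
    "significance floor the SNP sits — a branch whose null calibration "
    "already demands a high MPPI gets less credit for the same raw BF. "
    "With this panel the triplet ranks first for the shared TG/HDL signal."
)
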
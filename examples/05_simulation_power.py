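"""Power evaluation on the reference multi-trait simulation design.

Generates one desk-scale replicate of scenario MT1 (three traits, eight
causal SNPs in four LD blocks, residual correlations 0.95/0.50/0.30,
5% variance-explained cap), runs the search, and summarises the ROC of
the MPPI score against the known truth.
"""

import numpy as np

from essbvs import (
    PriorConfig,
    evaluate_roc,
    make_replicate,
    run_analysis,
    scenario_presets,
)
from essbvs.ess import SamplerConfig

mt1 = next(s for s in scenario_presets() if s.name == "MT1")
scen = mt1.scaled(p=200, n=1000)  # desk scale; the full design uses p=273,294
rep = make_replicate(scen, seed=31)

res = run_analysis(
    rep.G,
    rep.Y,
    prior=PriorConfig(E=8, S=4, F=7),
    sampler=SamplerConfig(n_sweeps=4000, burn_in=800, n_chains=3, seed=32),
)

roc = evaluate_roc(res.mppi, rep.truth)
print("power at small false-positive counts:")
for nfp in (0, 1, 2, 5, 10):
    rows = roc[roc["n_false_positives"] <= nfp]
    print(f"  <= {nfp:2d} false positives: power {rows['power'].max():.2f}")

ranks = sorted(
    int(np.where(np.argsort(-res.mppi) == j)[0][0]) + 1 for j in rep.truth
)
print(f"\nMPPI ranks of the 8 causal SNPs: {ranks}")
print(
    "\nStrong effects (0.2 on some trait) are recovered at the top of the "
    "ranking; the weakest (0.075-0.1) may need the full n=3,175 design to "
    "separate from the LD background."
)
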
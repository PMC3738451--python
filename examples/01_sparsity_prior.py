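"""Setting up the sparsity prior from natural quantities.

The model-size prior is parameterised by the a-priori expected number of
true associations E and its standard deviation S; the truncation
multiplier F caps model size at T = E + F*S. This reproduces the
production GWAS setting on a 273,294-SNP panel.
"""

from essbvs import make_size_prior, model_space_size

p = 273_294
prior = make_size_prior(E=20, S=12, F=7, p=p)

print(f"panel size p                 : {p:,}")
print(f"truncation bound T           : {prior.T}")
print(f"likely prior model-size range: 0 .. {prior.likely_range[1]:.0f}")
print(f"per-SNP prior inclusion pi   : {prior.pi_avg:.3g}")
print(f"beta-binomial (a, b)         : ({prior.a:.4f}, {prior.b:.1f})")

small = model_space_size(p=10, T=3)
print(f"\nmodel count for p=10, T=3    : {small}")
print(
    "\nT caps the stochastic search: any proposed model with more than "
    f"{prior.T} SNPs is rejected outright, while pi ~ {prior.pi_avg:.1e} "
    "says each SNP enters with odds of roughly 1 in "
    f"{round(1/prior.pi_avg):,} a priori."
)
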
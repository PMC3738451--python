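# Methods

## Model

One analysis regresses a trait group **Y** (n×q continuous phenotypes,
inverse-normal transformed per trait) on a genotype panel **X** (n×p,
additive minor-allele counts). Fixed covariates (intercept always; e.g.
sex, age, body mass index) are removed by projecting both Y and X onto
the orthogonal complement of their column span before the search. This
is mathematically equivalent to carrying the covariates as always-
included regressors in the conjugate model, provided the projected-out
column count `c_eff = 1 + c` is subtracted from the degrees of freedom;
`c_eff` is propagated from the projection step into the marginal
likelihood for exactly that reason.

A model is a subset γ of SNP columns. Conditional on γ:

    Y = X_γ B_γ + E,   rows of E i.i.d. N_q(0, Σ)
    B_γ | g, Σ ~ MN(0, g (X_γᵀ X_γ)⁻¹, Σ)
    g ~ Inverse-Gamma(1/2, n/2)        (Zellner–Siow)
    p(Σ) ∝ |Σ|^−(q+1)/2                (Jeffreys-style, default)

Integrating B and Σ analytically gives, up to one additive constant per
dataset,

    log p(Y | γ, g) = −(k q / 2) log(1+g) − ((n−c_eff)/2) log det S(γ,g)
    S(γ,g) = ỸᵀỸ − (g/(1+g)) Ỹᵀ H_γ Ỹ,

with k = rank(X̃_γ) and H_γ the orthogonal projector onto the model
columns. The residual-covariance prior is the one genuinely open choice
here: the original description commits only to a "hierarchical conjugate
structure". The Jeffreys default gives the matrix-t marginal with
exponent (n−c_eff)/2 and no extra tuning constants; at GWAS sample sizes
the likelihood dominates any proper inverse-Wishart alternative, and no
attempt is made to reproduce original log-posterior values numerically.
Genotype columns are mean-centred but not variance-scaled: the
projection already removes the intercept, and scaling would silently
change the g-prior geometry.

The reference implementation (`likelihood.log_marginal_likelihood`)
computes H_γ from a column-pivoted QR factorisation, which also supplies
k when model columns are collinear: duplicating a column leaves the
value unchanged. The sampler uses an algebraically identical Gram/
Cholesky path (below); tests pin both against a dense normal-equations
oracle to 1e-10 and against the classical single-response g-prior Bayes
factor formula.

## Priors on model size

Sparsity is specified by natural quantities: prior expected model size E
and SD S. These are moment-matched to a beta-binomial: with π ~
Beta(a,b), c = a+b and π̄ = E/p,

    Var(p_γ) = p π̄(1−π̄) (p+c)/(1+c) = S²
    ⇒ c = (p² π̄(1−π̄) − S²) / (S² − p π̄(1−π̄)),  a = π̄c, b = (1−π̄)c.

The match exists iff S² exceeds the binomial variance E(1−E/p); at
equality the prior degenerates to Binomial(p, E/p), which the
constructor substitutes automatically (within 1e-9 relative tolerance —
the only representable case at p = 1). The per-model prior mass is
f(p_γ)/C(p, p_γ) (exchangeable over equal-sized models) and the prior
marginal inclusion probability of every SNP is exactly E/p.

Model size is hard-truncated at T = ⌊E + F·S⌋; the sampler rejects any
proposal above T, so the truncation's normalising constant never enters
an acceptance ratio. The reported "likely range" of the prior model size
is [0, E+3S]. Note that the untruncated tail mass Pr(p_γ > T) of the
beta-binomial is heavier than the normal heuristic 1−Φ(F) suggests
(≈1e-2 at F=3); at the production F=7 it is 2.8e-5, i.e. the truncation
is genuinely negligible there, and that is what the tests assert.

## The sampler

L chains (default 3) run in parallel; chain l targets posterior^(1/t_l)
on a geometric ladder t_l = b^(l−1) with t_1 = 1 pinned. Each sweep:

1. **Fast-Scan MH pass per chain.** A random permutation of the scanned
   SNP subset is fixed *before* the scan (all p SNPs by default; a
   Bernoulli-thinned quarter above p = 10⁴), and each index is
   flip-proposed at most once: an add if currently excluded, a delete if
   included. Fixing the proposal order independently of the evolving
   state makes the pass a systematic scan — a composition of reversible
   single-flip kernels with state-independent selection — which
   preserves the tempered target. (An earlier variant that re-proposed
   adds for indices deleted in the same pass measurably biased the
   sampler away from small models and was removed; the enumeration-
   oracle test guards against regressions.) Flip proposals are
   deterministic given the scan position, so the acceptance probability
   is min(1, exp(Δ log posterior / t)).
2. **One global move** (chains ≥ 2): with probability 1/2 a uniform
   crossover — two chains' inclusion vectors are recombined with a
   Bernoulli(1/2) mask on their symmetric difference and the offspring
   pair is accepted jointly under the two tempered targets — otherwise a
   state exchange of a temperature-adjacent pair with the standard
   parallel-tempering ratio. The shrinkage coefficient g travels with
   its chain through crossover and is swapped together with γ in an
   exchange.
3. **A random-walk update of log g per chain**, targeting the tempered
   marginal-likelihood × prior with the (untempered) Jacobian g′/g from
   the log-scale parameterisation.

Adaptation is confined to burn-in and frozen afterwards: every 100
sweeps the ladder base b is multiplied/divided (exponent 1.25) to steer
the windowed exchange acceptance into [0.2, 0.6], and the per-chain
g step is scaled towards 0.35 acceptance.

### Fast inner loop

Per-proposal work is O(k) BLAS, not O(n k²) refactorisation. Each chain
caches the Cholesky factor L of the current model's Gram matrix, W =
L⁻¹X_γᵀỸ, A = WᵀW = ỸᵀH_γỸ and S⁻¹. For *adds*, all remaining
candidates' increments are computed in one vectorised pass (rank-one
Cholesky extension: d² = x_jᵀx_j − ‖L⁻¹v‖², w = (x_jᵀỸ − lᵀW)/d, and
log det shrinks by log(1 − h·wS⁻¹wᵀ) via the determinant lemma). Because
a rejected flip changes nothing, those increments stay exact until the
first acceptance; the scan draws all uniforms, jumps to the first
accepted candidate, applies it and refreshes. For *deletes*, the
inverse-downdate identity gives all columns at once: removing column c
changes A by −a_c a_cᵀ/P_cc with P = M⁻¹, a_c = (PB)_c, so log det S
grows by log(1 + h·a_cS⁻¹a_cᵀ/P_cc). Candidates whose residual norm
falls below 1e-9 (relative) are treated as rank-preserving (Δ logML =
0 for the likelihood; the size prior still penalises them), and models
containing such redundant columns fall back to per-column probes. When
p ≤ 2000 the full p×p Gram matrix is precomputed once, removing the
n-dependence from the scan entirely. Caches are rebuilt from scratch
every 100 sweeps; the recorded cold-chain log-posteriors are asserted
reproducible from (γ, g) by the reference likelihood to 1e-9.

All randomness flows from one seed through per-chain, global-move and
initialisation `SeedSequence` streams; runs are bit-reproducible.

## Posterior summaries

The cold chain's post-burn-in history (every sweep, no thinning) feeds:

* **Best Models Visited** — unique models ranked by MPP, the
  log-posterior renormalised over the unique visited set. A model seen
  at several g values is scored by its best recorded log-posterior: the
  MPP attaches to the model, not a (model, g) pair; integrating over the
  visited g's instead would change third-decimal MPPs at most but
  introduce a dependence on the g-chain's mixing.
* **MPPI** — the empirical inclusion frequency per SNP (no
  Rao-Blackwellisation).
* **Bayes factors** — BF_j = [m_j/(1−m_j)]/[π̄/(1−π̄)] with m_j clipped
  to [ε, 1−ε], ε = 1/(10 · retained sweeps), the resolution of the
  frequency estimator; log10 BF is conventionally display-truncated
  at 20.
* **RBF** — BF divided by the group's BF at its empirical-FDR MPPI
  threshold. Within a group this is a positive rescaling (ranks
  preserved exactly, RBF ≥ 1 for declared SNPs); across groups it
  measures strength of association relative to each group's own
  significance baseline, which is what makes trait-group rankings per
  SNP meaningful.

## Empirical FDR

K (default 3) datasets are created by permuting the rows of the trait
matrix (all traits together, preserving their correlation); the full
analysis is re-run on each and the resulting MPPI pooled — across trait
groups of equal cardinality when a tree is analysed, so the null tail
has enough mass. The threshold m* is the smallest observed MPPI value
at which

    (#{null MPPI ≥ m*}/K) / #{observed MPPI ≥ m*} ≤ α .

The pooled null count is divided by the number of contributing permuted
runs so the numerator is a per-dataset expectation; without it the
estimate scales with K. Candidate thresholds are the observed values
themselves (the declared set only changes there), giving the least
conservative valid threshold.

**Known behaviour:** when the largest observed MPPI exceeds *every*
pooled null value, the estimated FDR at that value is 0 and the top hit
is declared. Under a completely null dataset the observed and permuted
MPPI vectors are exchangeable, so this happens with probability
≈ 1/(K+1) — about 25% of pure-null datasets at K = 3 yield one or two
(spurious) declarations. This is a property of the threshold rule
itself, not of the sampler; raising K, or adding +1 to the null count
(which this package does not do, to keep the stated rule exact), makes
it rarer.

## Simulation module

`simulate_genotypes` draws two latent standard-normal haplotype chains
per individual; an allele is minor when its latent value falls below
Φ⁻¹(MAF), and the genotype is the allele sum — Hardy–Weinberg by
construction. Within an LD block the latent chains are AR(1), and the
step correlation is calibrated per adjacent pair (bivariate-normal CDF
root-finding) so that the *genotype* correlation equals the requested
decay. SNPs inside one block share one MAF drawn from the block: tightly
linked markers have near-identical frequencies in real panels, and a
high genotype correlation between markers of very different MAF is not
even attainable. Positions are synthesised at 5 kb spacing with one
"chromosome" label per block.

Trait generation is the matrix-variate design Y = X_causal B + E with
error rows N_q(0, D_σ R D_σ). `calibrate_error_variance` sets σ_t² =
Var(X_causal b_t)·(1−r)/r from the *empirical* genetic variance, so the
expected variance explained equals the cap r (5% in all presets)
exactly, for every trait; null traits get σ_t = 1.

The four presets encode the reference designs: MT1 (q=3, eight causal
SNPs, two per each of four blocks, fixed 8×3 effect matrix, residual
correlations 0.95/0.50/0.30), MT2 (correlations halved), ST1 (first
trait of MT1), ST2 (single trait, four primary/secondary pairs with
effects [4, 1, 1, 6, 1.5, 3, 4, 0.5], the secondary drawn from within
±5 positions — 25 kb at the synthetic spacing — of the primary). All use
n = 3,175 and 20 replicates. The preset block decay is 0.7 (adjacent
r² ≈ 0.5): the reference panels were tag-pruned at r² > 0.8, so a
synthetic panel whose adjacent pairs exceed that bound would be
qualitatively harder than the stated world; 0.7 keeps realistic local
LD below the pruning threshold.

What the generator does **not** emulate: real LD (long-range structure,
variable block lengths, MAF-dependent decay), population structure and
relatedness, missing genotypes, genotyping error, non-normal trait
distributions. A green recovery test therefore establishes that the
search finds sparse multi-SNP, multi-trait signal embedded in blocked
LD at the stated effect sizes — not robustness to confounding or panel
artefacts.

`evaluate_roc` sweeps score thresholds; with a window, hits within
±window bp of a truth collapse to one true positive and false positives
deduplicate per interval, matching how relaxed power comparisons are
usually reported.

## Numerical choices

* Rank decisions (candidate collinearity) at 1e-9 relative residual
  norm; QR rank at `max(n,k)·eps·|R₀₀|`.
* S(γ,g) must be positive definite; near-singular S falls back to
  eigenvalue clipping at 1e-12·trace with a warning, and a genuinely
  non-PD S raises.
* log g proposals beyond |700| are rejected outright (exp overflow; such
  g carries essentially zero density).
* HWE QC uses the 1-df chi-square test on expected genotype counts (no
  continuity correction) — fast at panel scale; an exact test would
  differ only at tiny minor-allele counts, below the MAF filter anyway.
* Greedy tagging is maximum-coverage (pick the SNP covering most
  yet-uncovered SNPs at r² > threshold, ties to the lower index) on
  mean-imputed additive codes.
* The inverse-normal transform uses the Blom-style offset
  (rank − 3/8)/(n + 1/4) with average ranks for ties.

## Limitations

* Pure Python/BLAS: ~5–10 ms per sweep at p = 500, n = 3,175 — ample for
  panels up to a few thousand SNPs (regions, pathways, scaled designs);
  a 273k-SNP genome-wide run is out of desk scope.
* The empirical-FDR top-hit behaviour under complete nulls described
  above.
* Weak effects (≤0.1 SD per allele at a 5% total variance cap) are not
  recoverable at n = 1,000 in the MT1 design — a power fact, not a
  sampler one; the reference n = 3,175 recovers all eight causal SNPs.
* X-chromosome handling, imputation and genotype calling are out of
  scope; missing genotypes are mean-imputed with a warning.
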
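# Methods

## Model

For individual *j* of family *i*, a binary trait `Y_ij ∈ {0,1}` follows the
marginal logistic model

    logit(μ_ij) = X_ij' γ + G_ij' β,

with covariates `X_ij` (intercept included), dosages `G_ij ∈ {0,1,2}` for
the r variants of a region, and coefficients γ, β. Within a family the
trait vector is coupled by a latent-threshold construction:
`Y_ij = 1{Z_ij ≤ Φ⁻¹(μ_ij)}` with `Z_i ~ N(0, Γ_i)` and

    Γ_i = h² Ψ_i + (1 − h²) I,

where Ψ_i is the expected identity-by-descent sharing matrix (twice the
kinship matrix) and h² ∈ [0,1) the latent-scale polygenic heritability.
This is a Gaussian copula over the logistic margins: margins are preserved
exactly for every h², and h² is "margin-free" — it lives only in the
copula. Families are assumed independent, so every N×N matrix in the
method is block-diagonal over families (plus low-rank estimation
corrections).

## The test

The region effect is tested as a variance component: β is treated as
random with mean 0 and covariance τW, W = diag(w_1..w_r) per-variant
weights, and H₀: τ = 0. The score of the working-independence likelihood
in τ at τ = 0 is, up to a constant and a negligible trace term,

    Q = (Y − μ̂)' K (Y − μ̂),

where μ̂ comes from the null logistic fit (γ only) and K is a genotype
similarity kernel; the canonical choice is the weighted linear kernel
K = G W G'. Under H₀, Q is distributed as a weighted mixture
`Σ_n θ_n χ²₁` with θ_n the eigenvalues of `Ω^{1/2} K Ω^{1/2}` and Ω the
covariance of the stacked null residuals Y − μ̂.

### Residual covariance Ω

Within family *i*, `Σ_i` has diagonal μ(1−μ) and off-diagonal entries
`Φ₂(Φ⁻¹(μ_j), Φ⁻¹(μ_k); Γ_i[j,k]) − μ_j μ_k` (bivariate-normal orthant
probabilities). Estimating γ perturbs the residuals, giving the sandwich
blocks

    Ω_ii  = Σ_i − (1/I) Δ_i X_i A⁻¹ X_i' Σ_i − (1/I) Σ_i X_i A⁻¹ X_i' Δ_i
                 + (1/I) Δ_i X_i A⁻¹ B A⁻¹ X_i' Δ_i,
    Ω_ii' = −(1/I) Δ_i X_i A⁻¹ X_i'' Σ_i' − (1/I) Σ_i X_i A⁻¹ X_i'' Δ_i'
                 + (1/I) Δ_i X_i A⁻¹ B A⁻¹ X_i'' Δ_i',

with Δ = diag(μ(1−μ)), `A = (1/I) Σ X_i' Δ_i X_i`, and B either
model-based `(1/I) Σ X_i' Σ_i X_i` (default — smoother at I≈120 because it
reuses the fitted copula) or the empirical score outer product
`(1/I) Σ S_i S_i'`. The assembled Ω is symmetrized; a dedicated
simulation test verifies Ω entrywise against the empirical covariance of
null residuals over 2×10⁴ replicates, which pins down both the block
formulas and the 1/I scaling.

### Heritability

h² is estimated under H₀ by maximizing the pairwise composite
log-likelihood over all within-family pairs: each pair contributes the log
of its 2×2 cell probability built from the bivariate Gaussian copula with
latent correlation h²Ψ_jk. The ordered double sum equals twice the
unordered sum, which leaves the argmax unchanged. Optimization is a
bounded scalar search on [0, 1−10⁻⁶] with tolerance 10⁻⁴. With 120
families of the default design the estimator is unbiased but variable
(SD ≈ 0.16 at h² = 0.5); at h² = 0 it piles up on the boundary with a
long right tail, so point estimates near zero should be read
distributionally. If no relative pair with Ψ_jk > 0 exists the likelihood
is flat and the function returns 0 with a warning (or raises when there
are no pairs at all); a fixed h² can always be supplied.

### P-values

Mixture weights θ are computed from the symmetric square root of Ω after
clipping negative eigenvalues at zero (the sandwich subtraction can make Ω
slightly indefinite at finite I; the clipped mass is logged and a warning
raised if it exceeds 10⁻³ of the trace). For the linear kernel the same
nonzero weights are obtained as eigenvalues of the r×r matrix `L'ΩL`
(K = LL'), avoiding the N×N eigendecomposition. Weights below 10⁻¹⁰ of
the largest are dropped; if none remain the region is degenerate
(monomorphic) and an error is raised.

The tail probability `P(Σ θ_n χ²₁ > Q)` is computed by direct numerical
inversion of the characteristic function (Imhof's integral) with adaptive
quadrature at absolute tolerance 10⁻¹¹, after rescaling by max θ so the
integrand oscillates on an O(1) scale. When the quadrature flags
non-convergence or the probability is below its 10⁻¹⁰ resolution, the Liu
moment-matching noncentral-χ² approximation is used instead; the method
actually used is recorded in the result. P-values are clipped to
[10⁻¹⁶, 1].

## Kernels and weights

Five kernels: linear `Σ w_l G_ul G_vl`; quadratic `(1 + Σ w_l G_ul G_vl)²`;
IBS `Σ w_l (2 − |G_ul − G_vl|)`; Gaussian
`exp(−Σ w_l (G_ul − G_vl)²/b)` with bandwidth b = r by default;
polynomial `(1 + Σ w_l G_ul G_vl)^d` with offset 1 and degree 3 (degree 2
would duplicate the quadratic kernel). Weights enter once (w_l, not
w_l²). The default weight is the Beta(1,25) density of the MAF —
`25(1−m)²⁴`, the standard rare-variant up-weighting — with flat and custom
alternatives. MAFs for weighting are computed from founders only (the
unbiased allele-frequency estimate in pedigrees); allele frequencies above
0.5 are folded. Monomorphic variants are dropped before weighting, and
subjects with any missing value are removed listwise upstream of the test.
The exact IBS/Gaussian/polynomial parameterizations in other software
vary; ours are the documented conventions above, so cross-package numeric
comparisons should fix the kernel definition first.

## Simulated study conditions

The default design is 120 families: 40 parent-parent-child trios, 40
two-parent/two-child families and 40 three-generation octets (grandparent
couple, their two children with married-in spouses, two first cousins) —
600 subjects, 320 founders, 280 nonfounders, 240 males / 360 females.

Genotypes: 20 linked SNPs per region, MAF drawn Uniform(0.003, 0.01),
squared correlation between adjacent SNPs d² = 0.16 **on the allele
scale**. Founder haplotypes come from a latent AR(1) Gaussian process
thresholded at Φ⁻¹(MAF), with each adjacent latent correlation calibrated
numerically (via bivariate-normal orthant probabilities) so the binary
correlation hits √d² exactly; infeasible MAF/d² combinations (beyond the
Fréchet bound) are rejected with the offending pair named. Gene dropping
transmits whole parental haplotypes (uniform choice per gamete): the
regions modelled are tightly linked, and whole-haplotype transmission
preserves the founder LD structure; an optional per-interval recombination
fraction exists (default 0).

Covariates are X1 ~ U(0,1) and X2 ~ Bernoulli(0.2) with effects
γ = (−2, 1, 1) (population prevalence ≈ 0.26). Causal effects for power
runs pick 5 of 20 SNPs at random with β ~ N(0, τ·w), τ ∈ {0.05, 0.2}.

Four phenotype generators: the Gaussian copula above (the model the test
assumes); a GLMM with `b_i ~ N(0, h²Ψ_i)` added to the linear predictor;
a Student-t copula (df = 3, Gaussian scale-mixture construction with one
mixing draw per family) whose variates are thresholded at Φ⁻¹(μ) exactly
as in the Gaussian case — this deliberately distorts the margins to
F_t(Φ⁻¹(μ)) and is kept as the stress scenario, with a
`correct_margins` flag for users wanting a pure t-copula; and a chi-square
copula (noncentrality a = 1) via the transform
`U = sign(z̃+a){Φ(z̃+2a) + Φ(z̃) − 1}`, `Z = Φ⁻¹(U)`, with sign(0) := 0
and U clipped to [10⁻¹², 1−10⁻¹²] so the probability-zero point z̃ = −a
cannot produce infinities. Missing-data mechanisms (MCAR at rate p; MAR
with masking logit-linear in the covariates, unit slopes, centred at the
covariate means) mark subjects for listwise deletion.

What the simulator does **not** emulate: ascertainment/selection bias (no
generation rule is defined for it here), genotyping error, recombination
maps, population structure or admixture, inbreeding, X-linked dosage
conventions, and continuous or multivariate traits. Passing tests
therefore demonstrate calibration and power under random family sampling
with correctly typed pedigrees, not robustness to those features.

## Experiment defaults and problem sizes

Type-I experiments default to 2000 replicates and power experiments to
500 — sizes chosen so a full calibration runs in minutes on a laptop core
while keeping the Wilson 99% interval at α = 0.01 tight enough to detect
meaningful miscalibration (±0.006 at B = 2000); flags raise them. Each
experiment derives per-replicate seed streams from one master seed, so any
single replicate is independently reproducible. Multi-kernel scans share
the null fit, ĥ² and Ω across kernels (none of which depend on K).

## Numerical choices

- Null logistic fit: damped Newton/IRLS from γ = 0 to score sup-norm
  < 10⁻⁸; diverging coefficients or boundary fitted probabilities raise a
  separation error (cross-checked against statsmodels GLM in tests).
- Bivariate normal CDF: Owen's-T identity (vectorized, ~machine accuracy),
  validated against scipy's bivariate CDF and Monte-Carlo orthant
  estimates; exact zeros of the bounds are nudged by 10⁻¹³, |ρ| within
  10⁻¹² of 1 uses the Fréchet limits.
- Pairwise-likelihood cells are floored at 10⁻¹² inside logs.
- Kinship uses the standard founder-first recursion; pedigrees implying
  inbreeding (self-kinship > ½) are rejected because Γ requires a unit
  diagonal. Unknown-parent members inside a family are treated as
  founders; a half-known parent pair is a structural error.
- Eigenvalue clipping and drop thresholds as described under P-values.

## Limitations

The asymptotics are in the number of families; with I < 30 a warning is
attached to results and p-values should be treated cautiously. The
block-diagonal structure is essential: empirical genomic-relatedness
matrices (not block-diagonal) are out of scope. The test assumes
non-inbred pedigrees, a single binary trait, and listwise-complete data.
Under GLMM-generated traits with strong heritability the marginal logistic
working model is mildly biased, which pushes the test toward conservatism
rather than inflation; under t-copula misspecification mild inflation has
been observed, consistent with the heavier-than-Gaussian tail dependence.
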
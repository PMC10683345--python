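# nrvat

Variant-set association testing for **binary traits in family-based
designs**, built on a marginal logistic model coupled with a **Gaussian
copula** over pedigree kinship. The package is aimed at statistical
geneticists analysing sequencing data from pedigrees (trios to extended
multi-generation families) who want a region-based rare/common-variant
test that respects familial dependence without conditioning the effect
sizes on random effects — the regression coefficients keep their marginal,
population-level interpretation.

## The method

For subject *j* in family *i* with covariates `X_ij`, region dosages
`G_ij` and trait `Y_ij ∈ {0,1}`:

    logit(μ_ij) = X_ij'γ + G_ij'β,       Y_ij = 1{Z_ij ≤ Φ⁻¹(μ_ij)},
    Z_i ~ N(0, Γ_i),                      Γ_i = h²Ψ_i + (1−h²)I,

with Ψ_i the expected IBD-sharing (relatedness) matrix and h² the
latent-scale polygenic heritability, estimated by pairwise composite
likelihood. Treating β as random with covariance τW and testing τ = 0
gives the score statistic

    Q = (Y − μ̂)' K (Y − μ̂),

where K is a weighted genotype-similarity kernel (linear, quadratic, IBS,
Gaussian or polynomial; Beta(1,25) MAF weights by default). Under H₀,
Q ~ Σ θ_n χ²₁ with θ_n the eigenvalues of Ω^{1/2}KΩ^{1/2}, where Ω is the
copula-implied residual covariance with sandwich corrections for the
estimated γ. Tail probabilities come from characteristic-function
inversion with a moment-matching fallback. See `docs/methods.md` for the
full account, assumptions and limitations.

The package also contains the simulation machinery used to validate the
test: the standard 120-family study design, linked-SNP founder-haplotype
simulation with calibrated adjacent-SNP LD, Mendelian gene dropping, and
four phenotype generators (Gaussian copula, GLMM, Student-t copula,
chi-square copula) covering the correctly specified and misspecified
regimes.

## Worked example

```python
import numpy as np, nrvat

ped = nrvat.default_pedigree_set()          # 120 families, 600 subjects
cfg = nrvat.ExperimentConfig(setting="copula_gaussian", h2=0.5, tau=0.2,
                             n_replicates=1, seed=7)
Y, X, G = nrvat.simulate_dataset(cfg, ped, np.random.default_rng(7))
results = nrvat.nrvat_test_multi(Y, X, G, ped, kernels=["linear", "ibs"])
```

Output (`examples/run_region_test.py`):

```
simulated 600 subjects in 120 families; prevalence 0.245
 linear: Q =    1913.38   p = 0.009458   h2_hat = 0.512  (19 variants, imhof)
    ibs: Q =    3813.22   p = 0.007573   h2_hat = 0.512  (19 variants, imhof)
```

The region was simulated with five causal variants (τ = 0.2), and both
kernels flag it at p < 0.01. `h2_hat` is the pairwise-likelihood estimate
of the latent heritability (truth 0.5 here); one of the 20 SNPs was
monomorphic in this draw and dropped, leaving 19. `imhof` records which
tail-probability algorithm produced the p-value.

Further scripts in `examples/`: data simulation to FAM/VCF/TSV files,
type-I-error calibration, power curves, and Bonferroni multiple-testing
summaries. A thin CLI wraps the same machinery:

```bash
nrvat simulate --setting copula_gaussian --h2 0.5 --seed 4 --out sim/
nrvat test --ped sim/families.fam --geno sim/genotypes.vcf \
           --covar sim/phenotypes.tsv --kernel linear --out results/
nrvat experiment type1 --reps 2000 --seed 1 --out exp/
```

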
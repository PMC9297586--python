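# Methods

## Model

`csprs` performs Bayesian polygenic modeling on GWAS summary statistics.
The data enter as standardized marginal effects: for SNP j with reported
effect β_j (or log OR) and p-value p_j, the model works with
β̂_j = sign(β_j)·z(p_j/2)/√n, where z is the upper standard-normal quantile
and n the GWAS sample size, so that β̂ has sampling variance ≈ 1/n
regardless of the phenotype's units.  (An SE-based route,
β̂_j = (β_j/se_j)/√n, is available behind a flag for files whose p-values
are rounded or missing.)

True effects β on the standardized-genotype scale follow a global-local
scale-mixture ("continuous shrinkage") prior:

    β_j | ψ_j, σ², φ ~ N(0, (σ²/n)·φ·ψ_j)
    ψ_j ~ Gamma(a, δ_j),   δ_j ~ Gamma(b, φ)

The local scales ψ_j give per-SNP adaptivity (null SNPs shrink hard, large
effects escape nearly unbiased); the global scale φ tracks overall
polygenicity.  Defaults a = 1, b = 1/2 put the mixture in the
horseshoe-like family.  The likelihood conditions on LD through per-block
reference correlation matrices D; between-block correlation is modeled as
zero, which makes the block Gibbs update exact under the model.

## Gibbs sweep

Per iteration, in genomic block order:

1. β_blk ~ N(A⁻¹β̂_blk, (σ²/n)A⁻¹), A = D_blk + diag(1/ψ_blk), via a lower
   Cholesky factorization (mean by `cho_solve`, noise by a triangular
   back-solve).
2. ψ_j ~ GIG(a − ½, 2δ_j, n·β_j²/σ²), then capped at 1;
   δ_j ~ Gamma(a + b, rate ψ_j + φ).
3. φ (auto mode only): w ~ Gamma(1, rate φ + 1), then
   φ ~ Gamma(p·b + ½, rate Σδ + w).
4. 1/σ² ~ Gamma((n+p)/2, rate e), with
   e = max((n/2)(1 − 2βᵀβ̂ + Σ_blk βᵀ(D + diag(1/ψ))β), (n/2)·Σβ_j²/ψ_j),
   the second argument guaranteeing a positive rate for any nonzero β.

The ψ cap at 1 stabilizes the auto-φ chain (an uncapped local scale can
otherwise absorb the global one).  The sweep order β → (ψ, δ) → φ → σ² is a
fixed-scan Gibbs sampler; within step 2, ψ is refreshed from the current δ
and δ from the refreshed ψ — any fixed order of these conjugate refreshes
leaves the stationary distribution intact, and this one was chosen for
simplicity of the state contract (ψ always reflects the δ it was drawn
from).

GIG variates use Devroye's uniformly-fast rejection scheme on the log
scale, vectorized across SNPs with mask-based lane retirement; lanes with
χ = 0 fall back to the exact Gamma limit.  `scipy.stats.geninvgauss`
serves as an independent cross-check in the tests, never as the sampler.

Numerical choices: Cholesky failures on near-singular LD blocks trigger
diagonal jitter ε = 1e−6·trace(A)/dim, doubled up to 6 times before a hard
error naming the block.  p-values that underflow to 0 in the input text are
floored at 1e−323 (|z| ≈ 38.5).  NaN in the chain aborts with the iteration
index.

## MCMC configuration

Program defaults are 1,000 iterations, 500 burn-in, thinning 5 (100
retained draws), which on block-LD inputs of a few thousand SNPs already
yields Monte-Carlo error far below the posterior spread; a documented
"full" preset (10,000 iterations, 5,000 burn-in, thin 5) matches the
configuration typically used for production runs at biobank scale.
Weights are running means (Welford accumulation, no stored samples), with
per-SNP retained-draw variances kept as a Monte-Carlo error scale.  The
posterior weight is emitted on the standardized scale by default, or
per-allele (divided by √(2·maf·(1−maf))) on request.

Each chromosome runs as an independent chain whose RNG stream derives from
(seed, chromosome), so per-chromosome runs reproduce independently and
parallel execution (`--x-parallel`, joblib processes) is bit-identical to
sequential.

## Harmonization and QC

The analysis set is the intersection of the summary statistics, the LD
reference, and the target variant list, with allele matching in four
configurations — direct, swapped (β sign flips), strand-complement, and
swapped-complement — using A↔T/C↔G complements.  Non-complement
configurations are tried first, so palindromic A/T and C/G pairs resolve
without a strand flip; `--x-drop-ambiguous` removes them instead.  The
reference defines SNP order and allele orientation.  Duplicate SNP ids are
fatal (id is the join key); duplicate positions with distinct ids are
allowed.  Chromosome labels are normalized to strings without a "chr"
prefix; positions are 1-based as in `.bim`.

Variant QC removes SNPs with MAF ≤ 0.01, Hardy–Weinberg χ² p < 10⁻¹⁰, or a
MAF differing from the reference panel's by more than 0.10, and reports one
(variant, rule) row per violation so per-rule counts are auditable.

## Scoring and evaluation

Raw scores are unnormalized weighted allele sums (the per-SNP average would
differ only by a constant factor that z-scaling removes); alleles are
aligned with the same four-configuration logic, a swapped coding counting
2 − d toward the weight's effect allele.  Missing dosages are imputed with
the cohort mean of the counted allele (equivalently 2× its frequency), or
dropped behind a flag.  z-scores use the sample SD (denominator n − 1),
matching R's `scale()`.

Quantitative accuracy is OLS R² of phenotype on score plus covariates,
reported as full-model R² with the incremental R² over covariates-only
alongside (the headline is full-model; both are always emitted).  Binary
accuracy: AUC by the rank formulation (ties ½); Nagelkerke pseudo-R²
(1 − (L₀/L₁)^{2/n})/(1 − L₀^{2/n}) from nested logistic fits
(covariates-only vs covariates + score); and the odds ratio of the top 10%
of scores versus the bottom 90%, with boundary ties assigned to the top
stratum and Haldane–Anscombe 0.5 correction on zero cells.  Covariates
enter as joint model terms, not by pre-residualization.  Replicate runs are
summarized as mean and sample SD (k − 1).  Concordance between two weight
vectors reports per-SNP squared errors, their median, and a paired t-test
(exactly identical vectors get t = 0, p = 1 rather than a 0/0).

## Synthetic data

The generator emulates the full input ecosystem.  Genotypes: within each
block, a latent Gaussian AR(1) process (correlation ρ) is drawn twice per
individual and thresholded at Φ⁻¹(maf); summing the two haplotypes gives
0/1/2 dosages in Hardy–Weinberg equilibrium by construction, with zero
between-block LD — deliberately matching the sampler's block-conditional
structure so recovery tests are not confounded by LD misspecification.
Phenotypes: round(π·p) causal SNPs receive effects drawn N(0, h²/(π·p)) and
then rescaled so the genetic variance is exactly h² on the generating
cohort (without this, the chi-square fluctuation of Σβ² at small causal
counts, SD ≈ h²√(2/m), would dominate the realized heritability); noise is
N(0, 1 − h²).  Binary traits threshold the unit-variance liability at the
theoretical Φ⁻¹(1 − K) for prevalence K, so the case fraction is binomial
around K.  Marginal GWAS uses exact per-SNP OLS (t-test p, n − 2 df) for
quantitative traits and the logistic score test (trend test; one-step
estimate U/V, SE 1/√V) for binary ones.

Default study conditions: n_gwas = 20,000, p = 2,000 SNPs in blocks of 250,
ρ = 0.5, MAF ∈ [0.05, 0.5], h² = 0.5, causal fraction π = 0.05, reference
cohort 2,500, held-out target 2,000, prevalence 0.2.  Where a value was an
open choice (ρ, block size, MAF range, cohort sizes, K), it was fixed once
at a level typical of common-variant studies of complex traits.

What the generator does **not** emulate: coalescent haplotype structure,
between-block LD, allele-frequency–dependent architectures, ancestry
admixture or stratification, genotyping error and missingness patterns.
Passing recovery tests therefore demonstrate correctness of the inference
machinery under the model's own assumptions, not robustness to the LD
mismatch and confounding of real panels.

## File formats

LD references live in a directory: `snpinfo.tsv` (CHR SNP BP A1 A2 MAF)
plus one HDF5 file per block (`ldblk_<idx>_chr<c>.h5`, datasets `D`,
`snp_ids`); symmetry, unit diagonal, and near-PSD are validated on load.
Block boundaries are an input (TSV of chr/start/end) or default to fixed
windows of 1,000 SNPs.  Genotypes are text dosage matrices (IID column +
one column per SNP) paired with a PLINK `.bim` for allele coding; the
binary `.bed` format is out of scope.  Weight files are header-less
6-column TSV (CHR SNP BP A1 A2 BETA), one per chromosome.

## Known limitations

Single-ancestry only (no cross-population joint modeling); no
validation-based grid search for fixed φ; dense per-block LD storage (no
sparse/banded form); the evaluation module assumes complete-case
covariates.  The concordance t-test treats per-SNP differences as
exchangeable, which is adequate for the weakly cross-correlated
Monte-Carlo noise of thinned chains but not for systematically shifted
weight sets.
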
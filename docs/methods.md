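# Methods

## Model and estimator

The phenotype model is an additive multi-component linear mixed model.
Genotypes are standardized per SNP — missing calls mean-imputed (twice
the in-sample counted-allele frequency), columns centered, then rescaled
so each column's sum of squares equals exactly N. Under this scaling the
genetic relatedness matrix of every category, K_k = X_k X_kᵀ / M_k, has
trace exactly N, which fixes the b-entries of the normal equations; for
continuous annotations (X_k diag(√a_k)) the trace is N·mean(a_k) and the
b-entries carry that factor.

Variance components are estimated by matching y yᵀ against
Σ_k σ²_k K_k + σ²_e I in Frobenius norm, which reduces to a bordered
(K+1)×(K+1) linear system with T_{kl} = tr(K_k K_l), c_k = yᵀK_k y. The
traces are estimated by the Hutchinson identity E[zᵀCz] = tr(C) with B
i.i.d. standard-normal probe vectors shared across all components (the
sharing is required: the cross-terms T_{kl} must use the same probes).
The estimator is unbiased for T entry-wise; the subsequent linear solve
is nonlinear in T̂, with consequences quantified below.

Solving is a direct dense solve; if the bordered matrix's condition
number exceeds 1e12 the solver falls back to minimum-norm least squares
with a warning. Component estimates are reported unconstrained —
negative values are informative noise around small components — with an
optional post-hoc truncation flag in the CLI.

## Streaming accumulation and the jackknife

All sufficient statistics are collected in one pass over SNP blocks:
for each standardized block, one GEMM gives X_blockᵀ[Z | y], and the
probe images X_block(X_blockᵀ z_b) are scattered into the owning
component(s) and the owning jackknife block (J near-equal contiguous
SNP blocks in genome order, default J = 100). Accumulated moments are
invariant to the streaming block size (tested to 1e-8). The retained
per-block images cost O(N·K·B·J) memory — the intended desk-scale
trade-off — and make every delete-one-block refit a subtraction plus a
(K+1)-dimensional solve; genotypes are never re-read. SE² =
((J−1)/J)·Σ_j (θ̂_{−j} − mean)² elementwise for σ², h², and enrichment;
enrichment is tested against its null value 1 with a normal Z.

The jackknife is over SNP blocks (not individuals): it captures
sampling noise of the genome partition, is LD-aware through contiguity,
and is what the accumulator design supports. A delete-block fit that
empties a component drops that component and flags the replicate.

## Covariates

The phenotype is always residualized on an intercept (centering) plus
any covariates via the orthogonal projector P = I − QQᵀ (Q an
orthonormal basis, rank-deficient columns dropped). The same projector
is applied to the probe vectors and to the accumulated images before
inner products, so every moment is computed on projected data, and
n_eff = N − rank(W) replaces N in the bordered system. Because
standardized columns are centered, the intercept part of P acts as the
identity on genotype images; only n_eff changes in the no-covariate
case.

## Annotation maps

Disjoint MAF × score partitions use left-closed/right-open MAF
intervals (the last closed), in-sample empirical score quantiles with
ties to the lower bin, and drop empty bins (a zero-size component makes
the normal equations singular). LD scores are in-sample sums of squared
correlations within a window, self-correlation included (minimum 1).
The window defaults to 1 Mb; the simulation studies use 100 kb because
the simulator spaces SNPs 1 kb apart and a 1 Mb window would span much
of the synthetic chromosome. External per-SNP scores (e.g. LD-taper
weights computed by other software) are accepted as a score column and
never computed internally.

## Simulator

Phenotypes follow σ²_m = S·c_m·w_m^b·[f_m(1−f_m)]^a with S normalizing
Σσ²_m = h², β_m ~ N(0, σ²_m) on the standardized scale, and residual
variance 1−h², so E[var(y)] = 1. a = b = 0 is the equal-variance
(GCTA-style) architecture; a = 0.75, b = 1 an LDAK-style one. Causal
SNPs are drawn uniformly among SNPs whose MAF lies in a window; w_m
defaults to 1 and is exercised with synthetic log-normal(0, 0.5²)
scores in the studies. Genotypes are independent Binomial(2, f) draws
with f ~ Uniform(0.01, 0.5) by default, or a blockwise latent Gaussian
AR(ρ) thresholded per haplotype to the target frequencies for positive
within-block LD. All randomness flows from one seed through spawned
independent streams (genotypes / causal mask / effects / noise).

What the generator does **not** emulate: realistic LD decay and
haplotype structure, allele-frequency spectra skewed toward rare
variants, population stratification, relatedness, genotyping or
imputation error, and non-normal effect distributions. Passing
recovery tests therefore demonstrate correctness of the estimator under
its own model assumptions at desk scale, not robustness to the
confounders of real cohorts.

## Simulation-study design (tests and `scripts/acceptance.py`)

Replicate studies fix the genotype matrix per architecture and draw
many phenotype replicates on it, matching how heritability estimators
are usually evaluated. For point-estimate studies the probe sketch is
the only phenotype-independent randomized part, so a pool of
independently seeded sketches (hundreds) is computed once and cycled
across replicates: replicate means still average over sketch noise
while the O(NMB) probe pass is amortized; each pool system is
LU-factorized once and replicates only substitute the right-hand side.
Calibration studies (enrichment Z-test, jackknife SE) run the full
per-replicate fit with a fresh sketch and the full jackknife instead.

Problem sizes used (chosen once from a Monte-Carlo error analysis so
that the standard error of each study's mean sits well inside the
quantity being asserted): genome-wide bias grid N = 2000, M = 5000,
h² = 0.5, 8 bins, B = 10, four (a, b) architectures, 3200 replicates ×
450-sketch pool each; 24-bin small-cohort grid N = 2000, M = 6000,
h² = 0.25, 1% causal in MAF ∈ [0.05, 0.5], 1200 replicates ×
250-sketch pool; enrichment calibration N = 2000, M = 4000, J = 100,
400 full fits; jackknife calibration 200 full fits. The test suite
runs the same studies at moderately reduced sizes.

## Numerical behaviour and known limitations

* **Probe-count bias at small N.** T̂ is unbiased, but σ̂² = Â⁻¹c is
  nonlinear in T̂, so sketch noise induces a bias of order 1/B that also
  grows as bins get small (T entries scale like N²/M_k). At desk scale
  (N ≈ 2000, B = 10, low-MAF bins of ~100 SNPs) this inflates the
  genome-wide estimate by several tenths of a percent of h²; it
  disappears as B or N grows (the B = 10⁴ fit matches the exact
  dense-GRM oracle to <1%, and the bias is immaterial at biobank N).
  Users fitting small cohorts with many small bins should raise
  `n_vectors` or use the exact oracle.
* Empty or near-empty bins are dropped up front; duplicated or
  degenerate component definitions route to the least-squares fallback
  rather than crashing.
* Enrichment is undefined (NaN) when the total heritability estimate is
  zero; Z-scores are NaN when a jackknife SE is zero.
* The dense oracle refuses N > 5000 to avoid accidental O(N²) memory
  use.
* Binary traits are treated as continuous; no liability-scale
  transformation is provided.
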
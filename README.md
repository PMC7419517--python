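# randhe

Randomized multi-component Haseman–Elston regression: scalable
method-of-moments estimation of genome-wide and partitioned SNP
heritability, with annotation enrichment and block-jackknife standard
errors.

## The problem

Complex-trait heritability analyses model a centered phenotype vector
**y** over *N* individuals as an additive function of *M* standardized
genotypes split into *K* categories (MAF/LD bins, chromosomes,
functional annotations):

    y = Σₖ Xₖ βₖ + ε,   βₖ ~ (0, σ²ₖ/Mₖ · I),   ε ~ (0, σ²ₑ I)

The genome-wide SNP heritability is h²= Σₖσ²ₖ / (Σₖσ²ₖ + σ²ₑ), the
per-category share h²ₖ = σ²ₖ / (Σσ² + σ²ₑ), and the enrichment of
category *k* is eₖ = (h²ₖ/h²)/(Mₖ/M), with null value 1. Fitting many
variance components matters because single-component fits are biased
when effect sizes vary with minor allele frequency (MAF) and linkage
disequilibrium (LD).

Method-of-moments estimation matches **y yᵀ** against
Σₖ σ²ₖ Kₖ + σ²ₑ I, where Kₖ = XₖXₖᵀ/Mₖ is the category's genetic
relatedness matrix, giving the normal equations

    [ T  b ] [σ²_g]   [ c  ]
    [ bᵀ N ] [σ²ₑ ] = [yᵀy]

with T_{kl} = tr(Kₖ Kₗ), bₖ = tr(Kₖ) = N and cₖ = yᵀKₖy. The O(N²M)
bottleneck, T, is replaced by the Hutchinson estimator

    T̂_{kl} = (1/B) (1/MₖMₗ) Σ_b  z_bᵀ Xₖ Xₖᵀ Xₗ Xₗᵀ z_b

over B (default 10) standard-normal probe vectors — only matrix–vector
products with the genotype matrix, accumulated in **one streaming pass**
over SNP blocks. Sufficient statistics are kept per contiguous SNP block
so that delete-one-block jackknife refits (default J = 100 blocks) cost
nothing extra and yield standard errors for every reported quantity,
plus a Z-test of eₖ = 1. Covariates are handled by projecting the
phenotype and the probe vectors onto their orthogonal complement.
Estimates are deliberately not constrained to be non-negative.

The package also ships:

* disjoint MAF × LD-score binning (the common 8-, 24- and 144-bin
  schemes), overlapping binary annotations, and continuous non-negative
  annotations (Xₖ → Xₖ·diag(√aₖ));
* in-sample windowed LD scores;
* an exact dense-GRM oracle for small cohorts (every randomized path is
  validated against it);
* a phenotype simulator with MAF/LD-coupled architectures
  σ²ₘ ∝ cₘ wₘᵇ [fₘ(1−fₘ)]ᵃ and a PLINK fixture writer.

## Worked example

```python
import numpy as np
from randhe import (annotations, simulate, fit_variance_components)

# simulate 2000 individuals x 5000 SNPs, h2 = 0.5, MAF-coupled effects
block, freqs, _ = simulate.standardized_dataset(2000, 5000, seed=1)
spec = simulate.ArchitectureSpec(h2=0.5, a_maf=0.75, seed=2)
y, truth = simulate.simulate_phenotype(block.values, freqs, spec)

# 8 bins: MAF split at 5% x quartiles of in-sample LD score
scores = annotations.compute_ld_scores(block, window_bp=100_000).scores
annot = annotations.make_maf_ld_partition(freqs, scores, (0.05,), 4)

fit = fit_variance_components(block.values, y, annot,
                              n_vectors=10, n_jackknife_blocks=100, seed=3)
print(fit.summary_line())
print(fit.to_frame()[["component", "M_k", "h2", "h2_SE", "enrichment", "Z"]])
```

prints (for these seeds):

```
h2_total 0.5429 (SE 0.0695)  sigma2_e 0.4839  N 2000  N_eff 1999  M 5000  K 8  B 10  J 100  seed 3
  component   M_k        h2     h2_SE  enrichment         Z
0  maf0_ld0   106  0.002420  0.011312    0.210243 -0.780630
1  maf0_ld1   114 -0.001838  0.008455   -0.148480 -1.633570
2  maf0_ld2   112  0.010300  0.007186    0.846971 -0.256059
3  maf0_ld3    98 -0.005483  0.005964   -0.515235 -2.659452
4  maf1_ld0  1144  0.108237  0.029963    0.871326 -0.596884
5  maf1_ld1  1136  0.154862  0.033629    1.255437  1.144285
6  maf1_ld2  1138  0.160346  0.033584    1.297616  1.279326
7  maf1_ld3  1152  0.114081  0.028279    0.911990 -0.407693
```

The genome-wide estimate 0.543 ± 0.070 covers the simulated h² = 0.5.
Per-bin heritability concentrates in the common-MAF bins (which hold
~92% of the SNPs); the small low-MAF bins show small, sometimes
negative point estimates — variance components are intentionally left
unconstrained, so noise around zero is reported as-is.

A thin CLI wraps the same pipeline for PLINK files on disk:

```bash
randhe simulate --n 2000 --m 5000 --h2 0.5 --seed 1 --out sim
randhe estimate --bfile sim --pheno sim.pheno --num-vec 10 --num-blocks 100 \
                --seed 3 --out run        # writes run.results.tsv + run.log
randhe validate --bfile sim --pheno sim.pheno --num-vec 10000 --out chk
```

Short narrative scripts, one per capability, live in `examples/`.

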
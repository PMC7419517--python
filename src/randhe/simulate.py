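"""Synthetic genotypes and phenotypes with known architecture truth.

Phenotypes follow a MAF/LD-coupled additive architecture: the variance of
the (standardized-scale) effect of SNP m is

    sigma_m^2 = S * c_m * w_m^b * [f_m (1 - f_m)]^a

where c_m is the causal indicator, f_m the minor allele frequency, w_m a
non-negative per-SNP score (an LD-taper weight in practice; 1 by
default), and S normalizes so that sum_m sigma_m^2 = h2.  Effects are
drawn normal, and y | beta ~ N(X beta, (1 - h2) I) on standardized X, so
E[var(y)] = 1.  Setting a = b = 0 gives the classical equal-variance
(GCTA-style) architecture; a = 0.75, b = 1 gives an LDAK-style one.

Genotypes are either independent binomial draws or a blockwise latent
Gaussian AR(rho) thresholded to the target allele frequencies, which
induces positive LD within blocks.  All randomness flows from one seed
through independent spawned streams (genotypes / causal mask / effects /
noise).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import plink
from .annotations import AnnotationSet
from .plink import StandardizedBlock


@dataclass
class ArchitectureSpec:
    """Generative parameters of the phenotype model."""

    h2: float = 0.5
    causal_fraction: float = 1.0  # proportion of SNPs with nonzero effect
    causal_maf_window: tuple[float, float] = (0.0, 0.5)
    a_maf: float = 0.0  # MAF-coupling exponent (0 or 0.75 in common use)
    b_ld: float = 0.0  # score-coupling exponent (0 or 1 in common use)
    per_snp_weights: np.ndarray | None = None  # w_m >= 0; 1.0 when None
    seed: int | None = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if not 0.0 < self.causal_fraction <= 1.0:
            raise ValueError("causal_fraction must lie in (0, 1]")


@dataclass
class SimTruth:
    """Per-SNP ground truth of a simulated phenotype."""

    causal_mask: np.ndarray  # bool, c_m
    per_snp_variance: np.ndarray  # sigma_m^2, sums to h2
    beta: np.ndarray  # realized standardized-scale effects
    h2: float

    def component_h2(self, annot: AnnotationSet) -> np.ndarray:
        """True h2_k = sum of sigma_m^2 over SNPs of each component."""
        return np.array(
            [self.per_snp_variance[idx].sum() for idx in annot.snp_indices]
        )


def _spawn(seed, n_children: int):
    if isinstance(seed, np.random.SeedSequence):
        return seed.spawn(n_children)
    return np.random.SeedSequence(seed).spawn(n_children)


def simulate_genotypes(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.01, 0.5),
    ld_rho: float = 0.0,
    ld_block_len: int = 50,
    spacing_bp: int = 1000,
    seed: int | None = 0,
    maf_sampler=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate allele-count genotypes for one chromosome.

    With ``ld_rho = 0`` counts are independent Binomial(2, f_m).  With
    ``ld_rho > 0`` a latent Gaussian AR(rho) within blocks of
    ``ld_block_len`` SNPs is thresholded (per haplotype) to match each
    SNP's marginal frequency, inducing positive LD inside blocks and none
    across.  Returns (counts, target_freqs, positions_bp); positions are
    evenly spaced.
    """
    freq_seq, geno_seq = _spawn(seed, 2)
    rng_f = np.random.default_rng(freq_seq)
    if maf_sampler is not None:
        freqs = np.asarray(maf_sampler(rng_f, m), dtype=float)
    else:
        freqs = rng_f.uniform(maf_range[0], maf_range[1], size=m)
    rng_g = np.random.default_rng(geno_seq)
    if ld_rho == 0.0:
        counts = rng_g.binomial(2, freqs[None, :], size=(n, m)).astype(np.int8)
    else:
        thresholds = stats.norm.ppf(freqs)  # P(Z < t) = f
        counts = np.zeros((n, m), dtype=np.int8)
        for _ in range(2):  # two independent haplotypes per individual
            latent = np.empty((n, m))
            for start in range(0, m, ld_block_len):
                stop = min(start + ld_block_len, m)
                width = stop - start
                innov = rng_g.standard_normal((n, width))
                z = np.empty((n, width))
                z[:, 0] = innov[:, 0]
                for t in range(1, width):
                    z[:, t] = ld_rho * z[:, t - 1] + np.sqrt(1 - ld_rho**2) * innov[:, t]
                latent[:, start:stop] = z
            counts += (latent < thresholds[None, :]).astype(np.int8)
    positions = (np.arange(m, dtype=np.int64) + 1) * spacing_bp
    return counts, freqs, positions


def select_causal(
    freqs: np.ndarray,
    causal_fraction: float,
    maf_window: tuple[float, float] = (0.0, 0.5),
    seed: int | None = 0,
) -> np.ndarray:
    """Uniformly sample round(p * M) causal SNPs among those whose MAF
    falls in the window."""
    freqs = np.asarray(freqs, dtype=float)
    m = len(freqs)
    maf = np.minimum(freqs, 1.0 - freqs)
    lo, hi = maf_window
    eligible = np.flatnonzero((maf >= lo) & (maf <= hi))
    if eligible.size == 0:
        raise ValueError(f"no SNPs with MAF in [{lo}, {hi}]")
    n_causal = max(1, int(round(causal_fraction * m)))
    if n_causal > eligible.size:
        raise ValueError(
            f"requested {n_causal} causal SNPs but only {eligible.size} lie in the MAF window"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(eligible, size=n_causal, replace=False)
    mask = np.zeros(m, dtype=bool)
    mask[chosen] = True
    return mask


def per_snp_variances(
    freqs: np.ndarray,
    causal_mask: np.ndarray,
    spec: ArchitectureSpec,
) -> np.ndarray:
    """sigma_m^2 = S c_m w_m^b [f_m(1-f_m)]^a, normalized to sum to h2."""
    freqs = np.asarray(freqs, dtype=float)
    maf = np.minimum(freqs, 1.0 - freqs)
    w = (
        np.ones_like(freqs)
        if spec.per_snp_weights is None
        else np.asarray(spec.per_snp_weights, dtype=float)
    )
    if np.any(w < 0):
        raise ValueError("per-SNP weights must be non-negative")
    raw = causal_mask * np.power(w, spec.b_ld) * np.power(maf * (1 - maf), spec.a_maf)
    total = raw.sum()
    if spec.h2 > 0 and total == 0:
        raise ValueError("all causal SNPs received zero architecture weight")
    return spec.h2 * raw / total if total > 0 else np.zeros_like(raw)


def simulate_phenotype(
    x_std: np.ndarray,
    freqs: np.ndarray,
    spec: ArchitectureSpec,
    causal_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, SimTruth]:
    """Draw one phenotype from standardized genotypes under the spec.

    Randomness splits into independent causal-mask / effect / noise
    streams derived from ``spec.seed``.
    """
    n, m = x_std.shape
    causal_seq, beta_seq, noise_seq = _spawn(spec.seed, 3)
    if causal_mask is None:
        causal_mask = select_causal(
            freqs, spec.causal_fraction, spec.causal_maf_window, seed=causal_seq
        )
    sigma_m2 = per_snp_variances(freqs, causal_mask, spec)
    rng_b = np.random.default_rng(beta_seq)
    beta = rng_b.standard_normal(m) * np.sqrt(sigma_m2)
    rng_e = np.random.default_rng(noise_seq)
    y = x_std @ beta + rng_e.standard_normal(n) * np.sqrt(1.0 - spec.h2)
    truth = SimTruth(
        causal_mask=causal_mask, per_snp_variance=sigma_m2, beta=beta, h2=spec.h2
    )
    return y, truth


def write_fixture(
    prefix: str | os.PathLike,
    counts: np.ndarray,
    positions: np.ndarray,
    y: np.ndarray,
    truth: SimTruth | None = None,
    chromosome: str = "1",
) -> None:
    """Write a PLINK BED/BIM/FAM trio plus .pheno (and .truth.tsv)."""
    n, m = counts.shape
    bim = pd.DataFrame(
        {
            "chrom": chromosome,
            "id": [f"snp{j+1}" for j in range(m)],
            "cm": 0,
            "bp": np.asarray(positions, dtype=np.int64),
            "a1": "A",
            "a2": "G",
        }
    )
    fam = pd.DataFrame(
        {
            "fid": [f"F{i+1}" for i in range(n)],
            "iid": [f"I{i+1}" for i in range(n)],
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    plink.write_plink(prefix, counts, bim, fam)
    prefix = os.fspath(prefix)
    pheno = fam[["fid", "iid"]].copy()
    pheno["pheno"] = y
    pheno.to_csv(prefix + ".pheno", sep="\t", header=False, index=False)
    if truth is not None:
        pd.DataFrame(
            {
                "id": bim["id"],
                "causal": truth.causal_mask.astype(int),
                "sigma2_m": truth.per_snp_variance,
                "beta": truth.beta,
            }
        ).to_csv(prefix + ".truth.tsv", sep="\t", index=False)


def standardized_dataset(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.01, 0.5),
    ld_rho: float = 0.0,
    seed: int | None = 0,
    **kwargs,
) -> tuple[StandardizedBlock, np.ndarray, np.ndarray]:
    """Convenience: simulate genotypes and return them standardized.

    Returns (block, in-sample freqs, positions).  Monomorphic draws are
    resampled column-wise to keep the design full of usable SNPs.
    """
    counts, freqs, positions = simulate_genotypes(
        n, m, maf_range=maf_range, ld_rho=ld_rho, seed=seed, **kwargs
    )
    emp, _ = plink.allele_stats(counts)
    bad = np.flatnonzero((emp <= 0) | (emp >= 1))
    rng = np.random.default_rng(_spawn(seed, 3)[2])
    while bad.size:
        counts[:, bad] = rng.binomial(2, freqs[bad][None, :], size=(n, bad.size))
        emp, _ = plink.allele_stats(counts)
        bad = np.flatnonzero((emp <= 0) | (emp >= 1))
    records = [
        plink.SnpRecord(id=f"snp{j+1}", chromosome="1", position_bp=int(positions[j]))
        for j in range(m)
    ]
    block = plink.standardize(counts, snps=records)
    return block, emp, positions
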
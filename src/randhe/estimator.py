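"""Randomized method-of-moments estimation of variance components.

The model is y = sum_k X_k beta_k + eps with per-category effect variance
sigma_k^2 / M_k and residual variance sigma_e^2.  Matching the empirical
covariance y y^T to its population value sum_k sigma_k^2 K_k + sigma_e^2 I
(K_k = X_k X_k^T / M_k) gives the normal equations

    [ T   b ] [ sigma_g^2 ]   [ c     ]
    [ b^T  N ] [ sigma_e^2 ] = [ y^T y ]

with T_{kl} = tr(K_k K_l), b_k = tr(K_k) = N and c_k = y^T K_k y.  The
O(N^2 M) bottleneck tr(K_k K_l) is replaced by a Hutchinson estimate

    T_hat_{kl} = (1/B) (1/(M_k M_l)) sum_b z_b^T X_k X_k^T X_l X_l^T z_b

over B standard-normal probe vectors, which needs only matrix-vector
products with the genotype matrix.  All sufficient statistics are
accumulated in a single streaming pass over SNP blocks and are kept
per jackknife block so that delete-one-block refits never touch the
genotypes again.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .annotations import AnnotationSet
from .plink import StandardizedBlock

DEFAULT_NUM_VECTORS = 10
DEFAULT_NUM_JACKKNIFE_BLOCKS = 100
CONDITION_CUTOFF = 1e12


@dataclass
class RandomSketch:
    """B standard-normal probe vectors used for trace estimation."""

    vectors: np.ndarray  # N x B
    seed: int | None = None

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[1]


def make_sketch(
    n: int, n_vectors: int = DEFAULT_NUM_VECTORS, seed: int | None = 0
) -> RandomSketch:
    """Draw B i.i.d. standard-normal probe vectors, reproducibly."""
    if n < 1 or n_vectors < 1:
        raise ValueError("n and n_vectors must be positive")
    rng = np.random.default_rng(seed)
    return RandomSketch(vectors=rng.standard_normal((n, n_vectors)), seed=seed)


@dataclass
class Projector:
    """Orthogonal projector onto the complement of a covariate span."""

    q: np.ndarray  # N x C orthonormal basis of the covariate column space

    @property
    def n_covariates(self) -> int:
        return self.q.shape[1]

    def apply(self, v: np.ndarray) -> np.ndarray:
        """(I - Q Q^T) v along the first axis."""
        flat = v.reshape(v.shape[0], -1)
        out = flat - self.q @ (self.q.T @ flat)
        return out.reshape(v.shape)


def project_covariates(
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    add_intercept: bool = True,
) -> tuple[np.ndarray, int, Projector]:
    """Residualize the phenotype on covariates (plus an intercept).

    Returns the projected phenotype, the effective sample size
    n_eff = N - rank(W), and the projector to apply to probe vectors and
    genotype images so that all moments are computed on projected data.
    Rank-deficient covariate columns are dropped with a warning.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    cols = [np.ones((n, 1))] if add_intercept else []
    if covariates is not None:
        w = np.atleast_2d(np.asarray(covariates, dtype=float))
        if w.shape[0] != n:
            w = w.T
        cols.append(w)
    if not cols:
        raise ValueError("no covariates and no intercept: nothing to project")
    w = np.hstack(cols)
    u, s, _ = np.linalg.svd(w, full_matrices=False)
    keep = s > 1e-10 * s[0]
    if not keep.all():
        import warnings

        warnings.warn(
            f"dropping {int((~keep).sum())} linearly dependent covariate column(s)",
            stacklevel=2,
        )
    proj = Projector(q=u[:, keep])
    return proj.apply(y), n - proj.n_covariates, proj


@dataclass
class MomAccumulator:
    """Single-pass sufficient statistics, partitioned by jackknife block.

    ``sketch_images[j, k]`` holds the N x B partial image
    sum_{m in component k, jackknife block j} x_m (x_m . z_b); summing
    over j recovers X_k X_k^T z_b for the full data.
    """

    sketch_images: np.ndarray  # (J, K, N, B)
    quad_partials: np.ndarray  # (K, J): partials of ||X_k^T y||^2
    snp_counts: np.ndarray  # (K, J): M_{k,j}
    weight_partials: np.ndarray  # (K, J): sums of a_{k,m}; equals snp_counts when binary
    yty: float
    n: int
    n_eff: int
    annot: AnnotationSet
    projector: Projector | None = None

    @property
    def n_jackknife_blocks(self) -> int:
        return self.sketch_images.shape[0]

    @property
    def n_vectors(self) -> int:
        return self.sketch_images.shape[3]


def jackknife_boundaries(m: int, n_blocks: int) -> np.ndarray:
    """Split M SNPs (in genome order) into J near-equal contiguous blocks."""
    if n_blocks < 1 or n_blocks > m:
        raise ValueError("need 1 <= n_blocks <= number of SNPs")
    return np.linspace(0, m, n_blocks + 1).astype(int)


def iter_matrix_blocks(
    x: np.ndarray,
    block_size: int = 1000,
    snps: Sequence | None = None,
) -> Iterator[StandardizedBlock]:
    """Wrap an in-memory standardized matrix as a stream of blocks."""
    m = x.shape[1]
    for i, start in enumerate(range(0, m, block_size)):
        stop = min(start + block_size, m)
        yield StandardizedBlock(
            values=x[:, start:stop],
            snps=list(snps[start:stop]) if snps is not None else [],
            block_index=i,
        )


def accumulate(
    blocks: Iterable[StandardizedBlock],
    annot: AnnotationSet,
    sketch: RandomSketch,
    y: np.ndarray,
    n_jackknife_blocks: int = DEFAULT_NUM_JACKKNIFE_BLOCKS,
    projector: Projector | None = None,
) -> MomAccumulator:
    """Stream standardized SNP blocks once, scattering each block's probe
    and phenotype products into its variance component(s) and jackknife
    block.  ``y`` must already be centered / covariate-projected.
    """
    y = np.asarray(y, dtype=float)
    z = sketch.vectors
    if projector is not None:
        z = projector.apply(z)
    n, b = z.shape
    m_total = annot.n_snps
    j_edges = jackknife_boundaries(m_total, n_jackknife_blocks)
    j_of_snp = np.searchsorted(j_edges, np.arange(m_total), side="right") - 1
    k_count = annot.n_components
    images = np.zeros((n_jackknife_blocks, k_count, n, b))
    quad = np.zeros((k_count, n_jackknife_blocks))
    counts = np.zeros((k_count, n_jackknife_blocks), dtype=np.int64)
    wsums = np.zeros((k_count, n_jackknife_blocks))
    zy = np.hstack([z, y[:, None]])
    offset = 0
    for blk in blocks:
        x = blk.values
        if x.shape[0] != n:
            raise ValueError("genotype block and sketch disagree on N")
        stop = offset + x.shape[1]
        w_all = x.T @ zy  # (m_block, B+1): probe images and X^T y in one GEMM
        for k, local, a in annot.slice_block(offset, stop):
            jk = j_of_snp[offset + local]
            for j in np.unique(jk):
                sel = jk == j
                cols = local[sel]
                aw = a[sel]
                wk = w_all[cols]
                if np.all(aw == 1.0):
                    images[j, k] += x[:, cols] @ wk[:, :b]
                    quad[k, j] += float(wk[:, b] @ wk[:, b])
                else:  # continuous weights: X_k diag(sqrt(a_k))
                    images[j, k] += x[:, cols] @ (aw[:, None] * wk[:, :b])
                    quad[k, j] += float(aw @ (wk[:, b] ** 2))
                counts[k, j] += cols.size
                wsums[k, j] += float(aw.sum())
        offset = stop
    if offset != m_total:
        raise ValueError(
            f"streamed {offset} SNPs but the annotation map covers {m_total}"
        )
    if np.any(counts.sum(axis=1) == 0):
        empty = [annot.names[k] for k in np.flatnonzero(counts.sum(axis=1) == 0)]
        raise ValueError(f"components with zero streamed SNPs: {empty}")
    if projector is not None:
        # project images so every inner product is over projected data
        flat = images.reshape(n_jackknife_blocks * k_count, n, b)
        for i in range(flat.shape[0]):
            flat[i] = projector.apply(flat[i])
        n_eff = n - projector.n_covariates
    else:
        n_eff = n
    return MomAccumulator(
        sketch_images=images,
        quad_partials=quad,
        snp_counts=counts,
        weight_partials=wsums,
        yty=float(y @ y),
        n=n,
        n_eff=n_eff,
        annot=annot,
        projector=projector,
    )


@dataclass
class MomSystem:
    """Assembled normal-equation ingredients."""

    t_hat: np.ndarray  # K x K
    b_vec: np.ndarray  # K (each entry = effective N)
    c_vec: np.ndarray  # K
    yty: float
    n_eff: int


def _system_from_parts(
    v: np.ndarray,
    quad: np.ndarray,
    m_k: np.ndarray,
    yty: float,
    n_eff: int,
    b: int,
    trace_factor: np.ndarray | None = None,
) -> MomSystem:
    """Normal-equation pieces from summed images v (K, N, B).

    ``trace_factor`` is mean(a_k) per component: tr(K_k) = N * mean(a_k),
    which is N exactly for binary membership.
    """
    k = v.shape[0]
    flat = v.reshape(k, -1)
    gram = flat @ flat.T  # sums the b-inner-products in one GEMM
    t_hat = gram / (b * np.outer(m_k, m_k))
    c_vec = quad / m_k
    if trace_factor is None:
        trace_factor = np.ones(k)
    return MomSystem(
        t_hat=t_hat,
        b_vec=n_eff * trace_factor,
        c_vec=c_vec,
        yty=yty,
        n_eff=n_eff,
    )


def assemble_system(acc: MomAccumulator) -> MomSystem:
    """Full-data T_hat, b, c from the accumulator."""
    v = acc.sketch_images.sum(axis=0)  # (K, N, B)
    m_k = acc.snp_counts.sum(axis=1).astype(float)
    tau = acc.weight_partials.sum(axis=1) / m_k
    return _system_from_parts(
        v,
        acc.quad_partials.sum(axis=1),
        m_k,
        acc.yty,
        acc.n_eff,
        acc.n_vectors,
        trace_factor=tau,
    )


def solve_system(system: MomSystem) -> np.ndarray:
    """Solve the bordered (K+1) x (K+1) normal equations.

    Estimates are deliberately unconstrained: negative variance-component
    estimates are reported as-is.  Ill-conditioned or singular systems
    fall back to a minimum-norm least-squares solution.
    """
    k = system.t_hat.shape[0]
    a = np.empty((k + 1, k + 1))
    a[:k, :k] = system.t_hat
    a[:k, k] = system.b_vec
    a[k, :k] = system.b_vec
    a[k, k] = system.n_eff
    rhs = np.concatenate([system.c_vec, [system.yty]])
    if np.linalg.cond(a) > CONDITION_CUTOFF:
        import warnings

        warnings.warn(
            "normal equations ill-conditioned; using least-squares solution",
            stacklevel=2,
        )
        return np.linalg.lstsq(a, rhs, rcond=None)[0]
    return np.linalg.solve(a, rhs)


@dataclass
class Summary:
    """Heritability and enrichment summaries derived from sigma^2."""

    sigma2: np.ndarray  # (K+1,), last entry residual
    h2_total: float
    h2_per_component: np.ndarray
    enrichment: np.ndarray


def summarize(sigma2: np.ndarray, annot: AnnotationSet) -> Summary:
    """Total and per-component SNP heritability plus enrichment.

    Disjoint mode: h2_k = sigma_k^2 / (sum sigma^2 + sigma_e^2).
    Overlapping annotations: h2_k sums, over the SNPs of annotation k,
    the per-SNP variance contributed by every annotation containing the
    SNP.  Continuous annotations scale each component's contribution by
    its mean weight.  Enrichment e_k = (h2_k / h2_total) / (M_k / M),
    with null value 1; undefined (NaN) when h2_total = 0.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    k = annot.n_components
    m_k = annot.component_sizes.astype(float)
    m = float(annot.n_snps)
    sig_g, sig_e = sigma2[:k], sigma2[k]
    if annot.mode == "continuous":
        mean_w = np.array([w.sum() for w in annot.weights]) / m_k
        genetic = sig_g * mean_w
        denom = genetic.sum() + sig_e
        h2_k = genetic / denom if denom != 0 else np.full(k, np.nan)
        h2_tot = genetic.sum() / denom if denom != 0 else np.nan
    else:
        denom = sig_g.sum() + sig_e
        h2_tot = sig_g.sum() / denom if denom != 0 else np.nan
        if annot.mode == "disjoint":
            h2_k = sig_g / denom if denom != 0 else np.full(k, np.nan)
        else:  # overlapping: per-SNP density summed over covering annotations
            density = np.zeros(int(m))
            for idx, s2, mk in zip(annot.snp_indices, sig_g, m_k):
                density[idx] += s2 / mk
            h2_k = np.array(
                [density[idx].sum() for idx in annot.snp_indices]
            ) / denom if denom != 0 else np.full(k, np.nan)
    if h2_tot == 0 or not np.isfinite(h2_tot):
        enrich = np.full(k, np.nan)
    else:
        enrich = (h2_k / h2_tot) / (m_k / m)
    return Summary(
        sigma2=sigma2, h2_total=float(h2_tot), h2_per_component=h2_k, enrichment=enrich
    )
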
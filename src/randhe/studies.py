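"""Replicate simulation studies: bias, calibration and specificity.

The study design mirrors common practice for evaluating heritability
estimators: genotypes are simulated once per architecture and many
phenotype replicates are drawn on that fixed genotype matrix.  For
point-estimate studies the trace sketch is the only part of the
estimator that does not depend on the phenotype, so a pool of
independently seeded sketches is computed up front through the streaming
accumulator and cycled across replicates; sketch noise still averages
out over the pool while the O(NMB) probe pass is amortised.  Studies
that assess jackknife standard errors or the enrichment Z-test run the
full per-replicate fit instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import estimator, simulate
from .annotations import AnnotationSet
from .estimator import MomSystem, solve_system, summarize
from .fitting import VarianceComponentFit, fit_variance_components
from .simulate import ArchitectureSpec, SimTruth


def _seq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _factorize(system: MomSystem):
    """LU factorization of the bordered matrix (or None for the
    ill-conditioned least-squares fallback)."""
    from scipy.linalg import lu_factor

    k = system.t_hat.shape[0]
    a = np.empty((k + 1, k + 1))
    a[:k, :k] = system.t_hat
    a[:k, k] = system.b_vec
    a[k, :k] = system.b_vec
    a[k, k] = system.n_eff
    if np.linalg.cond(a) > estimator.CONDITION_CUTOFF:
        return a, None
    return a, lu_factor(a)


def _solve_factored(factor, rhs: np.ndarray) -> np.ndarray:
    from scipy.linalg import lu_solve

    a, lu = factor
    if lu is None:
        return np.linalg.lstsq(a, rhs, rcond=None)[0]
    return lu_solve(lu, rhs)


@dataclass
class ReplicateStudy:
    """Point estimates and truth across phenotype replicates."""

    h2_hat: np.ndarray  # (R,)
    h2_per_component: np.ndarray  # (R, K)
    true_h2_per_component: np.ndarray  # (R, K)
    annot: AnnotationSet

    @property
    def n_reps(self) -> int:
        return len(self.h2_hat)

    def relative_bias(self, true_h2: float) -> float:
        """(mean(h2_hat) - h2) / h2."""
        return float((self.h2_hat.mean() - true_h2) / true_h2)


def sketch_systems(
    x_std: np.ndarray,
    annot: AnnotationSet,
    n_vectors: int,
    seeds,
    n_eff: int,
) -> list[MomSystem]:
    """T_hat (and trace vector) for each seeded sketch.

    Computes the probe images per component on contiguous column copies —
    identical (to rounding) to running the streaming accumulator with one
    jackknife block, but faster when many sketches are needed.  Centering
    the phenotype leaves the images unchanged (standardized columns sum
    to zero), so only n_eff enters.
    """
    n = x_std.shape[0]
    k = annot.n_components
    m_k = annot.component_sizes.astype(float)
    xs = []
    for idx, w in zip(annot.snp_indices, annot.weights):
        xk = x_std[:, idx]
        if not np.all(w == 1.0):
            xk = xk * np.sqrt(w)
        xs.append(np.ascontiguousarray(xk))
    tau = np.array([w.sum() for w in annot.weights]) / m_k
    systems = []
    for s in seeds:
        z = estimator.make_sketch(n, n_vectors, seed=s).vectors
        v = np.empty((k, n * n_vectors))
        for i, xk in enumerate(xs):
            v[i] = (xk @ (xk.T @ z)).ravel()
        gram = v @ v.T
        t_hat = gram / (n_vectors * np.outer(m_k, m_k))
        systems.append(
            MomSystem(
                t_hat=t_hat,
                b_vec=n_eff * tau,
                c_vec=np.zeros(k),
                yty=0.0,
                n_eff=n_eff,
            )
        )
    return systems


def replicate_point_estimates(
    x_std: np.ndarray,
    freqs: np.ndarray,
    annot: AnnotationSet,
    spec: ArchitectureSpec,
    n_reps: int,
    n_vectors: int = 10,
    sketch_pool: int = 100,
    seed: int | None = 0,
    chunk: int = 250,
) -> ReplicateStudy:
    """Estimate h2 on many phenotype replicates over fixed genotypes.

    Each replicate draws its own causal mask (when the causal fraction is
    below 1), effect sizes and noise; replicate r uses sketch
    ``r % sketch_pool`` from the pool.  Phenotypes are centered, so
    n_eff = N - 1 throughout.
    """
    n, m = x_std.shape
    ss = _seq(seed)
    sketch_seeds, pheno_seed = ss.spawn(2)
    n_eff = n - 1
    pool = sketch_systems(
        x_std, annot, n_vectors, sketch_seeds.spawn(sketch_pool), n_eff
    )
    rng = np.random.default_rng(pheno_seed)
    k = annot.n_components
    h2_hat = np.empty(n_reps)
    h2_comp = np.empty((n_reps, k))
    true_comp = np.empty((n_reps, k))
    fixed_mask = None
    if spec.causal_fraction == 1.0 and spec.causal_maf_window == (0.0, 0.5):
        fixed_mask = np.ones(m, dtype=bool)
    # pre-factorize each pool system's bordered matrix once; the RHS is
    # the only phenotype-dependent part
    factors = [_factorize(s) for s in pool]
    done = 0
    while done < n_reps:
        r = min(chunk, n_reps - done)
        sig2 = np.empty((m, r))
        if fixed_mask is not None:
            sig2[:] = simulate.per_snp_variances(freqs, fixed_mask, spec)[:, None]
        else:
            for i in range(r):
                mask = simulate.select_causal(
                    freqs,
                    spec.causal_fraction,
                    spec.causal_maf_window,
                    seed=rng.integers(2**31),
                )
                sig2[:, i] = simulate.per_snp_variances(freqs, mask, spec)
        beta = rng.standard_normal((m, r)) * np.sqrt(sig2)
        y = x_std @ beta + rng.standard_normal((n, r)) * np.sqrt(1.0 - spec.h2)
        y -= y.mean(axis=0, keepdims=True)
        q2 = (x_std.T @ y) ** 2  # (M, R)
        yty = (y * y).sum(axis=0)
        c_mat = np.stack(
            [
                (w @ q2[idx]) / len(idx)
                for idx, w in zip(annot.snp_indices, annot.weights)
            ]
        )  # (K, R)
        rhs = np.vstack([c_mat, yty[None, :]])  # (K+1, R)
        sigma = np.empty((k + 1, r))
        pool_idx = (done + np.arange(r)) % len(pool)
        for p in np.unique(pool_idx):
            sel = pool_idx == p
            sigma[:, sel] = _solve_factored(factors[p], rhs[:, sel])
        for i in range(r):
            summ = summarize(sigma[:, i], annot)
            h2_hat[done + i] = summ.h2_total
            h2_comp[done + i] = summ.h2_per_component
            true_comp[done + i] = np.array(
                [sig2[idx, i].sum() for idx in annot.snp_indices]
            )
        done += r
    return ReplicateStudy(
        h2_hat=h2_hat,
        h2_per_component=h2_comp,
        true_h2_per_component=true_comp,
        annot=annot,
    )


def replicate_jackknife_fits(
    x_std: np.ndarray,
    freqs: np.ndarray,
    annot: AnnotationSet,
    spec: ArchitectureSpec,
    n_reps: int,
    n_vectors: int = 10,
    n_jackknife_blocks: int = 100,
    seed: int | None = 0,
) -> tuple[list[VarianceComponentFit], list[SimTruth]]:
    """Full per-replicate fits (fresh sketch, full jackknife) for studies
    of standard-error calibration and the enrichment Z-test."""
    ss = _seq(seed)
    fits, truths = [], []
    for child in ss.spawn(n_reps):
        pheno_seed, sketch_seed = child.spawn(2)
        y, truth = simulate.simulate_phenotype(
            x_std, freqs, replace(spec, seed=pheno_seed)
        )
        fit = fit_variance_components(
            x_std,
            y,
            annot,
            n_vectors=n_vectors,
            n_jackknife_blocks=n_jackknife_blocks,
            seed=sketch_seed,
        )
        fits.append(fit)
        truths.append(truth)
    return fits, truths
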
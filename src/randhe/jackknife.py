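"""Delete-one-block jackknife over contiguous SNP blocks.

The streaming accumulator keeps its sufficient statistics per jackknife
block, so the delete-block systems are reassembled by subtraction —
v_{k,b}^{(-j)} = v_{k,b} - u_{k,b,j}, with matching corrections to the
quadratic forms and SNP counts — and re-solved without re-reading any
genotypes.  Standard errors use the block-jackknife formula

    se^2 = ((J-1)/J) * sum_j (theta_{-j} - mean_j theta_{-j})^2

and enrichment is tested against its null value of 1 with a normal
Z-statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimator import (
    MomAccumulator,
    MomSystem,
    Summary,
    _system_from_parts,
    assemble_system,
    solve_system,
    summarize,
)


@dataclass
class JackknifeResult:
    """Point estimates with delete-block replicates and jackknife SEs."""

    point: Summary
    delete_block: list[Summary]
    se_sigma2: np.ndarray
    se_h2_total: float
    se_h2_per_component: np.ndarray
    se_enrichment: np.ndarray
    n_blocks: int
    dropped_components: list[tuple[int, int]]  # (block j, component k) emptied


def jackknife_se(point: np.ndarray | float, delete_values: np.ndarray) -> np.ndarray:
    """Block-jackknife SE from J delete-one-block estimates."""
    dv = np.atleast_2d(np.asarray(delete_values, dtype=float))
    j = dv.shape[0]
    if j < 2:
        raise ValueError("jackknife needs at least 2 blocks")
    dev = dv - dv.mean(axis=0, keepdims=True)
    var = (j - 1) / j * (dev * dev).sum(axis=0)
    return np.sqrt(var)


def delete_block_systems(acc: MomAccumulator) -> list[MomSystem]:
    """Reassemble the normal equations with each jackknife block removed."""
    j_blocks, k, n, b = acc.sketch_images.shape
    u = acc.sketch_images.reshape(j_blocks, k, n * b)
    v = u.sum(axis=0)  # (K, N*B)
    gram_full = v @ v.T
    cross = v @ u.reshape(j_blocks * k, n * b).T  # (K, J*K): <v_k, u_{l,j}>
    cross = cross.reshape(k, j_blocks, k).transpose(1, 0, 2)  # (J, K_v, K_u)
    own = np.matmul(u, u.transpose(0, 2, 1))  # (J, K, K)
    m_kj = acc.snp_counts.astype(float)
    m_k = m_kj.sum(axis=1)
    quad_k = acc.quad_partials.sum(axis=1)
    wsum_k = acc.weight_partials.sum(axis=1)
    systems = []
    for j in range(j_blocks):
        gram = gram_full - cross[j] - cross[j].T + own[j]
        m_del = m_k - m_kj[:, j]
        if np.any(m_del == 0):
            systems.append(None)
            continue
        t_hat = gram / (b * np.outer(m_del, m_del))
        c_vec = (quad_k - acc.quad_partials[:, j]) / m_del
        tau = (wsum_k - acc.weight_partials[:, j]) / m_del
        systems.append(
            MomSystem(
                t_hat=t_hat,
                b_vec=acc.n_eff * tau,
                c_vec=c_vec,
                yty=acc.yty,
                n_eff=acc.n_eff,
            )
        )
    return systems


def delete_block_fits(acc: MomAccumulator) -> list[Summary]:
    """Delete-one-block variance-component fits (genotypes not re-read).

    A delete-block fit whose deletion empties a component is refit with
    that component dropped; its summaries carry NaN for the dropped
    component.
    """
    annot = acc.annot
    fits: list[Summary] = []
    for j, system in enumerate(delete_block_systems(acc)):
        if system is not None:
            sigma2 = solve_system(system)
            fits.append(_summarize_deleted(sigma2, acc, j))
            continue
        # component emptied by deletion: drop it and flag via NaN entries
        keep = np.flatnonzero(acc.snp_counts.sum(axis=1) - acc.snp_counts[:, j] > 0)
        sub = _subset_system(acc, j, keep)
        sigma_sub = solve_system(sub)
        k = annot.n_components
        sigma2 = np.full(k + 1, np.nan)
        sigma2[keep] = sigma_sub[:-1]
        sigma2[k] = sigma_sub[-1]
        fits.append(_summarize_deleted(sigma2, acc, j, keep=keep))
    return fits


def _subset_system(acc: MomAccumulator, j: int, keep: np.ndarray) -> MomSystem:
    """Delete-block system restricted to the surviving components."""
    j_blocks, k, n, b = acc.sketch_images.shape
    v = acc.sketch_images.sum(axis=0) - acc.sketch_images[j]  # (K, N, B)
    v = v[keep].reshape(len(keep), n * b)
    m_del = (acc.snp_counts.sum(axis=1) - acc.snp_counts[:, j]).astype(float)[keep]
    quad = (acc.quad_partials.sum(axis=1) - acc.quad_partials[:, j])[keep]
    tau = (acc.weight_partials.sum(axis=1) - acc.weight_partials[:, j])[keep] / m_del
    gram = v @ v.T
    return MomSystem(
        t_hat=gram / (b * np.outer(m_del, m_del)),
        b_vec=acc.n_eff * tau,
        c_vec=quad / m_del,
        yty=acc.yty,
        n_eff=acc.n_eff,
    )


def _summarize_deleted(
    sigma2: np.ndarray, acc: MomAccumulator, j: int, keep: np.ndarray | None = None
) -> Summary:
    """Summaries for a delete-block fit, using the reduced M_k and M."""
    annot = acc.annot
    k = annot.n_components
    m_del = acc.snp_counts.sum(axis=1) - acc.snp_counts[:, j]
    if annot.mode == "disjoint":
        m_total = float(m_del.sum())
    else:
        from .estimator import jackknife_boundaries

        edges = jackknife_boundaries(annot.n_snps, acc.n_jackknife_blocks)
        m_total = float(annot.n_snps - (edges[j + 1] - edges[j]))
    sig_g = np.where(np.isnan(sigma2[:k]), 0.0, sigma2[:k])
    sig_e = sigma2[k]
    if annot.mode == "continuous":
        mean_w = np.array(
            [w.sum() / max(len(ix), 1) for ix, w in zip(annot.snp_indices, annot.weights)]
        )
        genetic = sig_g * mean_w
    else:
        genetic = sig_g
    denom = genetic.sum() + sig_e
    h2_tot = genetic.sum() / denom if denom != 0 else np.nan
    if annot.mode == "overlapping":
        density = np.zeros(annot.n_snps)
        for idx, s2, mk in zip(annot.snp_indices, sig_g, m_del):
            density[idx] += s2 / max(mk, 1.0)
        h2_k = np.array([density[idx].sum() for idx in annot.snp_indices]) / denom
    else:
        h2_k = genetic / denom if denom != 0 else np.full(k, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        enrich = (h2_k / h2_tot) / (m_del / m_total)
    if keep is not None:
        mask = np.ones(k, dtype=bool)
        mask[keep] = False
        h2_k = h2_k.copy()
        enrich = enrich.copy()
        h2_k[mask] = np.nan
        enrich[mask] = np.nan
    return Summary(
        sigma2=sigma2,
        h2_total=float(h2_tot),
        h2_per_component=h2_k,
        enrichment=enrich,
    )


def jackknife_fit(acc: MomAccumulator) -> JackknifeResult:
    """Full-data fit plus delete-block SEs for every reported quantity."""
    point = summarize(solve_system(assemble_system(acc)), acc.annot)
    fits = delete_block_fits(acc)
    sig = np.array([f.sigma2 for f in fits])
    h2t = np.array([f.h2_total for f in fits])
    h2k = np.array([f.h2_per_component for f in fits])
    enr = np.array([f.enrichment for f in fits])
    dropped = [
        (j, int(kk))
        for j in range(acc.n_jackknife_blocks)
        for kk in np.flatnonzero(
            acc.snp_counts.sum(axis=1) - acc.snp_counts[:, j] == 0
        )
    ]
    return JackknifeResult(
        point=point,
        delete_block=fits,
        se_sigma2=jackknife_se(point.sigma2, sig),
        se_h2_total=float(jackknife_se(point.h2_total, h2t[:, None])[0]),
        se_h2_per_component=jackknife_se(point.h2_per_component, h2k),
        se_enrichment=jackknife_se(point.enrichment, enr),
        n_blocks=acc.n_jackknife_blocks,
        dropped_components=dropped,
    )


def enrichment_test(
    enrichment: np.ndarray, se: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Z-test of the null hypothesis of no enrichment (e_k = 1).

    Components with zero (or undefined) SE get NaN statistics.
    """
    enrichment = np.atleast_1d(np.asarray(enrichment, dtype=float))
    se = np.atleast_1d(np.asarray(se, dtype=float))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, (enrichment - 1.0) / se, np.nan)
    p = np.where(np.isfinite(z), 2.0 * stats.norm.sf(np.abs(z)), np.nan)
    return z, p
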
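"""Exact dense reference implementation for small cohorts.

Builds the per-category genetic relatedness matrices K_k = X_k X_k^T / M_k
explicitly, computes the exact traces T_{kl} = tr(K_k K_l) and quadratic
forms y^T K_k y, and solves the same bordered normal equations as the
randomized estimator.  Every randomized code path is validated against
this module; it is installed (not test-only) so users can cross-check
small cohorts, with a size guard against accidental O(N^2) blow-ups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotations import AnnotationSet
from .estimator import MomSystem, solve_system

SIZE_GUARD = 5000


@dataclass
class DenseGrm:
    """Explicit N x N genetic relatedness matrix for one category."""

    matrix: np.ndarray
    component: int = 0
    m_snps: int = 0


def exact_grm(x_std: np.ndarray, component: int = 0, weights: np.ndarray | None = None) -> DenseGrm:
    """K = X diag(a) X^T / M from standardized columns (optionally weighted).

    M is the number of columns; with standardized input and unit weights
    tr(K) = N exactly.
    """
    n, m = x_std.shape
    if n > SIZE_GUARD:
        raise ValueError(f"N={n} exceeds the dense-oracle size guard ({SIZE_GUARD})")
    if weights is not None:
        xw = x_std * np.sqrt(np.asarray(weights, dtype=float))
    else:
        xw = x_std
    return DenseGrm(matrix=(xw @ xw.T) / m, component=component, m_snps=m)


def component_grms(x_std: np.ndarray, annot: AnnotationSet) -> list[DenseGrm]:
    """One dense GRM per variance component of the annotation map."""
    return [
        exact_grm(x_std[:, idx], component=k, weights=w if annot.mode == "continuous" else None)
        for k, (idx, w) in enumerate(zip(annot.snp_indices, annot.weights))
    ]


def exact_system(grms: list[DenseGrm], y: np.ndarray, n_eff: int | None = None) -> MomSystem:
    """Exact T, b, c for the bordered normal equations."""
    y = np.asarray(y, dtype=float)
    n = grms[0].matrix.shape[0]
    k = len(grms)
    t = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            t[i, j] = t[j, i] = float(np.sum(grms[i].matrix * grms[j].matrix))
    c = np.array([float(y @ g.matrix @ y) for g in grms])
    if n_eff is None:
        n_eff = n
    # b_k = tr(K_k): exactly N for standardized unit-weight columns,
    # N * mean(a_k) under continuous weights; scaled by n_eff/N when
    # covariate degrees of freedom have been removed.
    b = np.array([np.trace(g.matrix) for g in grms]) * (n_eff / n)
    return MomSystem(t_hat=t, b_vec=b, c_vec=c, yty=float(y @ y), n_eff=n_eff)


def exact_mom_fit(
    grms: list[DenseGrm], y: np.ndarray, n_eff: int | None = None
) -> np.ndarray:
    """Exact method-of-moments solve; verifies first-order optimality.

    The normal-equation solution must be a stationary point of the
    Frobenius objective || y y^T - (sum_k sigma_k^2 K_k + sigma_e^2 I) ||_F^2;
    the gradient at the solution is checked to vanish (relative to the
    problem scale) as a safeguard against assembly errors.
    """
    system = exact_system(grms, y, n_eff)
    sigma2 = solve_system(system)
    k = len(grms)
    # gradient of the Frobenius objective wrt sigma^2: 2(A s - rhs)
    a = np.empty((k + 1, k + 1))
    a[:k, :k] = system.t_hat
    a[:k, k] = a[k, :k] = system.b_vec
    a[k, k] = system.n_eff
    rhs = np.concatenate([system.c_vec, [system.yty]])
    grad = 2.0 * (a @ sigma2 - rhs)
    scale = max(np.abs(rhs).max(), 1.0)
    if np.abs(grad).max() > 1e-6 * scale:
        raise RuntimeError("normal-equation solution is not a stationary point")
    return sigma2
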
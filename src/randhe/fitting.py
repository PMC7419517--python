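"""High-level fitting interface: one call from genotypes to a report.

Wraps the streaming accumulator, the normal-equation solve and the
block-jackknife into a single entry point and a tabular report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from . import estimator, jackknife
from .annotations import AnnotationSet
from .plink import StandardizedBlock


@dataclass
class VarianceComponentFit:
    """Solved variance components with jackknife uncertainty."""

    sigma2: np.ndarray  # (K+1,): sigma_1^2 .. sigma_K^2, sigma_e^2
    h2_total: float
    h2_per_component: np.ndarray
    enrichment: np.ndarray
    se_sigma2: np.ndarray
    se_h2_total: float
    se_h2_per_component: np.ndarray
    se_enrichment: np.ndarray
    z_enrichment: np.ndarray
    p_enrichment: np.ndarray
    annot: AnnotationSet
    n: int
    n_eff: int
    n_vectors: int
    n_jackknife_blocks: int
    seed: int | None

    @property
    def sigma2_e(self) -> float:
        return float(self.sigma2[-1])

    def to_frame(self) -> pd.DataFrame:
        """One row per component: sizes, estimates, SEs and Z-scores."""
        return pd.DataFrame(
            {
                "component": self.annot.names,
                "M_k": self.annot.component_sizes,
                "sigma2": self.sigma2[:-1],
                "sigma2_SE": self.se_sigma2[:-1],
                "h2": self.h2_per_component,
                "h2_SE": self.se_h2_per_component,
                "enrichment": self.enrichment,
                "enrichment_SE": self.se_enrichment,
                "Z": self.z_enrichment,
                "p": self.p_enrichment,
            }
        )

    def summary_line(self) -> str:
        return (
            f"h2_total {self.h2_total:.4f} (SE {self.se_h2_total:.4f})  "
            f"sigma2_e {self.sigma2_e:.4f}  N {self.n}  N_eff {self.n_eff}  "
            f"M {self.annot.n_snps}  K {self.annot.n_components}  "
            f"B {self.n_vectors}  J {self.n_jackknife_blocks}  seed {self.seed}"
        )


def fit_variance_components(
    genotypes: np.ndarray | Iterable[StandardizedBlock],
    y: np.ndarray,
    annot: AnnotationSet,
    n_vectors: int = estimator.DEFAULT_NUM_VECTORS,
    n_jackknife_blocks: int = estimator.DEFAULT_NUM_JACKKNIFE_BLOCKS,
    seed: int | None = 0,
    covariates: np.ndarray | None = None,
    block_size: int = 1000,
) -> VarianceComponentFit:
    """Estimate variance components from standardized genotypes.

    ``genotypes`` is either an N x M standardized matrix or an iterator
    of standardized SNP blocks in genome order.  The phenotype is always
    residualized on an intercept (centering) plus any covariates, and the
    corresponding degrees of freedom are removed from the effective
    sample size.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    y_res, n_eff, projector = estimator.project_covariates(y, covariates)
    n_jk = int(min(n_jackknife_blocks, annot.n_snps))
    if n_jk < 2:
        raise ValueError("need at least 2 jackknife blocks")
    sketch = estimator.make_sketch(n, n_vectors, seed=seed)
    if isinstance(genotypes, np.ndarray):
        blocks = estimator.iter_matrix_blocks(genotypes, block_size=block_size)
    else:
        blocks = genotypes
    acc = estimator.accumulate(
        blocks, annot, sketch, y_res, n_jackknife_blocks=n_jk, projector=projector
    )
    jk = jackknife.jackknife_fit(acc)
    z, p = jackknife.enrichment_test(jk.point.enrichment, jk.se_enrichment)
    return VarianceComponentFit(
        sigma2=jk.point.sigma2,
        h2_total=jk.point.h2_total,
        h2_per_component=jk.point.h2_per_component,
        enrichment=jk.point.enrichment,
        se_sigma2=jk.se_sigma2,
        se_h2_total=jk.se_h2_total,
        se_h2_per_component=jk.se_h2_per_component,
        se_enrichment=jk.se_enrichment,
        z_enrichment=z,
        p_enrichment=p,
        annot=annot,
        n=n,
        n_eff=n_eff,
        n_vectors=n_vectors,
        n_jackknife_blocks=n_jk,
        seed=seed,
    )
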
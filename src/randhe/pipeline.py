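"""End-to-end orchestration from PLINK files to a fitted report.

Runs QC -> standardization -> (LD scores ->) partition -> streaming
moment accumulation -> solve -> jackknife, keeping a log of every
data-driven decision (dropped SNPs, sample intersection, defaults).
Genotypes are read in SNP blocks; at desk scale the standardized matrix
is retained in memory between the QC and accumulation stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotations as annot_mod
from . import plink
from .fitting import VarianceComponentFit, fit_variance_components

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat configuration for an end-to-end estimation run."""

    bfile: str
    pheno: str
    covar: str | None = None
    annot: str | None = None
    annot_mode: str = "binary"
    score_file: str | None = None
    num_vec: int = 10
    num_blocks: int = 100
    seed: int = 0
    maf_breaks: tuple[float, ...] = (0.05,)
    ld_quantiles: int = 4
    ld_window_bp: int = 1_000_000
    max_missing: float = 0.01
    min_maf: float = 0.01
    hwe_alpha: float = 1e-7
    block_size: int = 1000
    add_rest: bool = False
    nonneg: bool = False

    def validate(self) -> None:
        if self.num_vec < 1:
            raise ValueError("num_vec must be >= 1")
        if self.num_blocks < 2:
            raise ValueError("num_blocks must be >= 2")


@dataclass
class RunResult:
    fit: VarianceComponentFit
    info: dict = field(default_factory=dict)


class SampleMismatchError(ValueError):
    """No overlap between genotype and phenotype samples."""


def load_qc_standardized(
    bfile: str,
    max_missing: float = 0.01,
    min_maf: float = 0.01,
    hwe_alpha: float = 1e-7,
    block_size: int = 1000,
) -> tuple[np.ndarray, list[plink.SnpRecord], dict]:
    """Stream a PLINK trio, QC-filter and standardize the surviving SNPs."""
    mats, records = [], []
    dropped = 0
    for counts, recs in plink.stream_plink(
        bfile + ".bed", bfile + ".bim", bfile + ".fam", block_size=block_size
    ):
        keep = plink.qc_filter(
            counts, max_missing=max_missing, min_maf=min_maf, hwe_alpha=hwe_alpha
        )
        dropped += int((~keep).sum())
        if keep.any():
            kept_recs = [r for r, k in zip(recs, keep) if k]
            block = plink.standardize(counts[:, keep], snps=kept_recs)
            mats.append(block.values)
            records.extend(block.snps)
    if not mats:
        raise ValueError("no SNPs survived QC")
    x = np.hstack(mats)
    info = {"n_snps_dropped_qc": dropped, "n_snps_kept": x.shape[1]}
    return x, records, info


def _align_samples(
    fam: pd.DataFrame, pheno: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Row indices into FAM order and matching phenotype values."""
    key_fam = fam["fid"] + "\t" + fam["iid"]
    key_ph = pheno["fid"] + "\t" + pheno["iid"]
    lookup = dict(zip(key_ph, pheno["value"]))
    rows, values = [], []
    for i, key in enumerate(key_fam):
        if key in lookup:
            rows.append(i)
            values.append(lookup[key])
    if not rows:
        raise SampleMismatchError("no FID/IID overlap between FAM and phenotype file")
    return np.array(rows), np.array(values, dtype=float)


def run_estimate(config: RunConfig) -> RunResult:
    """Execute the full pipeline described by the configuration."""
    config.validate()
    x, records, info = load_qc_standardized(
        config.bfile,
        max_missing=config.max_missing,
        min_maf=config.min_maf,
        hwe_alpha=config.hwe_alpha,
        block_size=config.block_size,
    )
    fam = plink.read_fam(config.bfile + ".fam")
    pheno = plink.read_phenotype(config.pheno)
    rows, y = _align_samples(fam, pheno)
    info["n_samples"] = len(rows)
    info["n_samples_dropped"] = len(fam) - len(rows)
    if len(rows) < len(fam):
        logger.info("keeping %d of %d FAM samples present in phenotype", len(rows), len(fam))
        x = x[rows]
        # re-standardize on the surviving sample set
        x -= x.mean(axis=0, keepdims=True)
        ss = (x * x).sum(axis=0)
        if np.any(ss <= 0):
            raise ValueError("SNP became constant after sample intersection")
        x *= np.sqrt(len(rows) / ss)
    covar = None
    if config.covar:
        cv = pd.read_csv(config.covar, sep=r"\s+", header=None, dtype={0: str, 1: str})
        key = fam["fid"].iloc[rows] + "\t" + fam["iid"].iloc[rows]
        cv_key = cv[0] + "\t" + cv[1]
        cv = cv.set_index(cv_key.values).loc[key.values]
        covar = cv.iloc[:, 2:].to_numpy(dtype=float)
    freqs = np.array([r.allele_freq for r in records])
    if config.annot:
        annot = annot_mod.load_annotation_file(
            config.annot, config.annot_mode, n_snps=x.shape[1], add_rest=config.add_rest
        )
    else:
        if config.score_file:
            scores = plink.read_phenotype(config.score_file)["value"].to_numpy()
            if len(scores) != x.shape[1]:
                raise ValueError("score file rows do not match kept SNPs")
        else:
            block = plink.StandardizedBlock(values=x, snps=records)
            scores = annot_mod.compute_ld_scores(
                block, window_bp=config.ld_window_bp
            ).scores
        annot = annot_mod.make_maf_ld_partition(
            freqs,
            scores,
            maf_breaks=config.maf_breaks,
            n_score_quantiles=config.ld_quantiles,
        )
    info["n_components"] = annot.n_components
    fit = fit_variance_components(
        x,
        y,
        annot,
        n_vectors=config.num_vec,
        n_jackknife_blocks=config.num_blocks,
        seed=config.seed,
        covariates=covar,
    )
    if config.nonneg:
        fit.sigma2 = np.maximum(fit.sigma2, 0.0)
    info.update(
        N=fit.n, M=annot.n_snps, K=annot.n_components,
        B=config.num_vec, J=fit.n_jackknife_blocks, seed=config.seed,
    )
    return RunResult(fit=fit, info=info)


def run_validate(config: RunConfig, size_guard: int = 5000) -> dict:
    """Randomized fit vs the exact dense oracle on the same data and seed."""
    from . import oracle

    result = run_estimate(config)
    x, records, _ = load_qc_standardized(
        config.bfile,
        max_missing=config.max_missing,
        min_maf=config.min_maf,
        hwe_alpha=config.hwe_alpha,
        block_size=config.block_size,
    )
    if x.shape[0] > size_guard:
        raise ValueError(f"N={x.shape[0]} exceeds the validation size guard")
    fam = plink.read_fam(config.bfile + ".fam")
    pheno = plink.read_phenotype(config.pheno)
    rows, y = _align_samples(fam, pheno)
    x = x[rows]
    y = y - y.mean()
    grms = oracle.component_grms(x, result.fit.annot)
    sigma2_exact = oracle.exact_mom_fit(grms, y, n_eff=len(rows) - 1)
    sigma2_rand = result.fit.sigma2
    denom = np.maximum(np.abs(sigma2_exact), 1e-12)
    return {
        "sigma2_randomized": sigma2_rand,
        "sigma2_exact": sigma2_exact,
        "max_relative_diff": float(np.max(np.abs(sigma2_rand - sigma2_exact) / denom)),
    }
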
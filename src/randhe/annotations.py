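"""SNP-to-variance-component maps and in-sample LD scores.

A variance-component model partitions (or covers) the M SNPs with K
categories.  Three modes are supported:

* ``disjoint`` — every SNP in exactly one component (MAF x LD bins);
* ``overlapping`` — binary annotations that may share SNPs;
* ``continuous`` — non-negative per-SNP weights a_{k,m}; the design matrix
  of component k is the standardized genotype matrix with column m scaled
  by sqrt(a_{k,m}).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .plink import StandardizedBlock

logger = logging.getLogger(__name__)

MODES = ("disjoint", "overlapping", "continuous")


@dataclass
class AnnotationSet:
    """SNP membership and weights for K variance components."""

    mode: str
    snp_indices: list[np.ndarray]  # per component: global SNP indices
    weights: list[np.ndarray]  # per component: non-negative weights (1.0 binary)
    names: list[str]
    n_snps: int  # M, total SNPs in the analysis

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        for k, (idx, w) in enumerate(zip(self.snp_indices, self.weights)):
            if len(idx) == 0:
                raise ValueError(f"component {self.names[k]} is empty")
            if np.any(w < 0):
                bad = idx[np.argmin(w)]
                raise ValueError(
                    f"negative weight for SNP index {bad} in component {self.names[k]}"
                )
        if self.mode == "disjoint":
            allidx = np.concatenate(self.snp_indices)
            if len(allidx) != self.n_snps or len(np.unique(allidx)) != self.n_snps:
                raise ValueError(
                    "disjoint mode requires every SNP in exactly one component"
                )

    @property
    def n_components(self) -> int:
        return len(self.snp_indices)

    @property
    def component_sizes(self) -> np.ndarray:
        """M_k = |S_k| per component."""
        return np.array([len(ix) for ix in self.snp_indices], dtype=np.int64)

    def slice_block(self, start: int, stop: int):
        """Per-component (local column index, weight) pairs for the SNP
        range [start, stop) — the scatter map used by the streaming pass."""
        out = []
        for k, (idx, w) in enumerate(zip(self.snp_indices, self.weights)):
            lo, hi = np.searchsorted(idx, [start, stop])
            if hi > lo:
                out.append((k, idx[lo:hi] - start, w[lo:hi]))
        return out


def from_labels(labels: Sequence[int], names: Sequence[str] | None = None) -> AnnotationSet:
    """Disjoint AnnotationSet from an integer component label per SNP."""
    labels = np.asarray(labels, dtype=np.int64)
    uniq = np.unique(labels)
    snp_indices = [np.flatnonzero(labels == u) for u in uniq]
    if names is None:
        names = [f"bin{u}" for u in uniq]
    return AnnotationSet(
        mode="disjoint",
        snp_indices=snp_indices,
        weights=[np.ones(len(ix)) for ix in snp_indices],
        names=list(names),
        n_snps=len(labels),
    )


def single_component(n_snps: int) -> AnnotationSet:
    """The one-component (genome-wide) model."""
    return from_labels(np.zeros(n_snps, dtype=int), names=["genome"])


@dataclass
class LdScoreTable:
    """Per-SNP sum of squared correlations with SNPs within a window.

    The self-correlation is included, so a SNP uncorrelated with all of
    its neighbours scores exactly 1.
    """

    scores: np.ndarray
    window_bp: int = 0


def compute_ld_scores(
    blocks: Iterable[StandardizedBlock] | StandardizedBlock,
    window_bp: int = 1_000_000,
    chunk: int = 512,
) -> LdScoreTable:
    """In-sample LD scores over a window.

    score_m = sum of r^2(m, m') over SNPs m' on the same chromosome with
    |bp_m - bp_m'| <= window_bp, including m' = m.  Input SNPs must be
    sorted by (chromosome, position).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if isinstance(blocks, StandardizedBlock):
        blocks = [blocks]
    mats, chroms, positions = [], [], []
    for blk in blocks:
        mats.append(blk.values)
        chroms.extend(r.chromosome for r in blk.snps)
        positions.extend(r.position_bp for r in blk.snps)
    x = np.hstack(mats)
    n = x.shape[0]
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=np.int64)
    m = x.shape[1]
    scores = np.zeros(m)
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        bp = positions[sel]
        if np.any(np.diff(bp) < 0):
            raise ValueError("SNPs must be sorted by position within chromosome")
        xc = x[:, sel]
        mc = len(sel)
        for s0 in range(0, mc, chunk):
            s1 = min(s0 + chunk, mc)
            lo = np.searchsorted(bp, bp[s0] - window_bp, side="left")
            hi = np.searchsorted(bp, bp[s1 - 1] + window_bp, side="right")
            # r between standardized columns is the inner product / N
            r = xc[:, s0:s1].T @ xc[:, lo:hi] / n
            r2 = r * r
            within = (
                np.abs(bp[s0:s1, None] - bp[None, lo:hi]) <= window_bp
            )
            scores[sel[s0:s1]] = (r2 * within).sum(axis=1)
    return LdScoreTable(scores=scores, window_bp=window_bp)


def make_maf_ld_partition(
    freqs: np.ndarray,
    scores: np.ndarray,
    maf_breaks: Sequence[float] = (0.05,),
    n_score_quantiles: int = 4,
    min_maf: float = 0.0,
) -> AnnotationSet:
    """Disjoint MAF x score-quantile partition.

    MAF intervals are left-closed/right-open except the last; score
    quantile edges are in-sample empirical quantiles over all SNPs, with
    ties assigned to the lower bin.  Empty bins are dropped (with a
    logged remap) so that no component has zero SNPs.

    ``maf_breaks=[0.05]`` with ``n_score_quantiles=4`` gives the common
    8-bin scheme (two MAF bins split at 5%, LD-score quartiles).
    """
    freqs = np.asarray(freqs, dtype=float)
    scores = np.asarray(scores, dtype=float)
    maf = np.minimum(freqs, 1.0 - freqs)
    breaks = list(maf_breaks)
    if any(b <= 0 or b > 0.5 for b in breaks) or sorted(breaks) != breaks:
        raise ValueError("maf_breaks must be sorted and within (0, 0.5]")
    maf_edges = np.array([min_maf] + breaks + [0.5 + 1e-12])
    maf_bin = np.clip(np.searchsorted(maf_edges, maf, side="right") - 1, 0,
                      len(maf_edges) - 2)
    if n_score_quantiles < 1:
        raise ValueError("n_score_quantiles must be >= 1")
    if n_score_quantiles == 1:
        score_bin = np.zeros(len(scores), dtype=int)
    else:
        qs = np.quantile(scores, np.linspace(0, 1, n_score_quantiles + 1)[1:-1])
        if len(np.unique(qs)) < len(qs):
            logger.warning("degenerate score quantiles; ties collapse to lower bins")
        score_bin = np.searchsorted(qs, scores, side="left")
    n_maf = len(maf_edges) - 1
    labels = maf_bin * n_score_quantiles + score_bin
    names, remap = [], {}
    for mb in range(n_maf):
        for sb in range(n_score_quantiles):
            code = mb * n_score_quantiles + sb
            if np.any(labels == code):
                remap[code] = len(names)
                names.append(f"maf{mb}_ld{sb}")
            else:
                logger.info("dropping empty bin maf%d_ld%d", mb, sb)
    relabeled = np.array([remap[c] for c in labels])
    return from_labels(relabeled, names=names)


def load_annotation_file(
    path: str | os.PathLike,
    mode: str,
    n_snps: int | None = None,
    add_rest: bool = False,
) -> AnnotationSet:
    """Load a whitespace K-column annotation table (rows in BIM order).

    Binary mode requires values in {0, 1}; continuous mode requires
    non-negative values.  A SNP in zero annotations is an error unless
    ``add_rest`` appends a catch-all component for such SNPs.
    """
    if mode not in ("binary", "continuous"):
        raise ValueError("mode must be 'binary' or 'continuous'")
    with open(path) as fh:
        first = fh.readline().split()
    has_header = False
    for tok in first:
        try:
            float(tok)
        except ValueError:
            has_header = True
            break
    table = pd.read_csv(path, sep=r"\s+", header=0 if has_header else None)
    values = table.to_numpy(dtype=float)
    m, k = values.shape
    if n_snps is not None and m != n_snps:
        raise ValueError(
            f"annotation file has {m} rows but the BIM lists {n_snps} SNPs"
        )
    if np.any(values < 0):
        snp, col = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative annotation value at SNP row {snp}, column {col}"
        )
    if mode == "binary" and not np.all(np.isin(values, (0.0, 1.0))):
        raise ValueError("binary annotations must contain only 0/1 values")
    names = [str(c) for c in table.columns] if has_header else [
        f"annot{j}" for j in range(k)
    ]
    snp_indices = [np.flatnonzero(values[:, j] > 0) for j in range(k)]
    weights = [values[idx, j] for j, idx in enumerate(snp_indices)]
    covered = np.zeros(m, dtype=bool)
    for idx in snp_indices:
        covered[idx] = True
    if not covered.all():
        if add_rest:
            rest = np.flatnonzero(~covered)
            snp_indices.append(rest)
            weights.append(np.ones(len(rest)))
            names.append("rest")
        else:
            raise ValueError(
                f"{(~covered).sum()} SNPs belong to no annotation; "
                "pass add_rest=True to add a catch-all component"
            )
    out_mode = "continuous" if mode == "continuous" else "overlapping"
    return AnnotationSet(
        mode=out_mode,
        snp_indices=snp_indices,
        weights=weights,
        names=names,
        n_snps=m,
    )


def apply_continuous_weights(
    block: StandardizedBlock, annot: AnnotationSet, component: int, start: int = 0
) -> np.ndarray:
    """Columns of ``block`` that belong to ``component``, scaled by
    sqrt(a_{k,m}); ``start`` is the block's global SNP offset."""
    stop = start + block.n_snps
    for k, local, w in annot.slice_block(start, stop):
        if k == component:
            return block.values[:, local] * np.sqrt(w)
    return np.empty((block.n_individuals, 0))
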
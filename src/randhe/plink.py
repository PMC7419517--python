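"""PLINK binary genotype I/O, quality control and standardization.

Genotypes are held as additive counts of the BIM allele-1 (A1) per
individual: values in {0, 1, 2}, with ``-1`` marking a missing call.
Heritability is invariant to which allele is counted once columns are
standardized, so the A1 convention is purely internal.

The BED codec implements the SNP-major v1.0 layout (magic bytes
``0x6c 0x1b 0x01``): one SNP per record, two bits per individual,
``00`` = hom A1, ``10`` = het, ``11`` = hom A2, ``01`` = missing.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
MISSING = -1

# 2-bit code -> A1 count (code 1 is the missing sentinel)
_CODE_TO_COUNT = np.array([2, MISSING, 1, 0], dtype=np.int8)
_COUNT_TO_CODE = {2: 0, MISSING: 1, 1: 2, 0: 3}


class PlinkFormatError(ValueError):
    """Raised on malformed BED magic bytes or unsupported layout."""


class PlinkConsistencyError(ValueError):
    """Raised when BED/BIM/FAM dimensions disagree."""


@dataclass
class SnpRecord:
    """Per-SNP metadata carried alongside genotype blocks."""

    id: str
    chromosome: str
    position_bp: int
    allele_freq: float = np.nan  # frequency of the counted (A1) allele
    missing_rate: float = np.nan


@dataclass
class StandardizedBlock:
    """A contiguous block of SNP-standardized genotypes.

    Each column sums to 0 and has sum of squares equal to the number of
    individuals N, the scaling under which every per-category relatedness
    matrix has trace exactly N.
    """

    values: np.ndarray  # individuals x block_snps, float64
    snps: list[SnpRecord] = field(default_factory=list)
    block_index: int = 0

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]


def read_bim(path: str | os.PathLike) -> pd.DataFrame:
    bim = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "bp", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    return bim


def read_fam(path: str | os.PathLike) -> pd.DataFrame:
    fam = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    return fam


def _decode_snp_records(buf: np.ndarray, n: int) -> np.ndarray:
    """Unpack SNP-major BED bytes (one row per SNP) into A1 counts."""
    codes = np.empty((buf.shape[0], buf.shape[1] * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (buf >> (2 * shift)) & 0b11
    return _CODE_TO_COUNT[codes[:, :n]]


def stream_plink(
    bed_path: str | os.PathLike,
    bim_path: str | os.PathLike,
    fam_path: str | os.PathLike,
    block_size: int = 1000,
) -> Iterator[tuple[np.ndarray, list[SnpRecord]]]:
    """Stream a PLINK trio in consecutive SNP blocks.

    Yields ``(counts, records)`` where ``counts`` is individuals x
    block_snps int8 with missing = -1.  The BED file is traversed exactly
    once, front to back.
    """
    if block_size < 1:
        raise ValueError("block_size must be a positive integer")
    bim = read_bim(bim_path)
    fam = read_fam(fam_path)
    n, m = len(fam), len(bim)
    bytes_per_snp = (n + 3) // 4

    with open(bed_path, "rb") as fh:
        magic = fh.read(3)
        if magic != BED_MAGIC:
            raise PlinkFormatError(
                f"{bed_path}: bad BED magic bytes {magic!r}; expected SNP-major v1.0"
            )
        fh.seek(0, io.SEEK_END)
        payload = fh.tell() - 3
        if payload != bytes_per_snp * m:
            raise PlinkConsistencyError(
                f"{bed_path}: payload of {payload} bytes does not match "
                f"{m} SNPs x {n} individuals from BIM/FAM"
            )
        fh.seek(3)
        for start in range(0, m, block_size):
            stop = min(start + block_size, m)
            raw = np.frombuffer(
                fh.read(bytes_per_snp * (stop - start)), dtype=np.uint8
            ).reshape(stop - start, bytes_per_snp)
            counts = _decode_snp_records(raw, n).T  # individuals x snps
            records = [
                SnpRecord(
                    id=row.id, chromosome=str(row.chrom), position_bp=int(row.bp)
                )
                for row in bim.iloc[start:stop].itertuples()
            ]
            yield np.ascontiguousarray(counts), records


def write_plink(
    prefix: str | os.PathLike,
    counts: np.ndarray,
    bim: pd.DataFrame,
    fam: pd.DataFrame,
) -> None:
    """Write A1-count genotypes (individuals x SNPs, missing = -1) as a
    PLINK BED/BIM/FAM trio."""
    n, m = counts.shape
    if len(bim) != m or len(fam) != n:
        raise PlinkConsistencyError("counts shape disagrees with BIM/FAM rows")
    code = np.empty((m, n), dtype=np.uint8)
    cts = counts.T
    for value, c in _COUNT_TO_CODE.items():
        code[cts == value] = c
    pad = (-n) % 4
    if pad:  # trailing bits of the last byte are ignored by readers
        code = np.hstack([code, np.zeros((m, pad), dtype=np.uint8)])
    packed = (
        code[:, 0::4]
        | (code[:, 1::4] << 2)
        | (code[:, 2::4] << 4)
        | (code[:, 3::4] << 6)
    ).astype(np.uint8)
    prefix = os.fspath(prefix)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(BED_MAGIC)
        fh.write(packed.tobytes())
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)


def allele_stats(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP A1 allele frequency (over non-missing calls) and missing rate."""
    missing = counts == MISSING
    n_obs = counts.shape[0] - missing.sum(axis=0)
    total = np.where(missing, 0, counts).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0, total / (2.0 * np.maximum(n_obs, 1)), np.nan)
    miss_rate = missing.mean(axis=0)
    return freq, miss_rate


def hwe_pvalues(counts: np.ndarray) -> np.ndarray:
    """1-df chi-square goodness-of-fit p-value for Hardy-Weinberg
    proportions, computed per SNP from non-missing genotype counts."""
    m = counts.shape[1]
    p = np.ones(m)
    for j in range(m):
        col = counts[:, j]
        col = col[col != MISSING]
        n = col.size
        if n == 0:
            continue
        n_hom1 = int((col == 2).sum())
        n_het = int((col == 1).sum())
        n_hom0 = n - n_hom1 - n_het
        f = (2 * n_hom1 + n_het) / (2.0 * n)
        if f in (0.0, 1.0):
            continue  # monomorphic: HWE undefined, handled by MAF filter
        exp = np.array([n * f * f, 2 * n * f * (1 - f), n * (1 - f) ** 2])
        obs = np.array([n_hom1, n_het, n_hom0])
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        p[j] = stats.chi2.sf(chi2, df=1)
    return p


def qc_filter(
    counts: np.ndarray,
    max_missing: float = 0.01,
    min_maf: float = 0.01,
    hwe_alpha: float = 1e-7,
) -> np.ndarray:
    """Keep-mask over the SNPs of a raw count block.

    Drops SNPs with missingness above ``max_missing``, minor allele
    frequency below ``min_maf`` (monomorphic SNPs always fail), or a
    Hardy-Weinberg goodness-of-fit p-value below ``hwe_alpha``.
    """
    freq, miss = allele_stats(counts)
    maf = np.minimum(freq, 1.0 - freq)
    keep = (miss <= max_missing) & np.isfinite(maf) & (maf >= min_maf) & (maf > 0)
    if hwe_alpha > 0:
        need = np.flatnonzero(keep)
        if need.size:
            pvals = hwe_pvalues(counts[:, need])
            keep[need] &= pvals >= hwe_alpha
    return keep


def standardize(
    counts: np.ndarray,
    freqs: np.ndarray | None = None,
    snps: Sequence[SnpRecord] | None = None,
    block_index: int = 0,
) -> StandardizedBlock:
    """Mean-impute, center and rescale a count block column-wise.

    Missing calls are replaced by the SNP mean (twice the in-sample A1
    frequency); each column is then centered and rescaled so that its sum
    of squares equals N exactly.  Columns that are constant after
    imputation (frequency 0 or 1, or no variation) are degenerate and
    should have been removed by :func:`qc_filter`.
    """
    x = counts.astype(np.float64, copy=True)
    emp_freq, miss = allele_stats(counts)
    if freqs is None:
        freqs = emp_freq
    freqs = np.asarray(freqs, dtype=np.float64)
    if np.any((freqs <= 0.0) | (freqs >= 1.0) | ~np.isfinite(freqs)):
        raise ValueError("degenerate SNP with allele frequency 0 or 1; run qc_filter first")
    missing_mask = counts == MISSING
    if missing_mask.any():
        fill = np.broadcast_to(2.0 * freqs, x.shape)
        x[missing_mask] = fill[missing_mask]
    x -= x.mean(axis=0)
    ss = (x * x).sum(axis=0)
    if np.any(ss <= 0):
        raise ValueError("constant genotype column after imputation; run qc_filter first")
    n = x.shape[0]
    x *= np.sqrt(n / ss)
    records: list[SnpRecord]
    if snps is None:
        records = [
            SnpRecord(id=f"snp{j}", chromosome="1", position_bp=j)
            for j in range(x.shape[1])
        ]
    else:
        records = list(snps)
    for rec, f, mr in zip(records, emp_freq, miss):
        rec.allele_freq = float(f)
        rec.missing_rate = float(mr)
    return StandardizedBlock(values=x, snps=records, block_index=block_index)


def read_phenotype(path: str | os.PathLike) -> pd.DataFrame:
    """Read a whitespace-delimited FID IID value phenotype/score file.

    A header line is detected by a non-numeric third token.  Missing
    phenotypes coded ``NA`` or ``-9`` are dropped.
    """
    with open(path) as fh:
        first = fh.readline().split()
    header = 0
    if len(first) >= 3:
        try:
            float(first[2])
            header = None
        except ValueError:
            header = 0
    df = pd.read_csv(path, sep=r"\s+", header=header, dtype={0: str, 1: str})
    df.columns = ["fid", "iid"] + [f"value{i}" for i in range(len(df.columns) - 2)]
    value = pd.to_numeric(df["value0"], errors="coerce")
    keep = value.notna() & (value != -9)
    out = df.loc[keep, ["fid", "iid"]].copy()
    out["value"] = value[keep].astype(float)
    return out.reset_index(drop=True)
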
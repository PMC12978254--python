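"""Aneuploidy, karyotype heterogeneity, and breakpoint metrics.

Operates on binned integer copy-number calls (cells x genomic bins, with bin
sizes and chromosome labels), e.g. the output of a single-cell WGS
copy-number caller.  Scores:

* library (per-cell) aneuploidy = bin-size-weighted mean of
  ``|CN - expected euploid CN|``; sample score = mean over kept libraries;
* heterogeneity per bin = proportion of discordant cell pairs (any copy
  number difference counts); sample score = bin-size-weighted mean;
* structural breakpoints per Mb = count of adjacent same-chromosome bin pairs
  with differing CN, divided by genome length in Mb.

Libraries averaging fewer than 10 reads per bin per chromosome copy are
discarded by :func:`library_qc` when read counts are available.  The expected
euploid copy number is configurable per bin (sex chromosomes) and can be
raised genome-wide for whole-genome-doubled samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CopyNumberMatrix",
    "library_qc",
    "aneuploidy_score",
    "heterogeneity_score",
    "breakpoints_per_mb",
    "KaryotypeScores",
]

MIN_READS_PER_BIN_PER_COPY = 10.0


@dataclass
class CopyNumberMatrix:
    """Cells x bins integer copy-number states with bin annotation."""

    cn: pd.DataFrame  # cells x bins, int >= 0
    bin_sizes: np.ndarray  # bp, > 0
    chrom: np.ndarray  # chromosome label per bin, ordered chrom then position
    expected: np.ndarray | float = 2.0  # euploid CN per bin (or scalar)
    reads: pd.DataFrame | None = None  # optional per-cell per-bin read counts

    def __post_init__(self):
        self.bin_sizes = np.asarray(self.bin_sizes, np.int64)
        self.chrom = np.asarray(self.chrom, str)
        if (self.bin_sizes <= 0).any():
            raise ValueError("bin sizes must be > 0")
        if self.cn.shape[1] != len(self.bin_sizes) or len(self.chrom) != len(self.bin_sizes):
            raise ValueError("bin annotation length mismatch")
        if (self.cn.to_numpy() < 0).any():
            raise ValueError("copy numbers must be >= 0")

    @property
    def expected_per_bin(self) -> np.ndarray:
        e = np.asarray(self.expected, float)
        return np.full(len(self.bin_sizes), float(e)) if e.ndim == 0 else e


@dataclass
class KaryotypeScores:
    """Per-library and sample-level karyotype scores."""

    library_aneuploidy: pd.Series | None = None
    sample_aneuploidy: float = np.nan
    bin_heterogeneity: np.ndarray | None = None
    sample_heterogeneity: float = np.nan
    breakpoints_per_mb: pd.Series | None = None


def library_qc(matrix: CopyNumberMatrix, min_reads_per_copy: float = MIN_READS_PER_BIN_PER_COPY):
    """Cells kept by the reads-per-bin-per-copy criterion.

    Keep a cell iff the mean over bins of reads / copy number is at least
    ``min_reads_per_copy``; zero-copy bins are excluded from the mean.  With
    no read counts the QC is skipped (all cells kept) with a warning.
    """
    if matrix.reads is None:
        warnings.warn("no read counts supplied; library QC skipped")
        return matrix.cn.index.to_numpy()
    cn = matrix.cn.to_numpy().astype(float)
    reads = matrix.reads.to_numpy().astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_copy = np.where(cn > 0, reads / cn, np.nan)
    mean_rpc = np.nanmean(per_copy, axis=1)
    keep = mean_rpc >= min_reads_per_copy
    return matrix.cn.index.to_numpy()[keep]


def aneuploidy_score(matrix: CopyNumberMatrix) -> KaryotypeScores:
    """Bin-size-weighted copy-number deviation from the euploid expectation."""
    dev = np.abs(matrix.cn.to_numpy() - matrix.expected_per_bin[None, :])
    w = matrix.bin_sizes.astype(float)
    lib = (dev * w[None, :]).sum(axis=1) / w.sum()
    lib = pd.Series(lib, index=matrix.cn.index, name="aneuploidy")
    return KaryotypeScores(library_aneuploidy=lib, sample_aneuploidy=float(lib.mean()))


def heterogeneity_score(matrix: CopyNumberMatrix) -> KaryotypeScores:
    """Proportion of discordant cell pairs per bin, size-weighted per sample.

    Discordance is any difference in integer copy number between two cells at
    a bin; with n cells the denominator is C(n, 2).
    """
    cn = matrix.cn.to_numpy()
    n = cn.shape[0]
    if n < 2:
        raise ValueError("heterogeneity needs at least two cells")
    pairs = n * (n - 1) / 2.0
    het = np.empty(cn.shape[1])
    for j in range(cn.shape[1]):
        counts = np.bincount(cn[:, j])
        concordant = (counts * (counts - 1) // 2).sum()
        het[j] = 1.0 - concordant / pairs
    w = matrix.bin_sizes.astype(float)
    return KaryotypeScores(
        bin_heterogeneity=het,
        sample_heterogeneity=float((het * w).sum() / w.sum()),
    )


def breakpoints_per_mb(matrix: CopyNumberMatrix) -> pd.Series:
    """Per-cell structural breakpoints per megabase.

    A breakpoint is an adjacent same-chromosome bin pair with differing copy
    number; the rate divides by total genome length in Mb.  Single-bin
    chromosomes contribute no pairs.
    """
    cn = matrix.cn.to_numpy()
    same_chrom = matrix.chrom[:-1] == matrix.chrom[1:]
    diffs = (cn[:, :-1] != cn[:, 1:]) & same_chrom[None, :]
    genome_mb = matrix.bin_sizes.sum() / 1e6
    rate = diffs.sum(axis=1) / genome_mb
    return pd.Series(rate, index=matrix.cn.index, name="breakpoints_per_mb")


def score_sample(matrix: CopyNumberMatrix, apply_qc: bool = True) -> KaryotypeScores:
    """Convenience: QC (when possible) then all three score families."""
    if apply_qc and matrix.reads is not None:
        keep = library_qc(matrix)
        matrix = CopyNumberMatrix(
            cn=matrix.cn.loc[keep],
            bin_sizes=matrix.bin_sizes,
            chrom=matrix.chrom,
            expected=matrix.expected,
            reads=matrix.reads.loc[keep],
        )
    an = aneuploidy_score(matrix)
    het = heterogeneity_score(matrix)
    return KaryotypeScores(
        library_aneuploidy=an.library_aneuploidy,
        sample_aneuploidy=an.sample_aneuploidy,
        bin_heterogeneity=het.bin_heterogeneity,
        sample_heterogeneity=het.sample_heterogeneity,
        breakpoints_per_mb=breakpoints_per_mb(matrix),
    )
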
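"""Readers and writers for the pipeline's plain-text formats.

CSV/TSV for cell, focus, cohort and score tables; TSV or MatrixMarket for
count matrices (MTX via anndata); BED-like bin files plus a TSV matrix for
copy-number calls; GMT for gene sets; JSON for simulation ground truth.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .association import GeneSignature
from .karyotype import CopyNumberMatrix

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_counts",
    "write_counts",
    "read_copy_number",
    "write_copy_number",
]


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(signatures, path, description: str = "cinmn"):
    """Write signatures (mapping name -> genes, or GeneSignature list) as GMT."""
    if isinstance(signatures, dict):
        items = signatures.items()
    else:
        items = [(s.name, s.genes) for s in signatures]
    with open(path, "w") as fh:
        for name, genes in items:
            genes = genes.genes if isinstance(genes, GeneSignature) else list(genes)
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_counts(path, meta_path=None):
    """Read a genes x samples count matrix from TSV or MatrixMarket.

    For ``.mtx`` input, sidecar ``<stem>.genes.txt`` and ``<stem>.samples.txt``
    files provide the axis labels.  Returns ``counts`` or
    ``(counts, metadata)`` when ``meta_path`` is given (CSV indexed by
    sample).
    """
    path = os.fspath(path)
    if path.endswith(".mtx"):
        from scipy.io import mmread

        stem = path[: -len(".mtx")]
        genes = pd.read_csv(stem + ".genes.txt", header=None)[0].astype(str)
        samples = pd.read_csv(stem + ".samples.txt", header=None)[0].astype(str)
        counts = pd.DataFrame(
            np.asarray(mmread(path).todense(), dtype=np.int64), index=genes, columns=samples
        )
    else:
        counts = pd.read_csv(path, sep="\t", index_col=0)
    if meta_path is None:
        return counts
    meta = pd.read_csv(meta_path, index_col=0)
    return counts, meta.loc[counts.columns]


def write_counts(counts: pd.DataFrame, path, meta: pd.DataFrame | None = None, meta_path=None):
    """Write a count matrix as TSV or MatrixMarket (with label sidecars)."""
    path = os.fspath(path)
    if path.endswith(".mtx"):
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(path, csr_matrix(counts.to_numpy()))
        stem = path[: -len(".mtx")]
        pd.Series(counts.index).to_csv(stem + ".genes.txt", index=False, header=False)
        pd.Series(counts.columns).to_csv(stem + ".samples.txt", index=False, header=False)
    else:
        counts.to_csv(path, sep="\t")
    if meta is not None and meta_path is not None:
        meta.to_csv(meta_path)


def read_copy_number(cn_path, bins_path, reads_path=None, expected: float = 2.0) -> CopyNumberMatrix:
    """Copy-number matrix from a cells x bins TSV plus a BED-like bin file.

    The bin file has columns chrom, start, end (tab-separated, no header),
    ordered by chromosome then position, one row per matrix column.
    """
    cn = pd.read_csv(cn_path, sep="\t", index_col=0)
    bins = pd.read_csv(bins_path, sep="\t", header=None, names=["chrom", "start", "end"])
    reads = pd.read_csv(reads_path, sep="\t", index_col=0) if reads_path else None
    return CopyNumberMatrix(
        cn=cn,
        bin_sizes=(bins["end"] - bins["start"]).to_numpy(),
        chrom=bins["chrom"].to_numpy(),
        expected=expected,
        reads=reads,
    )


def write_copy_number(matrix: CopyNumberMatrix, cn_path, bins_path, reads_path=None):
    """Write a CopyNumberMatrix as TSV matrix + BED-like bin file."""
    matrix.cn.to_csv(cn_path, sep="\t")
    starts = np.concatenate([[0], np.cumsum(matrix.bin_sizes)[:-1]])
    # restart coordinates at each chromosome boundary
    start_in_chrom = np.zeros(len(matrix.bin_sizes), dtype=np.int64)
    pos = 0
    for i, c in enumerate(matrix.chrom):
        if i > 0 and c != matrix.chrom[i - 1]:
            pos = 0
        start_in_chrom[i] = pos
        pos += matrix.bin_sizes[i]
    pd.DataFrame(
        {
            "chrom": matrix.chrom,
            "start": start_in_chrom,
            "end": start_in_chrom + matrix.bin_sizes,
        }
    ).to_csv(bins_path, sep="\t", header=False, index=False)
    if matrix.reads is not None and reads_path is not None:
        matrix.reads.to_csv(reads_path, sep="\t")
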
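"""Count-matrix loading, scaling normalization, gene filtering and CV-mean statistics.

The container is a plain genes x cells dense matrix with identifier lists.
Normalization rescales every cell (column) to the average library size,
``k_ij_hat = k_ij * Kbar / K_j`` with ``K_j = sum_i k_ij``; genes expressed
(count > 0) in less than a given fraction of cells (default 1 %) are removed
before modelling.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "GeneStats", "read_counts", "normalize_scaling", "filter_genes", "gene_stats"]


@dataclass
class CountMatrix:
    """Genes x cells nonnegative expression matrix (raw UMI counts or normalized)."""

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("count matrix must be 2-D (genes x cells)")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.cell_ids)} cell ids"
            )
        if self.values.size and self.values.min() < 0:
            raise ValueError("count matrix contains negative entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class GeneStats:
    """Per-gene mean, standard deviation (n-1 denominator), CV = sd/mean and
    number of cells with a nonzero value, computed across cells."""

    gene_ids: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    cv: np.ndarray
    n_expressed: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        for name in ("mean", "sd", "cv", "n_expressed"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"GeneStats field {name!r} length mismatch")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean": self.mean,
                "sd": self.sd,
                "cv": self.cv,
                "n_expressed": self.n_expressed,
            },
            index=self.gene_ids,
        )


def read_counts(
    path: str,
    format: str = "tsv",
    genes_path: Optional[str] = None,
    cells_path: Optional[str] = None,
) -> CountMatrix:
    """Load a genes x cells count matrix.

    ``format='tsv'``: tab-separated, header row of cell ids, first column gene
    ids.  ``format='mtx'``: matrix-market triplet plus row/column name files
    (defaulting to ``genes.tsv`` / ``cells.tsv`` next to the .mtx).  Integers
    are preserved as integers; duplicate gene ids and negative entries are
    load errors naming the offending record.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except pd.errors.EmptyDataError as exc:
            raise ValueError(f"empty or malformed count file: {path}") from exc
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValueError(f"count file has no data: {path}")
        values = df.to_numpy()
        gene_ids, cell_ids = df.index.to_numpy(), df.columns.to_numpy()
    elif format == "mtx":
        from scipy.io import mmread

        base = os.path.dirname(path)
        genes_path = genes_path or os.path.join(base, "genes.tsv")
        cells_path = cells_path or os.path.join(base, "cells.tsv")
        values = np.asarray(mmread(path).todense())
        gene_ids = pd.read_csv(genes_path, sep="\t", header=None)[0].to_numpy()
        cell_ids = pd.read_csv(cells_path, sep="\t", header=None)[0].to_numpy()
    else:
        raise ValueError(f"unknown format {format!r}; use 'tsv' or 'mtx'")

    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"non-numeric entries in count file: {path}")
    if np.isclose(values, np.round(values)).all():
        values = np.round(values).astype(np.int64)
    neg = np.argwhere(values < 0)
    if len(neg):
        i, j = neg[0]
        raise ValueError(f"negative count at gene {gene_ids[i]!r}, cell {cell_ids[j]!r}")
    dup = pd.Index(gene_ids).duplicated()
    if dup.any():
        raise ValueError(f"duplicate gene id {gene_ids[np.argmax(dup)]!r}")
    return CountMatrix(values=values, gene_ids=gene_ids, cell_ids=cell_ids)


def normalize_scaling(counts: CountMatrix) -> CountMatrix:
    """Rescale each cell to the average library size (grand total preserved).

    k_ij_hat = k_ij * Kbar / K_j with K_j the column total and Kbar their mean.
    """
    totals = counts.values.sum(axis=0, dtype=float)
    empty = np.flatnonzero(totals == 0)
    if len(empty):
        raise ValueError(f"cell {counts.cell_ids[empty[0]]!r} has zero total count")
    kbar = totals.mean()
    values = counts.values * (kbar / totals)[None, :]
    return replace(counts, values=values, normalized=True)


def filter_genes(counts: CountMatrix, min_fraction: float = 0.01) -> CountMatrix:
    """Remove genes expressed (value > 0) in fewer than ``min_fraction`` of cells.

    A gene is retained iff its nonzero-cell count is >= ceil(min_fraction * n_cells);
    gene order is preserved and the operation is idempotent.
    """
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must lie in [0, 1]")
    n_expressed = (counts.values > 0).sum(axis=1)
    keep = n_expressed >= int(np.ceil(min_fraction * counts.n_cells))
    return replace(
        counts,
        values=counts.values[keep],
        gene_ids=counts.gene_ids[keep],
    )


def gene_stats(counts: CountMatrix) -> GeneStats:
    """Per-gene mean, SD (ddof=1) and CV across cells.

    Genes with zero mean are excluded with a warning (their CV is undefined);
    fewer than two cells is an error since the SD needs n >= 2.
    """
    if counts.n_cells < 2:
        raise ValueError("CV is undefined with fewer than 2 cells")
    values = counts.values.astype(float)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    n_expressed = (values > 0).sum(axis=1)
    keep = mean > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} gene(s) with zero mean from statistics",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
    return GeneStats(
        gene_ids=counts.gene_ids[keep],
        mean=mean[keep],
        sd=sd[keep],
        cv=cv[keep],
        n_expressed=n_expressed[keep],
    )
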
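"""In-memory containers shared across the pipeline.

The single-cell matrix is kept genes x cells (the orientation of a
CellRanger-style MatrixMarket triplet); bulk expression tables are
genes x samples pandas DataFrames wrapped with a declared scale tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


class FormatError(ValueError):
    """Malformed on-disk input (dimension mismatch, bad field, ...)."""


@dataclass
class UmiCountMatrix:
    """Sparse genes x cells UMI count matrix with sidecar metadata.

    Parameters
    ----------
    counts : scipy.sparse matrix, shape (n_genes, n_cells)
        Non-negative integer UMI counts.
    genes : list of str
        Gene symbols, one per row.
    barcodes : list of str
        Cell barcodes, one per column.
    """

    counts: sp.spmatrix
    genes: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.counts = sp.csc_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative UMI counts")
        if not np.issubdtype(self.counts.dtype, np.integer):
            data = self.counts.data
            if data.size and not np.all(data == np.round(data)):
                raise FormatError("non-integer UMI counts")
            self.counts = self.counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def counts_per_cell(self) -> np.ndarray:
        """Total UMI count per cell (column sums), C_j."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def detected_genes_per_cell(self) -> np.ndarray:
        """Number of genes with nonzero count per cell, G_j."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def mito_fraction_per_cell(self, mito_prefix: str = "MT-") -> np.ndarray:
        """Fraction of each cell's counts coming from mitochondrial genes, m_j.

        Mitochondrial genes are recognised by a symbol prefix (default
        ``MT-``); with no matching genes the fraction is 0 everywhere.
        """
        mask = np.array([g.startswith(mito_prefix) for g in self.genes])
        totals = self.counts_per_cell().astype(float)
        if not mask.any():
            return np.zeros(self.n_cells)
        mito = np.asarray(self.counts[mask].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / totals, 0.0)
        return frac

    def subset_cells(self, index: np.ndarray) -> "UmiCountMatrix":
        return UmiCountMatrix(
            self.counts[:, index],
            list(self.genes),
            [self.barcodes[i] for i in np.asarray(index)],
        )


@dataclass
class NormalizedMatrix:
    """Dense genes x cells matrix of log-normalized expression.

    ``values[i, j] = ln(1 + scale * c_ij / C_j)`` — zero iff the raw
    count was zero.
    """

    values: np.ndarray
    genes: list[str]
    barcodes: list[str]
    scale_factor: float = 10_000.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError("normalized matrix shape mismatch with metadata")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            near = [g for g in self.genes if gene.lower() in g.lower()][:5]
            hint = f"; near matches: {near}" if near else ""
            raise KeyError(f"gene {gene!r} not present{hint}") from None


@dataclass
class ExpressionTable:
    """Bulk expression matrix (genes x samples) with a declared scale.

    scale is one of ``raw-count``, ``log-natural``, ``log2``.
    """

    values: pd.DataFrame
    scale: str = "log2"

    _SCALES = ("raw-count", "log-natural", "log2")

    def __post_init__(self) -> None:
        if self.scale not in self._SCALES:
            raise ValueError(f"scale must be one of {self._SCALES}")
        if self.values.index.duplicated().any():
            raise FormatError("duplicate gene identifiers")
        if self.values.columns.duplicated().any():
            raise FormatError("duplicate sample identifiers")
        vals = self.values.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise FormatError("non-finite expression values")
        if self.scale == "raw-count" and vals.min() < 0:
            raise FormatError("negative values in a raw-count table")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class GeneSet:
    name: str
    genes: list[str]
    description: str = ""

    def __post_init__(self) -> None:
        # empty sets are representable (a cluster may have no significant
        # positive markers) but cannot be serialised to GMT
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate genes")


@dataclass
class GeneSetCollection:
    """Named, ordered collection of gene sets (GMT semantics)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene set names")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]
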
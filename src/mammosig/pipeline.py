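"""Single-cell QC, normalization, PCA and SNN graph clustering.

The stages mirror the standard droplet scRNA-seq workflow: cells with
more than ``max_genes`` detected genes (probable aggregates) or with a
mitochondrial count fraction above ``max_mito`` (probable dead cells)
are removed; counts are library-size normalized to 10,000 and
log1p-transformed; highly variable genes feed a PCA; clustering is
modularity optimization on a shared-nearest-neighbor (Jaccard) graph,
with cluster labels renumbered so cluster 0 is the largest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .containers import NormalizedMatrix, UmiCountMatrix

logger = logging.getLogger(__name__)


@dataclass
class QcReport:
    n_input: int
    n_retained: int
    n_removed_genes: int
    n_removed_mito: int


@dataclass
class ClusterAssignment:
    """Cluster label per cell, labels ordered by decreasing size."""

    labels: pd.Series  # barcode -> integer cluster label
    sizes: pd.Series = field(init=False)  # label -> n_k

    def __post_init__(self) -> None:
        self.sizes = self.labels.value_counts().sort_index()

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def summary(self) -> pd.DataFrame:
        """Cluster report: label, cell count, percent of total (1 decimal)."""
        total = int(self.sizes.sum())
        pct = (100.0 * self.sizes / total).round(1)
        return pd.DataFrame(
            {"cluster": self.sizes.index, "n_cells": self.sizes.values,
             "percent": pct.values}
        ).reset_index(drop=True)


def qc_filter(
    counts: UmiCountMatrix,
    max_genes: int = 6500,
    max_mito: float = 0.1,
    mito_prefix: str = "MT-",
) -> tuple[UmiCountMatrix, QcReport]:
    """Remove probable aggregates and dead cells.

    Cells are retained iff detected genes <= ``max_genes`` AND
    mitochondrial fraction <= ``max_mito`` (strict inequalities remove;
    boundary cells stay).
    """
    g = counts.detected_genes_per_cell()
    m = counts.mito_fraction_per_cell(mito_prefix)
    bad_genes = g > max_genes
    bad_mito = m > max_mito
    keep = ~(bad_genes | bad_mito)
    if not keep.any():
        raise ValueError(
            "QC removed every cell; review max_genes/max_mito thresholds"
        )
    report = QcReport(
        n_input=counts.n_cells,
        n_retained=int(keep.sum()),
        n_removed_genes=int(bad_genes.sum()),
        n_removed_mito=int(bad_mito.sum()),
    )
    logger.info(
        "QC: %d/%d cells retained (%d over gene cap, %d over mito cap)",
        report.n_retained, report.n_input,
        report.n_removed_genes, report.n_removed_mito,
    )
    return counts.subset_cells(np.flatnonzero(keep)), report


def normalize(counts: UmiCountMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """Library-size normalize and log-transform: x = ln(1 + s * c / C)."""
    totals = counts.counts_per_cell().astype(float)
    if (totals == 0).any():
        raise ValueError("cells with zero total counts; run qc_filter first")
    frac = counts.counts.multiply(scale_factor / totals)
    values = np.log1p(np.asarray(frac.todense()))
    return NormalizedMatrix(values, list(counts.genes), list(counts.barcodes),
                            scale_factor=scale_factor)


def highly_variable_genes(
    norm: NormalizedMatrix, n_hvg: int = 2000, n_bins: int = 20
) -> np.ndarray:
    """Select genes by a dispersion-vs-mean criterion.

    Per-gene dispersion (variance/mean of expm1 expression) is z-scored
    within mean-expression bins; the top ``n_hvg`` by normalized
    dispersion are returned as row indices.
    """
    x = np.expm1(norm.values)
    mean = x.mean(axis=1)
    var = x.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    df = pd.DataFrame({"mean": mean, "disp": disp})
    df["bin"] = pd.cut(df["mean"], bins=n_bins, labels=False)
    grouped = df.groupby("bin")["disp"]
    mu = grouped.transform("mean")
    sd = grouped.transform("std").replace(0, np.nan)
    df["norm_disp"] = ((df["disp"] - mu) / sd).fillna(0.0)
    n_hvg = min(n_hvg, norm.n_genes)
    return np.sort(np.argsort(-df["norm_disp"].to_numpy(), kind="stable")[:n_hvg])


def pca_embed(
    norm: NormalizedMatrix, n_pcs: int = 10, n_hvg: int = 2000,
    scale: bool = True,
) -> np.ndarray:
    """Cells x n_pcs principal-component embedding.

    Highly variable genes are centered (and, with ``scale``, unit-scaled)
    per gene before the decomposition. Components are ordered by
    decreasing explained variance; each component's sign is fixed so its
    largest-magnitude gene loading is positive, making the embedding
    deterministic.
    """
    if n_pcs > min(norm.n_genes, norm.n_cells):
        raise ValueError("n_pcs exceeds matrix dimensions")
    hvg = highly_variable_genes(norm, n_hvg=n_hvg)
    x = norm.values[hvg].T.astype(float)  # cells x genes
    x -= x.mean(axis=0)
    if scale:
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x /= sd
    # exact SVD keeps the embedding deterministic
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, s, vt = u[:, :n_pcs], s[:n_pcs], vt[:n_pcs]
    flip = np.sign(vt[np.arange(len(s)), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    return u * s * flip


def _snn_graph(embedding: np.ndarray, k_neighbors: int) -> igraph.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights."""
    n = embedding.shape[0]
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(embedding)
    adj = nn.kneighbors_graph(embedding, mode="connectivity")
    adj = adj.maximum(sp.eye(n, format="csr"))  # each cell neighbors itself
    set_size = k_neighbors + 1
    shared = (adj @ adj.T).tocoo()  # |N(i) & N(j)| for overlapping pairs
    row, col, inter = shared.row, shared.col, shared.data
    keep = row < col
    row, col, inter = row[keep], col[keep], inter[keep]
    union = 2 * set_size - inter
    jac = inter / union
    pos = jac > 1 / 15  # prune negligible overlaps, Jaccard-SNN convention
    edges = np.column_stack([row[pos], col[pos]])
    g = igraph.Graph(n=n, edges=edges.tolist())
    g.es["weight"] = jac[pos].tolist()
    return g


def snn_cluster(
    embedding: np.ndarray,
    k_neighbors: int = 20,
    resolution: float = 0.8,
    seed: int = 0,
) -> "ClusterAssignment | pd.Series":
    """Cluster cells by modularity optimization on the SNN graph.

    A k-nearest-neighbor graph in PCA space is reweighted by the
    Jaccard overlap of neighbor sets, then partitioned with the Leiden
    algorithm (RB-configuration modularity at the given resolution).
    Labels are renumbered by decreasing cluster size; ties between
    equal-sized communities keep their original community order (a
    warning is logged when that happens).
    """
    n = embedding.shape[0]
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be smaller than the number of cells")
    g = _snn_graph(np.asarray(embedding, dtype=float), k_neighbors)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
    )
    raw = np.array(part.membership)
    return relabel_by_size(raw)


def relabel_by_size(raw_labels: np.ndarray, index=None) -> ClusterAssignment:
    """Renumber community ids 0..K-1 by decreasing size.

    Ties are broken by the original community id (stable), with a
    logged warning.
    """
    raw_labels = np.asarray(raw_labels)
    ids, counts = np.unique(raw_labels, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    if len(set(counts)) < len(counts):
        logger.warning("equal-sized clusters; ties broken by community id")
    mapping = {int(ids[o]): new for new, o in enumerate(order)}
    labels = pd.Series(
        [mapping[int(l)] for l in raw_labels],
        index=index if index is not None else range(len(raw_labels)),
        name="cluster",
    )
    return ClusterAssignment(labels)


def cluster_cells(
    counts: UmiCountMatrix,
    max_genes: int = 6500,
    max_mito: float = 0.1,
    n_pcs: int = 10,
    n_hvg: int = 2000,
    k_neighbors: int = 20,
    resolution: float = 0.8,
    seed: int = 0,
) -> tuple[NormalizedMatrix, ClusterAssignment, QcReport]:
    """QC -> normalize -> PCA -> SNN clustering, end to end."""
    kept, report = qc_filter(counts, max_genes=max_genes, max_mito=max_mito)
    norm = normalize(kept)
    emb = pca_embed(norm, n_pcs=n_pcs, n_hvg=n_hvg)
    assign = snn_cluster(emb, k_neighbors=k_neighbors,
                         resolution=resolution, seed=seed)
    assign.labels.index = pd.Index(norm.barcodes, name="barcode")
    return norm, ClusterAssignment(assign.labels), report
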
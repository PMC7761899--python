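"""Gene set variation analysis (GSVA) enrichment scores, from scratch.

Given a genes x samples expression matrix on a continuous (log) scale
and a collection of gene sets, the statistic proceeds in three steps:

1. **Kernel CDF transform.** Each gene's expression profile across
   samples is converted to a smoothed empirical CDF using a Gaussian
   kernel with bandwidth h_i = s_i / 4 (s_i the per-gene sample
   standard deviation):

       z_ij = (1/n) * sum_w Phi((x_ij - x_iw) / h_i)

   A constant gene (s_i = 0) carries no ranking information and maps to
   z = 0.5 everywhere.

2. **Rank symmetrization.** Per sample, genes are ranked by decreasing
   z (tau = 1 for the highest); the rank statistic r = |p/2 - tau|
   up-weights both extremes of the distribution.

3. **Weighted KS random walk.** Walking the genes of a sample in
   decreasing-z order, the walk statistic at step l is

       nu(l) = sum_{i<=l, i in set} r_i^tau_w / sum_{i in set} r_i^tau_w
             - #{i<=l, i not in set} / (p - |set|)

   The enrichment score is either ``max_diff`` (max nu + min nu, the
   default) or ``max_dev`` (nu at the largest |nu|); both lie in
   [-1, +1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr  # standard normal CDF, vectorized

from .containers import ExpressionTable, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class KcdfMatrix:
    """Kernel-CDF-transformed expression: z in (0,1), genes x samples."""

    z: pd.DataFrame
    bandwidths: pd.Series  # per-gene h_i
    n_degenerate: int = 0  # constant genes mapped to z = 0.5


@dataclass
class RankStatMatrix:
    """Decreasing-z gene orderings and symmetrized rank statistics.

    ``order[:, j]`` lists gene row indices of sample j from highest to
    lowest z; ``r[i, j] = |p/2 - tau_ij|`` where tau is gene i's rank
    in sample j (1 = highest).
    """

    order: np.ndarray  # p x n int, walk order per sample
    tau: np.ndarray  # p x n int ranks, 1-based
    r: np.ndarray  # p x n float
    genes: list[str]
    samples: list[str]

    @property
    def p(self) -> int:
        return self.r.shape[0]


@dataclass
class GsvaScoreMatrix:
    """Gene sets x samples enrichment scores, each in [-1, +1]."""

    scores: pd.DataFrame
    set_sizes: pd.Series  # genes used per set, after intersection
    missing_genes: pd.Series  # signature genes absent from the matrix


def kcdf_transform(expr: ExpressionTable) -> KcdfMatrix:
    """Gaussian-kernel CDF transform of each gene across samples."""
    if expr.scale == "raw-count":
        raise ValueError("kcdf_transform expects a continuous (log) scale")
    x = expr.values.to_numpy(dtype=float)
    p, n = x.shape
    if n < 2:
        raise ValueError("kernel CDF needs at least 2 samples")
    s = x.std(axis=1, ddof=1)
    if (s == 0).all():
        raise ValueError("all genes are constant across samples")
    h = s / 4.0
    z = np.empty_like(x)
    degenerate = s == 0
    z[degenerate] = 0.5
    live = np.flatnonzero(~degenerate)
    # pairwise kernel evaluation per gene; chunked to bound memory at
    # chunk * n * n floats
    chunk = max(1, int(1e7 // (n * n)))
    for start in range(0, len(live), chunk):
        idx = live[start:start + chunk]
        diff = (x[idx, :, None] - x[idx, None, :]) / h[idx, None, None]
        z[idx] = ndtr(diff).mean(axis=2)
    if degenerate.any():
        logger.info("%d constant genes mapped to z = 0.5", degenerate.sum())
    return KcdfMatrix(
        z=pd.DataFrame(z, index=expr.values.index, columns=expr.values.columns),
        bandwidths=pd.Series(h, index=expr.values.index),
        n_degenerate=int(degenerate.sum()),
    )


def rank_stats(kcdf: KcdfMatrix) -> RankStatMatrix:
    """Per-sample decreasing-z ranks and symmetrized rank statistic.

    Ties in z are broken by input gene order (stable sort), so the
    output is deterministic.
    """
    z = kcdf.z.to_numpy()
    p, n = z.shape
    order = np.argsort(-z, axis=0, kind="stable")  # walk order per sample
    tau = np.empty_like(order)
    rows = np.arange(p)
    for j in range(n):
        tau[order[:, j], j] = rows + 1
    r = np.abs(p / 2.0 - tau)
    return RankStatMatrix(
        order=order, tau=tau, r=r,
        genes=list(kcdf.z.index), samples=list(kcdf.z.columns),
    )


def enrichment_score(
    rs: RankStatMatrix,
    gene_set: set[str] | list[str],
    sample: int,
    tau_weight: float = 1.0,
    mode: str = "max_diff",
) -> float:
    """Enrichment score of one gene set in one sample.

    ``mode='max_diff'`` returns max(nu) + min(nu) over the walk;
    ``mode='max_dev'`` returns nu at the position of largest |nu|.
    """
    member = _membership(rs, gene_set)
    return float(_es_column(rs, member, sample, tau_weight, mode))


def _membership(rs: RankStatMatrix, gene_set) -> np.ndarray:
    gene_set = set(gene_set)
    member = np.fromiter((g in gene_set for g in rs.genes), bool, len(rs.genes))
    size = int(member.sum())
    if size == 0:
        raise ValueError("no signature genes present in the matrix")
    if size == rs.p:
        raise ValueError("gene set covers the whole matrix; penalty undefined")
    return member


def _es_column(
    rs: RankStatMatrix, member: np.ndarray, j: int,
    tau_weight: float, mode: str,
) -> float:
    if mode not in ("max_diff", "max_dev"):
        raise ValueError("mode must be 'max_diff' or 'max_dev'")
    order = rs.order[:, j]
    in_set = member[order]
    w = np.where(in_set, rs.r[order, j] ** tau_weight, 0.0)
    denom = w.sum()
    if denom == 0:  # all member ranks exactly p/2 with weight 0^tau
        hits = np.cumsum(in_set) / in_set.sum()
    else:
        hits = np.cumsum(w) / denom
    misses = np.cumsum(~in_set) / (rs.p - in_set.sum())
    nu = hits - misses
    if mode == "max_diff":
        return nu.max() + nu.min()
    return nu[np.argmax(np.abs(nu))]


def gsva(
    expr: ExpressionTable,
    signatures: GeneSetCollection,
    tau_weight: float = 1.0,
    mode: str = "max_diff",
) -> GsvaScoreMatrix:
    """Score every gene set in every sample.

    Signature genes absent from the expression matrix are intersected
    out; their per-set counts are reported in the result. A set with no
    genes left raises, naming the set.
    """
    kcdf = kcdf_transform(expr)
    rs = rank_stats(kcdf)
    genes_present = set(rs.genes)
    scores = np.empty((len(signatures), len(rs.samples)))
    sizes, missing = {}, {}
    for k, gs in enumerate(signatures):
        present = [g for g in gs.genes if g in genes_present]
        missing[gs.name] = len(gs.genes) - len(present)
        sizes[gs.name] = len(present)
        if missing[gs.name]:
            logger.info(
                "set %s: %d/%d genes missing from matrix",
                gs.name, missing[gs.name], len(gs.genes),
            )
        try:
            member = _membership(rs, present)
        except ValueError as e:
            raise ValueError(f"gene set {gs.name!r}: {e}") from None
        for j in range(len(rs.samples)):
            scores[k, j] = _es_column(rs, member, j, tau_weight, mode)
    return GsvaScoreMatrix(
        scores=pd.DataFrame(scores, index=signatures.names, columns=rs.samples),
        set_sizes=pd.Series(sizes),
        missing_genes=pd.Series(missing),
    )
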
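"""One-vs-rest cluster markers and top-100 signature gene sets.

Each cluster is compared against all remaining cells with the
two-sided Wilcoxon rank-sum test (exact null distribution for small
tie-free groups; tie-corrected, continuity-corrected normal
approximation otherwise). The average log fold
change follows the convention of comparing de-logged means with a
pseudocount:

    avg_logfc = ln((mean(expm1(x_in)) + 1) / (mean(expm1(x_out)) + 1))

Signatures keep, per cluster, the significant positive markers with the
largest fold change, truncated at 100 genes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .containers import GeneSet, GeneSetCollection, NormalizedMatrix
from .pipeline import ClusterAssignment

logger = logging.getLogger(__name__)


def wilcoxon_one_vs_rest(
    norm: NormalizedMatrix, clusters: ClusterAssignment, cluster: int
) -> pd.DataFrame:
    """Per-gene marker statistics of one cluster against the rest.

    Returns a frame with gene, cluster, avg_logfc, p_value, adj_p
    (Bonferroni across genes), pct_in, pct_out.
    """
    mask = (clusters.labels == cluster).to_numpy()
    n_in, n_out = int(mask.sum()), int((~mask).sum())
    if n_in == 0 or n_out == 0:
        raise ValueError(f"cluster {cluster}: empty group (in={n_in}, out={n_out})")
    if n_in == 1:
        logger.warning("cluster %s has a single cell; low-power test", cluster)

    x_in = norm.values[:, mask]
    x_out = norm.values[:, ~mask]

    # "auto" uses the exact null distribution for small tie-free groups
    # and the tie-corrected normal approximation otherwise
    res = mannwhitneyu(x_in, x_out, axis=1, alternative="two-sided",
                       method="auto")
    p = np.asarray(res.pvalue)

    # identical groups give sd 0 inside the normal approximation; the
    # test is then degenerate and p = 1 by convention
    constant = np.all(norm.values == norm.values[:, :1], axis=1)
    p = np.where(constant, 1.0, p)

    mean_in = np.expm1(x_in).mean(axis=1)
    mean_out = np.expm1(x_out).mean(axis=1)
    lfc = np.log((mean_in + 1) / (mean_out + 1))

    df = pd.DataFrame(
        {
            "gene": norm.genes,
            "cluster": cluster,
            "avg_logfc": lfc,
            "p_value": p,
            "adj_p": np.minimum(1.0, p * norm.n_genes),
            "pct_in": (x_in > 0).mean(axis=1),
            "pct_out": (x_out > 0).mean(axis=1),
        }
    )
    return df


def all_markers(
    norm: NormalizedMatrix, clusters: ClusterAssignment, min_pct: float = 0.0
) -> pd.DataFrame:
    """Marker statistics for every cluster, concatenated.

    ``min_pct`` optionally drops genes detected in fewer than that
    fraction of cells in both groups before testing (off by default).
    """
    frames = []
    for k in clusters.sizes.index:
        df = wilcoxon_one_vs_rest(norm, clusters, int(k))
        if min_pct > 0:
            df = df[(df["pct_in"] >= min_pct) | (df["pct_out"] >= min_pct)]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def build_signatures(
    stats: pd.DataFrame, max_genes: int = 100, alpha: float = 0.05
) -> GeneSetCollection:
    """Top-``max_genes`` signature per cluster from marker statistics.

    Per cluster: keep genes with Bonferroni-adjusted p < alpha and
    positive fold change, sort by avg_logfc descending (ties: smaller p
    first, then symbol), truncate. Clusters with no qualifying marker
    yield an empty set and a warning rather than disappearing.
    """
    sets = []
    for k, grp in stats.groupby("cluster", sort=True):
        sig = grp[(grp["adj_p"] < alpha) & (grp["avg_logfc"] > 0)]
        sig = sig.sort_values(
            ["avg_logfc", "p_value", "gene"], ascending=[False, True, True]
        ).head(max_genes)
        if sig.empty:
            logger.warning("cluster %s: no significant positive markers", k)
        sets.append(
            GeneSet(
                name=f"cluster{k}",
                genes=list(sig["gene"]),
                description=f"top {max_genes} markers of cluster {k}",
            )
        )
    return GeneSetCollection(sets)
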
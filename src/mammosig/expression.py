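"""Per-cluster expression summaries, fold ratios, and expressed-gene
set partitions (Venn regions) for selected genes."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import NormalizedMatrix
from .pipeline import ClusterAssignment


@dataclass
class ClusterGeneSummary:
    gene: str
    table: pd.DataFrame  # cluster, mean, sd, median, frac_nonzero, shaded


def cluster_gene_summary(
    norm: NormalizedMatrix,
    clusters: ClusterAssignment,
    gene: str,
    scale: str = "lognorm",
    shade_threshold: float = 0.1,
) -> ClusterGeneSummary:
    """Mean/sd/median of a gene's expression per cluster.

    ``scale='lognorm'`` summarises the log-normalized values directly;
    ``scale='relmax'`` first divides by the gene's all-cell maximum so
    values are comparable across genes. Clusters whose mean exceeds
    ``shade_threshold`` are flagged (the >0.1 shading convention).
    """
    gi = norm.gene_index(gene)  # raises with near-matches when absent
    x = norm.values[gi]
    if scale == "relmax":
        m = x.max()
        x = x / m if m > 0 else x
    elif scale != "lognorm":
        raise ValueError("scale must be 'lognorm' or 'relmax'")
    rows = []
    for k in clusters.sizes.index:
        vals = x[(clusters.labels == k).to_numpy()]
        rows.append(
            {
                "cluster": k,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=0)),
                "median": float(np.median(vals)),
                "frac_nonzero": float((vals > 0).mean()),
            }
        )
    table = pd.DataFrame(rows)
    table["shaded"] = table["mean"] > shade_threshold
    return ClusterGeneSummary(gene=gene, table=table)


def fold_ratio(value_a: float, value_b: float) -> float:
    """a / b rounded half-up to one decimal.

    A zero denominator is an error: the comparison is then "exclusive
    expression", not a ratio.
    """
    if value_b == 0:
        raise ZeroDivisionError(
            "denominator is zero: report exclusive expression, not a ratio"
        )
    ratio = Decimal(value_a) / Decimal(value_b)
    return float(ratio.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def expressed_gene_sets(
    norm: NormalizedMatrix,
    clusters: ClusterAssignment,
    genes: list[str],
    which_clusters: list[int],
    min_frac: float = 0.1,
) -> tuple[dict[int, set[str]], dict[frozenset, set[str]]]:
    """Per-cluster expressed-gene sets and their Venn region partition.

    A gene counts as expressed in a cluster iff it is nonzero in at
    least ``min_frac`` of that cluster's cells. Returns the per-cluster
    sets and, for every non-empty combination of the selected clusters,
    the genes expressed in exactly that combination (2^m - 1 regions,
    pairwise disjoint, union = genes detected anywhere).
    """
    if not genes:
        raise ValueError("empty gene list")
    if not which_clusters:
        raise ValueError("select at least one cluster")
    per_cluster: dict[int, set[str]] = {k: set() for k in which_clusters}
    for g in genes:
        gi = norm.gene_index(g)
        for k in which_clusters:
            vals = norm.values[gi][(clusters.labels == k).to_numpy()]
            if len(vals) and (vals > 0).mean() >= min_frac:
                per_cluster[k].add(g)
    regions: dict[frozenset, set[str]] = {}
    m = len(which_clusters)
    for size in range(1, m + 1):
        for combo in combinations(which_clusters, size):
            inside = set.intersection(*(per_cluster[k] for k in combo))
            outside = set.union(
                set(), *(per_cluster[k] for k in which_clusters if k not in combo)
            )
            regions[frozenset(combo)] = inside - outside
    return per_cluster, regions
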
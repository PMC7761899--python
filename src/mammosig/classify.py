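"""Argmax classification of tumors by GSVA score, receptor subtyping,
coverage statistics and subtype cross-tabulations."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .gsva import GsvaScoreMatrix

logger = logging.getLogger(__name__)

SUBTYPES = ("ER+HER2-", "ER+HER2+", "ER-HER2+", "TNBC", "unknown")


def assign_clusters(scores: GsvaScoreMatrix) -> pd.DataFrame:
    """Assign each tumor the cluster with the highest enrichment score.

    Exact ties are flagged (``is_tie``) and broken toward the lowest
    cluster label (first row in the score matrix).
    """
    df = scores.scores
    arr = df.to_numpy()
    best = arr.argmax(axis=0)  # argmax returns the first maximum
    best_score = arr[best, np.arange(arr.shape[1])]
    ties = (arr == best_score).sum(axis=0) > 1
    out = pd.DataFrame(
        {
            "sample": df.columns,
            "assigned_cluster": [df.index[b] for b in best],
            "assigned_score": best_score,
            "is_tie": ties,
        }
    )
    if ties.any():
        logger.warning("%d tumors with tied top scores", int(ties.sum()))
    return out


def map_subtype(er: str, pr: str, her2: str) -> str:
    """Receptor status to clinical subtype.

    ER+HER2- and ER+HER2+ (luminal A/B), ER-HER2+ (HER2), and
    triple-negative; any combination outside those four groups
    (including unknown statuses) maps to ``unknown``. PR enters only
    the triple-negative rule.
    """
    if er == "+" and her2 == "-":
        return "ER+HER2-"
    if er == "+" and her2 == "+":
        return "ER+HER2+"
    if er == "-" and her2 == "+":
        return "ER-HER2+"
    if er == "-" and pr == "-" and her2 == "-":
        return "TNBC"
    return "unknown"


def build_records(
    assignments: pd.DataFrame, clinical: pd.DataFrame
) -> pd.DataFrame:
    """Join cluster assignments with clinical fields and derive subtypes."""
    rec = assignments.merge(clinical, on="sample", how="left")
    rec["subtype"] = [
        map_subtype(e, p, h)
        for e, p, h in zip(
            rec.get("er", "NA"), rec.get("pr", "NA"), rec.get("her2", "NA")
        )
    ]
    return rec


@dataclass
class CoverageReport:
    per_cluster: pd.DataFrame  # cluster, n, percent
    subset_clusters: list
    subset_count: int
    subset_percent: float
    total: int


def coverage(records: pd.DataFrame, subset: list | None = None) -> CoverageReport:
    """Per-cluster tumor counts/percentages and a named-subset aggregate.

    Percentages are reported to one decimal; the subset aggregate is
    the sum of its member percentages alongside the raw-count fraction.
    """
    if len(records) == 0:
        raise ValueError("empty record table")
    total = len(records)
    counts = records["assigned_cluster"].value_counts().sort_index()
    per_cluster = pd.DataFrame(
        {
            "cluster": counts.index,
            "n": counts.values,
            "percent": np.round(100.0 * counts.values / total, 1),
        }
    ).reset_index(drop=True)
    subset = list(subset) if subset is not None else list(counts.index)
    member = per_cluster["cluster"].isin(subset)
    return CoverageReport(
        per_cluster=per_cluster,
        subset_clusters=subset,
        subset_count=int(per_cluster.loc[member, "n"].sum()),
        subset_percent=float(np.round(per_cluster.loc[member, "percent"].sum(), 1)),
        total=total,
    )


def subtype_crosstab(records: pd.DataFrame) -> pd.DataFrame:
    """Within-subtype percentage of tumors per assigned cluster.

    Rows are subtypes (``unknown`` excluded), columns clusters; each
    row sums to 100. Subtypes with zero tumors are omitted with a
    warning.
    """
    known = records[records["subtype"] != "unknown"]
    rows = {}
    for st in SUBTYPES[:-1]:
        grp = known[known["subtype"] == st]
        if grp.empty:
            logger.warning("subtype %s has zero tumors; row omitted", st)
            continue
        counts = grp["assigned_cluster"].value_counts()
        rows[st] = 100.0 * counts / len(grp)
    tab = pd.DataFrame(rows).T.fillna(0.0)
    return tab[sorted(tab.columns)] if len(tab) else tab


def score_group_summary(
    scores: GsvaScoreMatrix, assignments: pd.DataFrame
) -> pd.DataFrame:
    """Mean score of every signature within each designated tumor group,
    with a rank-sum p-value comparing the designated signature's scores
    against each other signature's scores in that group."""
    out = []
    for designated, grp in assignments.groupby("assigned_cluster"):
        cols = grp["sample"]
        sub = scores.scores[cols]
        own = sub.loc[designated]
        for other in scores.scores.index:
            row = {
                "designated": designated,
                "signature": other,
                "mean_score": float(sub.loc[other].mean()),
                "n_tumors": len(cols),
            }
            if other != designated and len(cols) > 1:
                row["p_vs_designated"] = float(
                    mannwhitneyu(own, sub.loc[other],
                                 alternative="two-sided").pvalue
                )
            else:
                row["p_vs_designated"] = np.nan
            out.append(row)
    return pd.DataFrame(out)
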
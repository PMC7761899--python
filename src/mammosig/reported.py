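"""Published summary values of the target study, used as inputs.

The original tissue and TCGA downloads are not redistributable, but the
study's printed tables are: cluster cell counts, tumor-coverage
percentages, per-cluster relative expression of *EPCAM*, and the
TNBC hazard ratio. The functions here recompute the derived quantities
(percentages, aggregates, fold ratios, reciprocal hazard ratios) from
those printed inputs through the same package routines the synthetic
pipeline uses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .expression import fold_ratio

# cluster -> number of cells (published cluster distribution table)
CLUSTER_CELL_COUNTS = {
    0: 769, 1: 749, 2: 453, 3: 336, 4: 305,
    5: 188, 6: 161, 7: 153, 8: 48, 9: 31,
}
TOTAL_CELLS = 3193

# tumor classification coverage: counts and printed per-cluster percentages
TUMORS_TOP5 = 946
TUMORS_TOTAL = 1100
CLUSTER_TUMOR_PCT = {2: 22.6, 3: 22.0, 7: 8.9, 8: 23.2, 9: 9.3}
EPITHELIAL_CLUSTERS = (2, 7, 9)
STROMA_IMMUNE_CLUSTERS = (3, 8)

# relative EPCAM expression per cluster (published mean values)
EPCAM_MEAN = {2: 0.42, 7: 0.12, 9: 1.15}

# average genes defining a cluster vs genes detected tissue-wide
GENES_PER_CLUSTER = 1290
GENES_TOTAL = 20_345

# TNBC cluster-9-vs-cluster-7 hazard ratio (cluster 9 as reference)
HR_C7_VS_C9 = 0.2863


def cluster_percentages() -> pd.Series:
    """Per-cluster percentage of total cells, one decimal."""
    counts = pd.Series(CLUSTER_CELL_COUNTS).sort_index()
    assert counts.sum() == TOTAL_CELLS
    return (100.0 * counts / counts.sum()).round(1)


def top5_coverage_percent() -> float:
    """Percent of tumors classified by the five covering clusters."""
    return float(np.round(100.0 * TUMORS_TOP5 / TUMORS_TOTAL, 1))


def epithelial_coverage_percent() -> float:
    """Summed coverage of the three epithelial cluster signatures."""
    return float(np.round(
        sum(CLUSTER_TUMOR_PCT[k] for k in EPITHELIAL_CLUSTERS), 1
    ))


def stroma_immune_coverage_percent() -> float:
    """Summed coverage of the fibroblast and immune cluster signatures."""
    return float(np.round(
        sum(CLUSTER_TUMOR_PCT[k] for k in STROMA_IMMUNE_CLUSTERS), 1
    ))


def epcam_fold_ratios() -> dict[str, float]:
    """EPCAM fold ratios of cluster 9 over clusters 2 and 7."""
    return {
        "cl9_vs_cl2": fold_ratio(EPCAM_MEAN[9], EPCAM_MEAN[2]),
        "cl9_vs_cl7": fold_ratio(EPCAM_MEAN[9], EPCAM_MEAN[7]),
    }


def cluster_gene_fraction_percent() -> int:
    """Average cluster-defining genes as a percent of detected genes."""
    return int(round(100.0 * GENES_PER_CLUSTER / GENES_TOTAL))


def reciprocal_hazard_ratio(hr: float = HR_C7_VS_C9) -> float:
    """Invert a hazard ratio (swap the reference group), 3 decimals."""
    return float(np.round(1.0 / hr, 3))
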
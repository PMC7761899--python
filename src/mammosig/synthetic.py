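"""Synthetic single-cell and bulk-tumor data with known ground truth.

The single-cell generator emulates a droplet scRNA-seq experiment on a
tissue with K discrete cell types: gene-wise negative-binomial UMI
counts with a shared dispersion, type-specific marker genes elevated by
a known log fold change, a contiguous block of mitochondrially named
genes, log-normal library sizes, and a handful of "aggregate" cells
(sums of two cells) that inflate detected-gene counts to exercise the
QC filter. The bulk generator produces tumors as noisy mixtures
dominated by one cell-type profile, with receptor labels and
exponential survival times whose hazard depends on the generating type.

Default parameters mirror the tissue the pipeline targets: 3193 cells
in 10 types with the observed type proportions, ~20k genes, and 100
markers per type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import UmiCountMatrix

# cell-type proportions of the target tissue (10 types, largest first)
_DEFAULT_PROPS = (
    769 / 3193, 749 / 3193, 453 / 3193, 336 / 3193, 305 / 3193,
    188 / 3193, 161 / 3193, 153 / 3193, 48 / 3193, 31 / 3193,
)

AGGREGATE_LABEL = "aggregate"


@dataclass
class ScSimConfig:
    """Parameters of the single-cell UMI count simulation."""

    n_cells: int = 3193
    n_genes: int = 20_345
    k_types: int = 10
    type_props: tuple[float, ...] = _DEFAULT_PROPS
    markers_per_type: int = 100
    marker_logfc: float = math.log(4.0)
    nb_dispersion: float = 0.3
    libsize_mu: float = math.log(5000.0)
    libsize_sigma: float = 0.35
    frac_mito_genes: float = 0.05
    n_aggregate_cells: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_genes", "k_types", "markers_per_type",
                     "n_aggregate_cells", "seed"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ValueError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.n_cells == 0 or self.n_genes == 0 or self.k_types == 0:
            raise ValueError("n_cells, n_genes and k_types must be positive")
        props = np.asarray(self.type_props, dtype=float)
        if len(props) != self.k_types:
            raise ValueError("type_props length must equal k_types")
        if (props < 0).any() or (props > 1).any():
            raise ValueError("type proportions must lie in [0, 1]")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("type_props must sum to 1 within 1e-9")
        if not 0 <= self.frac_mito_genes < 1:
            raise ValueError("frac_mito_genes must lie in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_aggregate_cells >= self.n_cells:
            raise ValueError("n_aggregate_cells must be smaller than n_cells")
        n_mito = int(round(self.frac_mito_genes * self.n_genes))
        if self.markers_per_type * self.k_types > self.n_genes - n_mito:
            raise ValueError(
                "markers_per_type x k_types exceeds the non-mitochondrial "
                "gene count"
            )


@dataclass
class BulkSimConfig:
    """Parameters of the bulk tumor expression + clinical simulation."""

    n_tumors: int = 300
    purity: float = 0.8
    noise_sd: float = 0.8
    subtype_rule: dict[str, tuple[str, str, str]] = field(default_factory=dict)
    baseline_hazard: float = 0.01
    hazard_multipliers: dict[str, float] = field(default_factory=dict)
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.n_tumors, (int, np.integer)) or self.n_tumors <= 0:
            raise ValueError("n_tumors must be a positive integer")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if any(m <= 0 for m in self.hazard_multipliers.values()):
            raise ValueError("hazard_multipliers must be strictly positive")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Generating labels backing a synthetic dataset."""

    cell_type_of_cell: pd.Series | None = None
    generating_type_of_tumor: pd.Series | None = None
    true_marker_genes: dict[str, list[str]] | None = None


def simulate_sc(config: ScSimConfig) -> tuple[UmiCountMatrix, GroundTruth]:
    """Draw a genes x cells UMI count matrix with known cell types.

    Gene-wise counts follow NB(mean mu_ij, shared dispersion) where
    mu_ij is the cell's library size times the gene's relative weight in
    the cell's type; each type's marker block is elevated by
    exp(marker_logfc) in its own type. The first block of genes carries
    a mitochondrial prefix and a fixed share of baseline expression.
    The last ``n_aggregate_cells`` columns are sums of two sampled
    cells, labelled ``aggregate`` in the ground truth.
    """
    rng = np.random.default_rng(config.seed)
    n_mito = int(round(config.frac_mito_genes * config.n_genes))
    genes = [f"MT-G{i:05d}" for i in range(n_mito)] + [
        f"G{i:05d}" for i in range(n_mito, config.n_genes)
    ]
    types = [f"type{t}" for t in range(config.k_types)]

    # baseline relative expression weights, log-normal across genes
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    if n_mito and config.frac_mito_genes > 0:
        non_mito_sum = weights[n_mito:].sum()
        target = config.frac_mito_genes / (1 - config.frac_mito_genes)
        weights[:n_mito] *= target * non_mito_sum / weights[:n_mito].sum()

    # marker blocks live in the non-mitochondrial region, one per type
    marker_genes: dict[str, list[str]] = {}
    type_weights = np.tile(weights, (config.k_types, 1))  # types x genes
    for t in range(config.k_types):
        lo = n_mito + t * config.markers_per_type
        hi = lo + config.markers_per_type
        type_weights[t, lo:hi] *= math.exp(config.marker_logfc)
        marker_genes[types[t]] = genes[lo:hi]

    n_real = config.n_cells - config.n_aggregate_cells
    cell_types = rng.choice(
        config.k_types, size=n_real, p=np.asarray(config.type_props)
    )
    libsizes = rng.lognormal(config.libsize_mu, config.libsize_sigma, size=n_real)

    r = 1.0 / config.nb_dispersion
    cols: list[sp.csc_matrix] = []
    chunk = max(1, int(2e7 // config.n_genes))  # bound dense scratch memory
    for start in range(0, n_real, chunk):
        stop = min(start + chunk, n_real)
        w = type_weights[cell_types[start:stop]]  # cells x genes
        mu = w / w.sum(axis=1, keepdims=True) * libsizes[start:stop, None]
        p = r / (r + mu)
        block = rng.negative_binomial(r, p).astype(np.int64)
        cols.append(sp.csc_matrix(block.T))
    counts = sp.hstack(cols, format="csc") if cols else sp.csc_matrix(
        (config.n_genes, 0), dtype=np.int64
    )

    labels = [types[t] for t in cell_types]
    if config.n_aggregate_cells:
        pairs = rng.choice(n_real, size=(config.n_aggregate_cells, 2))
        agg = counts[:, pairs[:, 0]] + counts[:, pairs[:, 1]]
        counts = sp.hstack([counts, sp.csc_matrix(agg)], format="csc")
        labels += [AGGREGATE_LABEL] * config.n_aggregate_cells

    barcodes = [f"BC{i:06d}" for i in range(config.n_cells)]
    umi = UmiCountMatrix(counts, genes, barcodes)
    truth = GroundTruth(
        cell_type_of_cell=pd.Series(labels, index=barcodes, name="cell_type"),
        true_marker_genes=marker_genes,
    )
    return umi, truth


def type_log2_profiles(
    umi: UmiCountMatrix, cell_types: pd.Series, scale: float = 10_000.0
) -> pd.DataFrame:
    """Per-type mean expression profiles on the log2 scale.

    For each type, genes' mean normalized expression across that type's
    cells, as log2(1 + scale * mean(c_ij / C_j)); genes x types frame
    suitable as input to :func:`simulate_bulk`.
    """
    totals = umi.counts_per_cell().astype(float)
    if (totals == 0).any():
        raise ValueError("zero-total cells; run QC first")
    frac = umi.counts.multiply(1.0 / totals).tocsc()
    out = {}
    for t in pd.unique(cell_types):
        mask = (cell_types == t).to_numpy()
        mean_frac = np.asarray(frac[:, mask].mean(axis=1)).ravel()
        out[t] = np.log2(1 + scale * mean_frac)
    return pd.DataFrame(out, index=umi.genes)


def simulate_bulk(
    config: BulkSimConfig, type_profiles: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate bulk tumors dominated by one cell-type profile each.

    Every tumor draws a generating type uniformly; its expression column
    is ``purity * profile_type + (1 - purity) * mean_profile`` plus
    Gaussian noise (sd = noise_sd) on the log2 scale. Survival times are
    exponential with rate ``baseline_hazard * hazard_multipliers[type]``
    under independent exponential censoring calibrated so the expected
    censored fraction is ``censor_rate``.

    Returns (expression genes x tumors, clinical table, ground truth).
    """
    if type_profiles.shape[0] == 0 or type_profiles.shape[1] == 0:
        raise ValueError("type_profiles must be non-empty")
    if config.subtype_rule:
        missing = set(config.subtype_rule) - set(type_profiles.columns)
        if missing:
            raise ValueError(f"subtype_rule references unknown types: {missing}")
    rng = np.random.default_rng(config.seed)
    types = list(type_profiles.columns)
    gen = rng.integers(len(types), size=config.n_tumors)
    profiles = type_profiles.to_numpy(dtype=float)
    mean_profile = profiles.mean(axis=1)

    expr = (
        config.purity * profiles[:, gen]
        + (1 - config.purity) * mean_profile[:, None]
    )
    if config.noise_sd > 0:
        expr = expr + rng.normal(0.0, config.noise_sd, size=expr.shape)

    samples = [f"TUMOR{i:04d}" for i in range(config.n_tumors)]
    expr_df = pd.DataFrame(expr, index=type_profiles.index, columns=samples)

    mults = np.array(
        [config.hazard_multipliers.get(types[t], 1.0) for t in gen]
    )
    rates = config.baseline_hazard * mults
    t_event = rng.exponential(1.0 / rates)
    if config.censor_rate > 0:
        lam_c = rates.mean() * config.censor_rate / (1 - config.censor_rate)
        t_cens = rng.exponential(1.0 / lam_c, size=config.n_tumors)
    else:
        t_cens = np.full(config.n_tumors, np.inf)
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)

    receptors = [
        config.subtype_rule.get(types[t], ("NA", "NA", "NA")) for t in gen
    ]
    clinical = pd.DataFrame(
        {
            "sample": samples,
            "er": [r[0] for r in receptors],
            "pr": [r[1] for r in receptors],
            "her2": [r[2] for r in receptors],
            "os_time": os_time,
            "os_event": os_event,
        }
    )
    truth = GroundTruth(
        generating_type_of_tumor=pd.Series(
            [types[t] for t in gen], index=samples, name="generating_type"
        )
    )
    return expr_df, clinical, truth


def dominant_type_per_cluster(
    cluster_labels: pd.Series, cell_types: pd.Series
) -> dict:
    """Map each cluster label to the most frequent ground-truth type
    among its cells (evaluation helper for recovery checks)."""
    aligned = cell_types.reindex(cluster_labels.index)
    return {
        k: aligned[cluster_labels == k].mode().iloc[0]
        for k in sorted(cluster_labels.unique())
    }


def write_ground_truth(truth: GroundTruth, dir_path: str | Path) -> None:
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    if truth.cell_type_of_cell is not None:
        truth.cell_type_of_cell.rename_axis("barcode").to_frame().to_csv(
            d / "cell_types.tsv", sep="\t"
        )
    if truth.generating_type_of_tumor is not None:
        truth.generating_type_of_tumor.rename_axis("sample").to_frame().to_csv(
            d / "tumor_types.tsv", sep="\t"
        )
    if truth.true_marker_genes is not None:
        lines = [
            "\t".join([t, *genes]) for t, genes in truth.true_marker_genes.items()
        ]
        (d / "true_markers.tsv").write_text("\n".join(lines) + "\n")
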
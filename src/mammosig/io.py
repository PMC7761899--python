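"""Readers and writers for the on-disk formats the pipeline touches.

All parsers validate strictly and raise :class:`FormatError` rather than
coercing malformed input. Gene identifiers are matched case-sensitively
as plain symbols; no alias resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import (
    ExpressionTable,
    FormatError,
    GeneSet,
    GeneSetCollection,
    UmiCountMatrix,
)

logger = logging.getLogger(__name__)

_STATUS_VALUES = {"+", "-", "NA"}


def read_mtx_triplet(dir_path: str | Path) -> UmiCountMatrix:
    """Read a CellRanger-style triplet (matrix.mtx, barcodes.tsv, features.tsv).

    The matrix is genes x cells in MatrixMarket coordinate format;
    dimensions must match the sidecar line counts and all entries must
    be non-negative integers.
    """
    d = Path(dir_path)
    mtx_path = d / "matrix.mtx"
    bc_path = d / "barcodes.tsv"
    ft_path = d / "features.tsv"
    for p in (mtx_path, bc_path, ft_path):
        if not p.exists():
            raise FormatError(f"missing file: {p}")
    mat = sp.csc_matrix(scipy.io.mmread(mtx_path))
    barcodes = bc_path.read_text().splitlines()
    features = [line.split("\t")[0] for line in ft_path.read_text().splitlines()]
    if mat.shape[0] != len(features):
        raise FormatError(
            f"features.tsv has {len(features)} lines but matrix.mtx declares "
            f"{mat.shape[0]} rows"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"barcodes.tsv has {len(barcodes)} lines but matrix.mtx declares "
            f"{mat.shape[1]} columns"
        )
    if mat.nnz and not np.issubdtype(mat.dtype, np.integer):
        if not np.all(mat.data == np.round(mat.data)):
            raise FormatError("matrix.mtx contains non-integer entries")
    return UmiCountMatrix(mat, features, barcodes)


def write_mtx_triplet(umi: UmiCountMatrix, dir_path: str | Path) -> None:
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(d / "matrix.mtx", sp.coo_matrix(umi.counts), field="integer")
    (d / "barcodes.tsv").write_text("\n".join(umi.barcodes) + "\n")
    (d / "features.tsv").write_text("\n".join(umi.genes) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: tab-separated name, description, genes...

    Gene order within a set is preserved; duplicate set names and lines
    with fewer than three fields are rejected.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{ln}: GMT line has fewer than 3 fields")
        name, desc, *genes = fields
        genes = [g for g in genes if g]
        if not genes:
            raise FormatError(f"{path}:{ln}: gene set {name!r} has no genes")
        if name in seen:
            raise FormatError(f"{path}:{ln}: duplicate gene set name {name!r}")
        seen.add(name)
        sets.append(GeneSet(name=name, genes=genes, description=desc))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for s in collection:
        if not s.genes:
            raise ValueError(f"cannot serialise empty gene set {s.name!r} to GMT")
        lines.append("\t".join([s.name, s.description, *s.genes]))
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class ClinicalTable:
    """Parsed clinical table plus a completeness report.

    ``records`` keeps every row; ``complete`` flags rows whose receptor
    and survival fields are all present (usable for subtype + survival
    analysis). Incomplete rows are flagged, never silently dropped.
    """

    records: pd.DataFrame
    n_total: int
    n_usable: int

    def usable(self) -> pd.DataFrame:
        return self.records[self.records["complete"]].copy()


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV: sample, er, pr, her2, os_time, os_event.

    Receptor statuses are ``+`` / ``-`` / ``NA``; os_time is a
    non-negative real (months); os_event is 0/1. Negative times and
    events outside {0, 1} are format errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample", "er", "pr", "her2", "os_time", "os_event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"clinical table missing columns: {missing}")

    out = pd.DataFrame({"sample": df["sample"]})
    for col in ("er", "pr", "her2"):
        bad = ~df[col].isin(_STATUS_VALUES | {""})
        if bad.any():
            raise FormatError(
                f"column {col!r}: invalid status {df.loc[bad, col].iloc[0]!r}"
            )
        out[col] = df[col].replace("", "NA")

    def _num(col: str) -> pd.Series:
        s = df[col].replace("", "nan")
        try:
            return s.astype(float)
        except ValueError as e:
            raise FormatError(f"column {col!r}: {e}") from None

    time = _num("os_time")
    if (time.dropna() < 0).any():
        raise FormatError("negative os_time")
    event = _num("os_event")
    if not event.dropna().isin([0.0, 1.0]).all():
        raise FormatError("os_event values must be 0 or 1")
    out["os_time"] = time
    out["os_event"] = event

    out["complete"] = (
        (out["er"] != "NA")
        & (out["pr"] != "NA")
        & (out["her2"] != "NA")
        & out["os_time"].notna()
        & out["os_event"].notna()
    )
    table = ClinicalTable(
        records=out, n_total=len(out), n_usable=int(out["complete"].sum())
    )
    logger.info(
        "clinical table: %d rows, %d usable", table.n_total, table.n_usable
    )
    return table


def read_expression_tsv(path: str | Path, scale: str = "log2") -> ExpressionTable:
    """Read a genes x samples expression TSV (first column = gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionTable(df, scale=scale)


def write_expression_tsv(table: ExpressionTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", index_label="gene")
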
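"""Readers and writers for the plain-text formats the pipeline consumes.

Counts arrive either as Matrix Market MTX (genes as rows, Cell Ranger
orientation, 1-based indices) with companion features/barcodes TSVs, or as a
dense CSV with gene rows and cell columns.  Marker tables are CSVs with the
standardized column set; cluster and truth labels are two-column TSVs.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .markerdb import (
    MARKER_COLUMNS,
    POLARITIES,
    WEIGHTED_COLUMNS,
    MarkerTable,
    MarkerTableError,
    WeightedMarkerTable,
)
from .preprocess import ExpressionData

logger = logging.getLogger(__name__)


class DimensionError(ValueError):
    """MTX dimensions disagree with the features/barcodes files."""


def _dedupe_ids(ids: Sequence[str], what: str) -> pd.Index:
    """Suffix duplicate identifiers with -1, -2, ... (logged)."""
    index = pd.Index(ids)
    if not index.has_duplicates:
        return index
    dupes = sorted(index[index.duplicated()].unique())
    logger.warning(
        "%d duplicated %s identifier(s), disambiguated by suffixing: %s%s",
        len(dupes),
        what,
        dupes[:10],
        "..." if len(dupes) > 10 else "",
    )
    seen: dict = {}
    out = []
    for name in index:
        n = seen.get(name, 0)
        out.append(name if n == 0 else f"{name}-{n}")
        seen[name] = n + 1
    return pd.Index(out)


def read_counts_mtx(
    mtx_path: str, features_path: str, barcodes_path: str
) -> ExpressionData:
    """Read a genes × cells MTX with companion features/barcodes TSVs."""
    matrix = scipy.io.mmread(mtx_path)
    features = pd.read_csv(features_path, sep="\t", header=None)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)
    genes = features.iloc[:, 0].astype(str).tolist()
    cells = barcodes.iloc[:, 0].astype(str).tolist()
    n_genes, n_cells = matrix.shape
    if n_genes != len(genes):
        raise DimensionError(
            f"MTX declares {n_genes} genes but features file has {len(genes)}"
        )
    if n_cells != len(cells):
        raise DimensionError(
            f"MTX declares {n_cells} cells but barcodes file has {len(cells)}"
        )
    if not np.allclose(matrix.data, np.round(matrix.data)):
        raise ValueError(f"{mtx_path}: non-integer count entries")
    counts = sp.csr_matrix(matrix).astype(np.int64)
    return ExpressionData(
        counts=counts,
        gene_ids=_dedupe_ids(genes, "gene"),
        cell_ids=_dedupe_ids(cells, "cell"),
    )


def read_counts_csv(path: str) -> ExpressionData:
    """Read a dense CSV with gene rows and cell columns."""
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy()
    if not np.allclose(values, np.round(values)):
        raise ValueError(f"{path}: non-integer count entries")
    return ExpressionData(
        counts=values.astype(np.int64),
        gene_ids=_dedupe_ids(df.index.astype(str), "gene"),
        cell_ids=_dedupe_ids(df.columns.astype(str), "cell"),
    )


def read_counts(
    counts: str,
    features: Optional[str] = None,
    barcodes: Optional[str] = None,
) -> ExpressionData:
    """Dispatch on format: MTX (with features/barcodes) or dense CSV."""
    if str(counts).endswith(".mtx"):
        if features is None or barcodes is None:
            raise ValueError("MTX input needs features and barcodes files")
        return read_counts_mtx(counts, features, barcodes)
    return read_counts_csv(counts)


def read_labels_tsv(path: str, value_name: str = "cluster") -> pd.Series:
    """Two-column TSV (barcode, label) → Series indexed by barcode."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    series = pd.Series(
        df.iloc[:, 1].to_numpy(),
        index=pd.Index(df.iloc[:, 0]),
        name=value_name,
    )
    return series


def read_marker_table(path: str, case_insensitive: bool = False) -> MarkerTable:
    """Validated, deduplicated marker table from the standardized CSV.

    Row-level violations (bad polarity, empty gene or source) are collected
    and reported together, each with its file line number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [c for c in MARKER_COLUMNS if c not in ("celltype_label", "disease")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MarkerTableError(f"{path}: missing required column(s): {missing}")
    problems = []
    for pos, (_, row) in enumerate(df.iterrows()):
        lineno = pos + 2  # header is line 1
        if row["polarity"].strip() not in POLARITIES:
            problems.append(
                f"line {lineno}: invalid polarity {row['polarity']!r}"
            )
        if not row["gene"].strip():
            problems.append(f"line {lineno}: empty gene symbol")
        if not row["source_id"].strip():
            problems.append(f"line {lineno}: empty source_id")
    if problems:
        raise MarkerTableError(f"{path}: " + "; ".join(problems))
    n_raw = len(df)
    table = MarkerTable(df, case_insensitive=case_insensitive)
    if len(table) < n_raw:
        logger.info(
            "%s: collapsed %d duplicate record(s)", path, n_raw - len(table)
        )
    return table


def write_weighted_markers(table: WeightedMarkerTable, path: str) -> None:
    table.markers.loc[:, list(WEIGHTED_COLUMNS)].to_csv(path, index=False)


def read_weighted_markers(path: str, ecs_max: Optional[int] = None) -> WeightedMarkerTable:
    df = pd.read_csv(path)
    missing = [c for c in WEIGHTED_COLUMNS if c not in df.columns]
    if missing:
        raise MarkerTableError(f"{path}: missing column(s): {missing}")
    if ecs_max is None:
        ecs_max = int(df["ECs"].max()) if len(df) else 1
    return WeightedMarkerTable(markers=df, ecs_max=ecs_max)


def write_counts_mtx(
    data: ExpressionData, mtx_path: str, features_path: str, barcodes_path: str
) -> None:
    counts = data.counts
    if not sp.issparse(counts):
        counts = sp.coo_matrix(counts)
    scipy.io.mmwrite(mtx_path, counts, field="integer")
    pd.Series(data.gene_ids).to_csv(
        features_path, sep="\t", header=False, index=False
    )
    pd.Series(data.cell_ids).to_csv(
        barcodes_path, sep="\t", header=False, index=False
    )


def write_labels_tsv(labels: pd.Series, path: str) -> None:
    labels.to_csv(path, sep="\t", header=False)


def write_annotation_tsv(
    winners: pd.Series, scores: pd.DataFrame, path: str
) -> None:
    """Winner/runner-up table: id, winner, winner_score, runner_up, score."""
    rows = []
    for row_id in scores.index:
        row = scores.loc[row_id].dropna()
        ranked = row.sort_index().sort_values(ascending=False, kind="stable")
        winner = winners.loc[row_id]
        runner_up = ranked.index[1] if len(ranked) > 1 else ""
        rows.append(
            {
                "id": row_id,
                "winner": winner,
                "winner_score": float(ranked.iloc[0]),
                "runner_up": runner_up,
                "runner_up_score": float(ranked.iloc[1]) if len(ranked) > 1 else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(obj: dict, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def convert_marker_excel(
    xlsx_path: str,
    out_csv: str,
    sheet: object = 0,
    column_map: Optional[dict] = None,
) -> MarkerTable:
    """Ingest a marker database shipped as Excel into the standardized CSV.

    ``column_map`` renames source columns to the standardized names; columns
    already matching are taken as-is, missing optional columns default to
    empty.
    """
    df = pd.read_excel(xlsx_path, sheet_name=sheet, dtype=str)
    if column_map:
        df = df.rename(columns=column_map)
    table = MarkerTable(df)
    table.records.to_csv(out_csv, index=False)
    return table
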
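"""Count normalization and marker-gene scaling (the SE layer).

Raw counts are library-size normalized per cell,
``ln(1 + count / cell_total × scale_factor)``, then z-scored per gene across
all cells on the marker genes only, clipped to ``[−clip, +clip]``.  The
resulting scaled-expression (SE) matrix is the input of the impact-score
engine.  An optional per-cluster log2 fold-change filter removes positive
markers that are not enriched in a cluster relative to all other cells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .markerdb import POSITIVE, WeightedMarkerTable

logger = logging.getLogger(__name__)

Matrix = Union[np.ndarray, sp.spmatrix]


class ZeroTotalCellError(ValueError):
    """A cell has zero total counts; it must be prefiltered."""


class NoUsableMarkersError(ValueError):
    """None of the requested marker genes are present in the matrix."""


@dataclass
class ExpressionData:
    """Gene × cell raw counts with an optional derived SE layer.

    ``counts`` may be dense or scipy-sparse, genes as rows.  ``se`` is a
    dense DataFrame restricted to marker genes (rows) × cells (columns).
    """

    counts: Matrix
    gene_ids: pd.Index
    cell_ids: pd.Index
    cluster_labels: Optional[pd.Series] = None
    se: Optional[pd.DataFrame] = None

    def __post_init__(self):
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_ids = pd.Index(self.cell_ids)
        n_genes, n_cells = self.counts.shape
        if n_genes != len(self.gene_ids) or n_cells != len(self.cell_ids):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.cluster_labels is not None:
            self.cluster_labels = pd.Series(self.cluster_labels).reindex(
                self.cell_ids
            )
            if self.cluster_labels.isna().any():
                missing = list(
                    self.cluster_labels.index[self.cluster_labels.isna()][:5]
                )
                raise ValueError(f"cells without cluster label: {missing}")


def lognormalize(
    counts: Matrix,
    scale_factor: float = 1e4,
    cell_ids: Optional[Sequence] = None,
) -> Matrix:
    """Per-cell library-size normalization, ``ln(1 + c/total × sf)``.

    Cells with zero total counts are an error (the offending barcode is
    named when ``cell_ids`` is given); callers must prefilter them.
    """
    totals = np.asarray(counts.sum(axis=0)).ravel()
    if (totals <= 0).any():
        bad = np.flatnonzero(totals <= 0)
        names = (
            [cell_ids[i] for i in bad[:5]]
            if cell_ids is not None
            else bad[:5].tolist()
        )
        raise ZeroTotalCellError(
            f"{len(bad)} cell(s) with zero total counts, e.g. {names}"
        )
    factors = scale_factor / totals
    if sp.issparse(counts):
        normalized = counts.multiply(factors[np.newaxis, :]).tocsc()
        normalized.data = np.log1p(normalized.data)
        return normalized
    return np.log1p(np.asarray(counts, dtype=float) * factors[np.newaxis, :])


def scale_markers(
    normalized: Matrix,
    gene_ids: Sequence,
    marker_genes: Iterable,
    clip: float = 10.0,
    cell_ids: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Per-gene z-score across all cells, restricted to marker genes.

    Uses the sample standard deviation (ddof=1); zero-variance genes map to
    all-zero rows; values are clipped to ``[−clip, +clip]``.  Marker genes
    absent from the matrix are dropped with a logged warning.
    """
    gene_index = pd.Index(gene_ids)
    wanted = list(dict.fromkeys(marker_genes))
    present = [g for g in wanted if g in gene_index]
    missing = [g for g in wanted if g not in gene_index]
    if missing:
        logger.warning(
            "%d marker gene(s) absent from the matrix: %s%s",
            len(missing),
            missing[:10],
            "..." if len(missing) > 10 else "",
        )
    if not present:
        raise NoUsableMarkersError(
            "no usable markers: none of the marker genes are in the matrix"
        )
    rows = gene_index.get_indexer(present)
    sub = normalized[rows, :]
    if sp.issparse(sub):
        sub = np.asarray(sub.todense())
    else:
        sub = np.asarray(sub, dtype=float)
    mean = sub.mean(axis=1, keepdims=True)
    if sub.shape[1] > 1:
        sd = sub.std(axis=1, ddof=1, keepdims=True)
    else:
        sd = np.zeros((sub.shape[0], 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (sub - mean) / sd, 0.0)
    z = np.clip(z, -clip, clip)
    columns = pd.Index(cell_ids) if cell_ids is not None else pd.RangeIndex(
        sub.shape[1]
    )
    return pd.DataFrame(z, index=pd.Index(present), columns=columns)


def log2fc_marker_filter(
    normalized: Matrix,
    gene_ids: Sequence,
    cell_ids: Sequence,
    cluster_labels: pd.Series,
    weighted_markers: WeightedMarkerTable,
    threshold: float = 1.0,
) -> Dict[object, WeightedMarkerTable]:
    """Per-cluster enrichment filter on positive markers.

    For each cluster and positive marker, the difference of mean normalized
    expression between the cluster and all other cells is converted to a
    log2 fold change (division by ln 2); positive markers below the
    threshold are removed from that cluster's candidate set.  Negative
    markers are never removed.  ``threshold = −inf`` disables the filter;
    a single cluster skips it with a warning.
    """
    labels = pd.Series(cluster_labels).reindex(pd.Index(cell_ids))
    if labels.isna().any():
        raise ValueError("every cell needs a cluster label for the filter")
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        logger.warning(
            "log2 fold-change filter skipped: only one cluster present"
        )
        return {c: weighted_markers for c in clusters}

    gene_index = pd.Index(gene_ids)
    marker_genes = weighted_markers.markers["gene"].unique()
    present = [g for g in marker_genes if g in gene_index]
    rows = gene_index.get_indexer(present)
    sub = normalized[rows, :]
    if sp.issparse(sub):
        sub = np.asarray(sub.todense())
    else:
        sub = np.asarray(sub, dtype=float)
    expr = pd.DataFrame(sub, index=pd.Index(present), columns=labels.index)

    out: Dict[object, WeightedMarkerTable] = {}
    ln2 = math.log(2.0)
    for cluster in clusters:
        in_mask = (labels == cluster).to_numpy()
        mean_in = expr.loc[:, in_mask].mean(axis=1)
        mean_out = expr.loc[:, ~in_mask].mean(axis=1)
        l2fc = (mean_in - mean_out) / ln2
        keep_genes = set(l2fc.index[l2fc >= threshold])
        m = weighted_markers.markers
        is_pos = m["polarity"] == POSITIVE
        measurable = m["gene"].isin(present)
        drop = is_pos & measurable & ~m["gene"].isin(keep_genes)
        out[cluster] = WeightedMarkerTable(
            markers=m[~drop].reset_index(drop=True),
            ecs_max=weighted_markers.ecs_max,
            scope=weighted_markers.scope,
        )
    return out
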
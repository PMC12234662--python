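"""Impact-score engine: gene and cell-type impact scores, winners, reports.

Each marker gene contributes a **gene impact score** to every cell and
candidate cell type,

    G_IMs(G, C, CT) = SE(G, C) · ECs_reg(G, CT) · SPs_reg(G)

i.e. scaled expression weighted by regularized evidence consistency and
specificity.  Per cell type, contributions of positive and negative markers
are combined into a **cell-type impact score**

    CT_IMs(C, CT) = Σ_{G∈PG} G_IMs / √(Σ_{G∈PG} w_G)
                  − Σ_{G∈NG} G_IMs / √(Σ_{G∈NG} w_G)

with w_G = ECs_reg·SPs_reg, where PG/NG are the positive/negative marker
sets; the square-root normalization makes scores comparable across cell
types with different marker-set sizes.  Cells (or clusters, aggregated at a
configurable quantile, by default the third quartile) are assigned to the
cell type with the highest score.  The same machinery scores cell-cycle
phases and arbitrary weighted gene signatures.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd

from .markerdb import NEGATIVE, POSITIVE, WeightedMarkerTable

logger = logging.getLogger(__name__)

#: Label given to rows whose best score is non-positive under allow_unknown.
UNKNOWN = "unknown"


class NoScorableCellTypeError(ValueError):
    """No cell type has any marker gene present in the SE matrix."""


def gene_impact_scores(
    se: pd.DataFrame, weighted_markers: WeightedMarkerTable
) -> Dict[str, pd.DataFrame]:
    """Per-cell-type gene impact matrices.

    Returns ``{celltype: DataFrame(genes × cells)}`` with values
    ``SE · ECs_reg · SPs_reg``; marker genes absent from the SE matrix are
    dropped with a logged warning.
    """
    out: Dict[str, pd.DataFrame] = {}
    absent = set(weighted_markers.markers["gene"]) - set(se.index)
    if absent:
        logger.warning(
            "%d marker gene(s) not in SE matrix, dropped: %s%s",
            len(absent),
            sorted(absent)[:10],
            "..." if len(absent) > 10 else "",
        )
    for ct, grp in weighted_markers.markers.groupby("celltype_id"):
        grp = grp[grp["gene"].isin(se.index)]
        if grp.empty:
            continue
        w = grp["weight"].to_numpy()[:, np.newaxis]
        out[ct] = pd.DataFrame(
            se.loc[grp["gene"]].to_numpy() * w,
            index=grp["gene"].to_numpy(),
            columns=se.columns,
        )
    return out


def celltype_impact_scores(
    se: pd.DataFrame, weighted_markers: WeightedMarkerTable
) -> pd.DataFrame:
    """Cell × cell-type impact score matrix.

    Cell types whose positive *and* negative marker sets are entirely absent
    from the SE matrix are excluded with a warning; if nothing remains a
    :class:`NoScorableCellTypeError` is raised.
    """
    values = se.to_numpy()
    gene_index = se.index
    scores: Dict[str, np.ndarray] = {}
    excluded = []
    for ct in weighted_markers.celltypes:
        total = np.zeros(values.shape[1])
        any_genes = False
        for polarity, sign in ((POSITIVE, 1.0), (NEGATIVE, -1.0)):
            m = weighted_markers.markers_for(ct, polarity)
            m = m[m["gene"].isin(gene_index)]
            if m.empty:
                continue
            any_genes = True
            w = m["weight"].to_numpy()
            rows = gene_index.get_indexer(m["gene"])
            total += sign * (w @ values[rows, :]) / math.sqrt(w.sum())
        if not any_genes:
            excluded.append(ct)
            continue
        scores[ct] = total
    if excluded:
        logger.warning(
            "cell type(s) with no marker present in the matrix, excluded "
            "from scoring: %s",
            excluded,
        )
    if not scores:
        raise NoScorableCellTypeError(
            "no scorable cell type: all marker genes absent from the matrix"
        )
    return pd.DataFrame(scores, index=se.columns).sort_index(axis=1)


def aggregate_scores_by_cluster(
    scores: pd.DataFrame, cluster_labels: pd.Series, q: float = 0.75
) -> pd.DataFrame:
    """Cluster × cell-type quantile aggregation (default: third quartile).

    Uses the linear-interpolation quantile definition.
    """
    labels = pd.Series(cluster_labels).reindex(scores.index)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()][:5])
        raise ValueError(f"cells without cluster label: {missing}")
    agg = scores.groupby(labels).quantile(q, interpolation="linear")
    return agg.sort_index()


def assign_labels(
    scores: pd.DataFrame, allow_unknown: bool = False
) -> pd.Series:
    """Per-row argmax winner; ties broken by lexicographic cell-type id.

    With ``allow_unknown``, rows whose maximum score is ≤ 0 are labelled
    :data:`UNKNOWN` — a non-positive impact score means no net positive
    marker evidence.
    """
    if scores.empty:
        raise ValueError("empty score matrix")
    ordered = scores[sorted(scores.columns)]
    winners = ordered.idxmax(axis=1)
    if allow_unknown:
        winners = winners.mask(ordered.max(axis=1) <= 0, UNKNOWN)
    winners.name = "winner"
    return winners


@dataclass
class AnnotationResult:
    """Everything the engine produces for one dataset.

    ``support`` maps each cluster to the fraction of member cells whose
    per-cell winner is each label (fractions sum to 1 per cluster).
    """

    cell_scores: pd.DataFrame
    cell_winners: pd.Series
    cluster_scores: Optional[pd.DataFrame] = None
    cluster_winners: Optional[pd.Series] = None
    support: Optional[pd.DataFrame] = None
    report: Optional[dict] = None
    quantile_used: float = 0.75


def support_fractions(
    cell_winners: pd.Series, cluster_labels: pd.Series
) -> pd.DataFrame:
    """Cluster × label matrix of per-cell winner fractions (rows sum to 1)."""
    labels = pd.Series(cluster_labels).reindex(cell_winners.index)
    frac = (
        pd.crosstab(labels, cell_winners, normalize="index")
        .sort_index()
        .sort_index(axis=1)
    )
    return frac


def impact_report(
    cluster_scores: pd.DataFrame,
    cell_winners: pd.Series,
    gene_impacts: Dict[str, pd.DataFrame],
    cluster_labels: pd.Series,
    k: int = 3,
    q: float = 0.75,
) -> dict:
    """Interpretability report at cluster resolution.

    Per cluster: the top-k cell types by cluster impact score, the winner,
    the per-cell winner support fractions, and the winner's marker genes
    ranked by the q-quantile of their gene impact scores across the
    cluster's cells.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    labels = pd.Series(cluster_labels).reindex(cell_winners.index)
    report: dict = {"quantile": q, "k": k, "clusters": {}}
    for cluster in cluster_scores.index:
        row = cluster_scores.loc[cluster].dropna()
        # stable sort on a lexicographically pre-sorted index breaks ties
        # by cell-type id
        ranked = row.sort_index().sort_values(ascending=False, kind="stable")
        top = ranked.head(k)
        winner = ranked.index[0]
        members = labels.index[labels == cluster]
        support = (
            cell_winners.loc[members].value_counts(normalize=True).to_dict()
        )
        top_genes: list = []
        if winner in gene_impacts:
            gim = gene_impacts[winner].loc[:, members]
            gq = gim.quantile(q, axis=1, interpolation="linear")
            gq = gq.sort_index().sort_values(ascending=False, kind="stable")
            top_genes = [
                {"gene": g, "impact": float(v)}
                for g, v in gq.head(k).items()
            ]
        report["clusters"][str(cluster)] = {
            "winner": winner,
            "top_celltypes": [
                {"celltype": ct, "score": float(v)} for ct, v in top.items()
            ],
            "support": {str(lab): float(f) for lab, f in sorted(support.items())},
            "top_genes": top_genes,
        }
    return report


def annotate_cell_cycle(
    se: pd.DataFrame,
    phase_markers: WeightedMarkerTable,
    allow_unknown: bool = False,
) -> tuple[pd.Series, pd.DataFrame]:
    """Assign each cell a cell-cycle phase from phase-specific marker sets.

    ``phase_markers`` is an ordinary weighted marker table whose "cell
    types" are phases (e.g. G0/G1/S/G2M); G0 markers make quiescence a
    first-class label.  Returns (per-cell phase labels, phase score matrix).
    """
    scores = celltype_impact_scores(se, phase_markers)
    return assign_labels(scores, allow_unknown=allow_unknown), scores


def score_signature(
    se: pd.DataFrame, signature: WeightedMarkerTable
) -> pd.Series:
    """Per-cell activation score of a weighted gene signature.

    The signature is scored as a single pseudo-cell-type with the standard
    impact-score normalization; build one with
    :meth:`WeightedMarkerTable.from_signature` (weight 1 per gene when
    unweighted).
    """
    celltypes = signature.celltypes
    if len(celltypes) != 1:
        raise ValueError(
            f"a signature must contain exactly one pseudo-cell-type, "
            f"got {celltypes}"
        )
    scores = celltype_impact_scores(se, signature)
    out = scores[celltypes[0]]
    out.name = celltypes[0]
    return out


def annotate(
    se: pd.DataFrame,
    weighted_markers: WeightedMarkerTable,
    cluster_labels: Optional[pd.Series] = None,
    q: float = 0.75,
    allow_unknown: bool = False,
    k: int = 3,
    per_cluster_markers: Optional[Dict[object, WeightedMarkerTable]] = None,
) -> AnnotationResult:
    """Run the full engine: scores, winners, and the cluster-level report.

    When ``per_cluster_markers`` is given (e.g. from the log2 fold-change
    filter), each cluster's aggregated scores are computed from its own
    filtered marker set; per-cell scores always use the global table.
    """
    cell_scores = celltype_impact_scores(se, weighted_markers)
    cell_winners = assign_labels(cell_scores, allow_unknown=allow_unknown)
    result = AnnotationResult(
        cell_scores=cell_scores,
        cell_winners=cell_winners,
        quantile_used=q,
    )
    if cluster_labels is None:
        return result
    labels = pd.Series(cluster_labels).reindex(se.columns)
    if per_cluster_markers is None:
        cluster_scores = aggregate_scores_by_cluster(cell_scores, labels, q=q)
    else:
        rows = {}
        for cluster in sorted(labels.unique()):
            members = labels.index[labels == cluster]
            table = per_cluster_markers.get(cluster, weighted_markers)
            sc = celltype_impact_scores(se.loc[:, members], table)
            rows[cluster] = sc.quantile(q, interpolation="linear")
        cluster_scores = pd.DataFrame(rows).T.sort_index().sort_index(axis=1)
    result.cluster_scores = cluster_scores
    result.cluster_winners = assign_labels(
        cluster_scores, allow_unknown=allow_unknown
    )
    result.support = support_fractions(cell_winners, labels)
    gims = gene_impact_scores(se, weighted_markers)
    result.report = impact_report(
        cluster_scores, cell_winners, gims, labels, k=k, q=q
    )
    return result
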
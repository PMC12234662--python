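"""Benchmark metrics: cluster truth mapping, ontology similarity, F1, tests.

Cluster-level evaluation mirrors the standard marker-annotation benchmark:
each cluster is mapped to the ground-truth label held by the largest
fraction of its cells, the predicted term is compared to that truth term by
ontology percentage similarity (0 worst … 100 perfect match), and the mean
over clusters summarizes performance.  Binary detection metrics
(precision/recall/F1 on an aberrant-cell flag) and the one-tailed Wilcoxon
rank-sum test for score-distribution shifts complete the toolbox.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import precision_recall_fscore_support

from .ontology import OntologyGraph

logger = logging.getLogger(__name__)


@dataclass
class BenchmarkReport:
    """Per-cluster similarities plus optional detection metrics and tests."""

    per_cluster: pd.DataFrame  # columns: cluster, predicted, truth, similarity
    mean_similarity: float
    detection: Optional[tuple] = None  # (precision, recall, F1)
    tests: Optional[list] = None

    def to_dict(self) -> dict:
        out = {
            "mean_similarity": self.mean_similarity,
            "per_cluster": self.per_cluster.to_dict(orient="records"),
        }
        if self.detection is not None:
            p, r, f1 = self.detection
            out["detection"] = {"precision": p, "recall": r, "f1": f1}
        if self.tests is not None:
            out["tests"] = self.tests
        return out


def majority_truth_label(
    cluster_labels: pd.Series, truth_labels: pd.Series
) -> pd.Series:
    """Map each cluster to the ground-truth label of most of its cells.

    Ties go to the lexicographically smallest label (logged).
    """
    clusters = pd.Series(cluster_labels)
    truth = pd.Series(truth_labels).reindex(clusters.index)
    if truth.isna().any():
        missing = list(truth.index[truth.isna()][:5])
        raise ValueError(f"cells without truth label: {missing}")
    out = {}
    for cluster, grp in truth.groupby(clusters):
        counts = grp.value_counts()
        top = counts.max()
        winners = sorted(counts.index[counts == top])
        if len(winners) > 1:
            logger.info(
                "cluster %r: majority tie between %s, choosing %r",
                cluster,
                winners,
                winners[0],
            )
        out[cluster] = winners[0]
    result = pd.Series(out).sort_index()
    result.name = "truth"
    return result


def ontology_performance(
    predictions: Mapping,
    truths: Mapping,
    graph: OntologyGraph,
) -> BenchmarkReport:
    """Ontology percentage similarity between predictions and truths.

    Both arguments map cluster id → term id; every term must be in the
    graph.  The report's summary is the arithmetic mean of per-cluster
    similarities.
    """
    predictions = dict(predictions)
    truths = dict(truths)
    rows = []
    for cluster in sorted(predictions):
        if cluster not in truths:
            raise ValueError(f"cluster {cluster!r} missing from truth map")
        pred, truth = predictions[cluster], truths[cluster]
        rows.append(
            {
                "cluster": cluster,
                "predicted": pred,
                "truth": truth,
                "similarity": graph.term_similarity(pred, truth),
            }
        )
    per_cluster = pd.DataFrame(rows)
    mean_sim = float(per_cluster["similarity"].mean())
    return BenchmarkReport(per_cluster=per_cluster, mean_similarity=mean_sim)


def binary_detection_metrics(
    predicted_flags: Sequence, truth_flags: Sequence
) -> tuple[float, float, float]:
    """Precision, recall and F1 on the positive (aberrant) class.

    Zero denominators yield 0 by convention (logged by sklearn as a
    zero-division warning suppressed via ``zero_division=0``).
    """
    pred = np.asarray(predicted_flags, dtype=bool)
    truth = np.asarray(truth_flags, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(
            f"length mismatch: {pred.shape} predictions vs "
            f"{truth.shape} truths"
        )
    p, r, f1, _ = precision_recall_fscore_support(
        truth, pred, average="binary", zero_division=0
    )
    return float(p), float(r), float(f1)


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], alternative: str = "greater"
) -> tuple[float, float]:
    """One-tailed Wilcoxon rank-sum (Mann-Whitney) test.

    ``alternative`` states where the *second* sample ``y`` lies relative to
    ``x``: ``"greater"`` tests H1: y tends to exceed x, ``"less"`` the
    opposite.  When both samples have ≤ 10 observations the exact null
    distribution is used (closed form without ties, exhaustive permutation
    enumeration with ties); larger samples use the normal approximation
    with tie and continuity corrections.  Returns the rank-sum statistic of
    ``y`` and the one-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if alternative not in ("greater", "less"):
        raise ValueError(f"alternative must be greater/less, got {alternative!r}")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size <= 10 and y.size <= 10:
        # C(20, 10) = 184756, so 2e5 resamples guarantee exhaustive
        # enumeration of every rank split
        method = (
            stats.PermutationMethod(n_resamples=200000)
            if has_ties
            else "exact"
        )
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        y,
        x,
        alternative=alternative,
        method=method,
        use_continuity=True,
    )
    n_y = y.size
    w = float(res.statistic) + n_y * (n_y + 1) / 2.0  # U -> rank sum of y
    return w, float(res.pvalue)
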
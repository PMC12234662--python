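"""Synthetic counts, marker sources and toy ontologies with known truth.

The count simulator plants cell types into a negative-binomial gene × cell
matrix: every gene has baseline mean ``nb_mean``, and the marker genes of a
cell's planted type are elevated by ``fold``.  Per-cell library-size
heterogeneity is a multiplicative uniform factor.  The variance follows the
(mean, dispersion) parameterization ``var = μ + μ²/dispersion``.

The marker-source simulator emits each true marker from each of
``n_sources`` independent sources with probability ``agreement``; an
emitting source flips polarity with probability ``conflict_rate``, which
exercises the subtraction-based conflict resolution downstream.

All randomness flows from one integer seed: identical (params, seed) give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .markerdb import MARKER_COLUMNS, POSITIVE, NEGATIVE, MarkerTable
from .ontology import OntologyGraph
from .preprocess import ExpressionData

#: Scope constants used by every synthetic marker table.
SYN_SPECIES = "human"
SYN_TISSUE = "synthetic tissue"
SYN_CATEGORY = "physiological"


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults are the package's study conditions."""

    n_types: int = 4
    cells_per_type: int = 200
    n_marker_genes: int = 5  # planted positive markers per cell type
    n_background_genes: int = 100
    fold: float = 8.0
    nb_mean: float = 2.0
    nb_dispersion: float = 2.0
    library_size_range: Tuple[float, float] = (0.75, 1.25)
    n_sources: int = 5
    agreement: float = 1.0
    conflict_rate: float = 0.0

    def validate(self) -> None:
        if min(self.n_types, self.cells_per_type, self.n_marker_genes) < 1:
            raise ValueError("n_types, cells_per_type, n_marker_genes must be >= 1")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")
        if self.fold < 1:
            raise ValueError(f"fold must be >= 1, got {self.fold}")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("nb_mean and nb_dispersion must be positive")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must satisfy 0 < lo <= hi")
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")
        for name in ("agreement", "conflict_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a simulated dataset."""

    cell_truth: pd.Series  # cell id -> planted cell-type id
    marker_truth: pd.DataFrame  # gene, celltype_id, polarity
    params: SimParams
    seed: int


def _celltype_id(t: int) -> str:
    return f"CT{t}"


def simulate_expression(
    params: SimParams, seed: int
) -> tuple[ExpressionData, SyntheticTruth]:
    """Negative-binomial counts with planted marker elevation.

    Returns an :class:`ExpressionData` (cluster labels set to the planted
    types, emulating a perfect clustering) and the ground truth.
    """
    params.validate()
    rng = np.random.default_rng(seed)

    n_cells = params.n_types * params.cells_per_type
    marker_genes = [
        f"MK{t}G{j}"
        for t in range(params.n_types)
        for j in range(params.n_marker_genes)
    ]
    background_genes = [f"BG{i:04d}" for i in range(params.n_background_genes)]
    genes = marker_genes + background_genes
    cells = [f"cell{c:05d}" for c in range(n_cells)]
    cell_types = np.repeat(np.arange(params.n_types), params.cells_per_type)

    mu = np.full((len(genes), n_cells), params.nb_mean)
    for t in range(params.n_types):
        g0 = t * params.n_marker_genes
        rows = slice(g0, g0 + params.n_marker_genes)
        mu[rows, cell_types == t] *= params.fold

    lo, hi = params.library_size_range
    lib = rng.uniform(lo, hi, size=n_cells)
    mu = mu * lib[np.newaxis, :]

    r = params.nb_dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)

    truth_labels = pd.Series(
        [_celltype_id(t) for t in cell_types], index=pd.Index(cells), name="truth"
    )
    marker_truth = pd.DataFrame(
        {
            "gene": marker_genes,
            "celltype_id": [
                _celltype_id(t)
                for t in range(params.n_types)
                for _ in range(params.n_marker_genes)
            ],
            "polarity": POSITIVE,
        }
    )
    data = ExpressionData(
        counts=counts,
        gene_ids=pd.Index(genes),
        cell_ids=pd.Index(cells),
        cluster_labels=truth_labels.rename("cluster"),
    )
    truth = SyntheticTruth(
        cell_truth=truth_labels,
        marker_truth=marker_truth,
        params=params,
        seed=seed,
    )
    return data, truth


def simulate_marker_sources(
    params: SimParams,
    seed: int,
    marker_truth: Optional[pd.DataFrame] = None,
) -> MarkerTable:
    """Multi-source marker table with configurable agreement and conflicts.

    Each true marker is emitted by each source independently with
    probability ``agreement``; an emitting source flips the marker's
    polarity with probability ``conflict_rate``.  With agreement 1 and no
    conflicts, every marker's recovered evidence consistency equals
    ``n_sources`` exactly.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    if marker_truth is None:
        marker_truth = pd.DataFrame(
            {
                "gene": [
                    f"MK{t}G{j}"
                    for t in range(params.n_types)
                    for j in range(params.n_marker_genes)
                ],
                "celltype_id": [
                    _celltype_id(t)
                    for t in range(params.n_types)
                    for _ in range(params.n_marker_genes)
                ],
                "polarity": POSITIVE,
            }
        )
    rows = []
    flip = {POSITIVE: NEGATIVE, NEGATIVE: POSITIVE}
    for _, marker in marker_truth.iterrows():
        for s in range(params.n_sources):
            if rng.random() >= params.agreement:
                continue
            polarity = marker["polarity"]
            if rng.random() < params.conflict_rate:
                polarity = flip[polarity]
            rows.append(
                {
                    "species": SYN_SPECIES,
                    "tissue": SYN_TISSUE,
                    "celltype_id": marker["celltype_id"],
                    "celltype_label": marker["celltype_id"],
                    "gene": marker["gene"],
                    "polarity": polarity,
                    "source_id": f"source{s}",
                    "category": SYN_CATEGORY,
                    "disease": "",
                }
            )
    if not rows:
        return MarkerTable.empty()
    return MarkerTable(pd.DataFrame(rows, columns=list(MARKER_COLUMNS)))


def simulate_toy_ontology(depth: int, branching: int) -> OntologyGraph:
    """Complete ``branching``-ary is_a tree of the given depth.

    Term ids are path-like (root ``T``, children ``T.0``, ``T.0.1``, ...);
    a depth of 0 yields a single root term.
    """
    if depth < 0:
        raise ValueError(f"depth must be >= 0, got {depth}")
    if branching < 1:
        raise ValueError(f"branching must be >= 1, got {branching}")
    import networkx as nx

    g = nx.DiGraph()
    root = "T"
    g.add_node(root, label=root)
    frontier = [root]
    for _ in range(depth):
        nxt = []
        for parent in frontier:
            for b in range(branching):
                child = f"{parent}.{b}"
                g.add_node(child, label=child)
                g.add_edge(child, parent)
                nxt.append(child)
        frontier = nxt
    return OntologyGraph(g)
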
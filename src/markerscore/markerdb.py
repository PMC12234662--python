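"""Integration of multi-source marker-gene tables into weighted marker sets.

A marker record states that a gene is a positive or negative marker of a cell
type, according to one annotation source, within a (species, tissue, category)
scope.  Integration proceeds in three steps:

1. **Evidence consistency (ECs)** — for each (gene, cell type), count the
   distinct sources listing the gene with each polarity.  Conflicts are
   resolved by subtraction: the signed difference ``d = n_pos − n_neg``
   determines the final polarity (positive if d > 0, negative if d < 0,
   discarded if d = 0) and ECs = |d|.

2. **Specificity (SPs)** — per gene and polarity, the reciprocal of the
   number of cell types the gene marks with that polarity.  A gene exclusive
   to one cell type has SPs = 1.

3. **Regularization** — ECs is compressed with an affine log transform,
   ``ECs_reg = 1 + log10(ECs)``.  The cell-type count ``N = 1/SPs`` is
   reverse-scaled (``r = N_max + N_min − N``), mapped linearly onto
   ``[1, ECs_max]`` so that the two scores carry the same overall weight, and
   transformed the same way: ``SPs_reg = 1 + log10(m(r))``.  The final weight
   is ``ECs_reg × SPs_reg`` and spans ``[1, (1 + log10 ECs_max)²]``.

The module also provides Jaccard concordance between marker databases and
whole-database summary counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
POLARITIES = (POSITIVE, NEGATIVE)

#: Columns of the standardized marker CSV (header required).
MARKER_COLUMNS = (
    "species",
    "tissue",
    "celltype_id",
    "celltype_label",
    "gene",
    "polarity",
    "source_id",
    "category",
    "disease",
)

#: Record identity: duplicates of this tuple collapse before any counting.
IDENTITY_COLUMNS = [
    "species",
    "tissue",
    "celltype_id",
    "gene",
    "polarity",
    "source_id",
]

WEIGHTED_COLUMNS = (
    "gene",
    "celltype_id",
    "polarity",
    "ECs",
    "SPs",
    "ECs_reg",
    "SPs_reg",
    "weight",
)


class MarkerTableError(ValueError):
    """Invalid marker table content (schema or row-level violations)."""


class ScopeError(ValueError):
    """A (species, tissue, category) scope selected no records."""


class NoCommonCellTypesError(ValueError):
    """Two databases share no cell-type identifiers."""


@dataclass(frozen=True)
class Scope:
    """Query scope applied to a marker table before any scoring.

    ``tissue`` or ``category`` set to None act as wildcards.
    """

    species: str
    tissue: Optional[str] = None
    category: Optional[str] = None

    def __str__(self) -> str:  # used in error messages
        return (
            f"species={self.species!r}, tissue={self.tissue!r}, "
            f"category={self.category!r}"
        )


class MarkerTable:
    """Deduplicated collection of multi-source marker records.

    Parameters
    ----------
    records
        DataFrame with at least the required columns of
        :data:`MARKER_COLUMNS` (``celltype_label`` and ``disease`` may be
        absent and default to empty).  Duplicate identity tuples are
        collapsed to one record.
    case_insensitive
        Uppercase gene symbols before matching (off by default; symbols are
        otherwise matched case-sensitively after whitespace trimming).
    """

    def __init__(self, records: pd.DataFrame, case_insensitive: bool = False):
        records = records.copy()
        for col in MARKER_COLUMNS:
            if col not in records.columns:
                if col in ("celltype_label", "disease"):
                    records[col] = ""
                else:
                    raise MarkerTableError(f"missing required column: {col!r}")
        records = records.loc[:, list(MARKER_COLUMNS)]
        for col in MARKER_COLUMNS:
            records[col] = records[col].fillna("").astype(str).str.strip()
        if case_insensitive:
            records["gene"] = records["gene"].str.upper()

        problems = []
        for idx, row in records.iterrows():
            if not row["gene"]:
                problems.append(f"row {idx}: empty gene symbol")
            if not row["source_id"]:
                problems.append(f"row {idx}: empty source_id")
            if row["polarity"] not in POLARITIES:
                problems.append(
                    f"row {idx}: invalid polarity {row['polarity']!r}"
                )
        if problems:
            raise MarkerTableError("; ".join(problems))

        n_before = len(records)
        records = records.drop_duplicates(subset=IDENTITY_COLUMNS)
        n_dropped = n_before - len(records)
        if n_dropped:
            logger.info("collapsed %d duplicate marker record(s)", n_dropped)
        self.records = records.reset_index(drop=True)

    @classmethod
    def empty(cls) -> "MarkerTable":
        return cls(pd.DataFrame(columns=list(MARKER_COLUMNS)))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sources(self) -> set:
        return set(self.records["source_id"])

    @property
    def celltypes(self) -> set:
        return set(self.records["celltype_id"])

    def scoped(self, scope: Scope) -> pd.DataFrame:
        """Records matching the scope; raises :class:`ScopeError` if empty."""
        mask = self.records["species"] == scope.species
        if scope.tissue is not None:
            mask &= self.records["tissue"] == scope.tissue
        if scope.category is not None:
            mask &= self.records["category"] == scope.category
        sub = self.records[mask]
        if sub.empty:
            raise ScopeError(f"no marker records in scope ({scope})")
        return sub


def compute_evidence_consistency(
    table: MarkerTable, scope: Scope
) -> pd.DataFrame:
    """Resolve polarity conflicts and count supporting sources per marker.

    Returns a DataFrame with columns ``gene, celltype_id, polarity, ECs``:
    one row per retained (gene, cell type) pair.  Pairs whose positive and
    negative source counts cancel exactly are dropped.
    """
    sub = table.scoped(scope)
    counts = (
        sub.groupby(["gene", "celltype_id", "polarity"])["source_id"]
        .nunique()
        .unstack("polarity")
        .reindex(columns=list(POLARITIES))
        .fillna(0)
        .astype(int)
    )
    d = counts[POSITIVE] - counts[NEGATIVE]
    d = d[d != 0]
    resolved = d.reset_index(name="signed")
    resolved["polarity"] = np.where(resolved["signed"] > 0, POSITIVE, NEGATIVE)
    resolved["ECs"] = resolved["signed"].abs()
    return resolved[["gene", "celltype_id", "polarity", "ECs"]].sort_values(
        ["celltype_id", "polarity", "gene"], ignore_index=True
    )


def compute_specificity(resolved: pd.DataFrame) -> pd.DataFrame:
    """Specificity per (gene, polarity) after conflict resolution.

    ``SPs = 1 / N`` where N is the number of distinct cell types the gene
    marks with that polarity inside the scope.  Genes never carrying a
    polarity simply have no row for it.
    """
    spec = (
        resolved.groupby(["gene", "polarity"])["celltype_id"]
        .nunique()
        .reset_index(name="n_celltypes")
    )
    spec["SPs"] = 1.0 / spec["n_celltypes"]
    return spec


def regularize_scores(
    resolved: pd.DataFrame, specificity: pd.DataFrame, ecs_max: int
) -> pd.DataFrame:
    """Attach ECs_reg, SPs_reg and the final weight to each marker.

    ``ECs_reg = 1 + log10(ECs)``.  Per polarity, the cell-type count
    ``N = 1/SPs`` is reverse-scaled over the genes of that polarity
    (``r = N_max + N_min − N``), mapped linearly from ``[N_min, N_max]`` onto
    ``[1, ecs_max]`` and log-transformed the same way.  When every gene of a
    polarity is equally specific (N_max = N_min) the map is the constant
    ``ecs_max`` — uniform specificity must not penalize.
    """
    if ecs_max < 1:
        raise ValueError(f"ECs_max must be >= 1, got {ecs_max}")
    if (resolved["ECs"] < 1).any():
        raise ValueError("every retained marker must have ECs >= 1")

    df = resolved.merge(specificity, on=["gene", "polarity"], how="left")
    df["ECs_reg"] = 1.0 + np.log10(df["ECs"].astype(float))

    sps_reg = np.empty(len(df))
    for pol, grp in df.groupby("polarity"):
        n = grp["n_celltypes"].astype(float)
        n_min, n_max = float(n.min()), float(n.max())
        if n_max == n_min:
            m = np.full(len(grp), float(ecs_max))
        else:
            r = n_max + n_min - n
            m = 1.0 + (r - n_min) * (ecs_max - 1.0) / (n_max - n_min)
        sps_reg[grp.index] = 1.0 + np.log10(m)
    df["SPs_reg"] = sps_reg
    df["weight"] = df["ECs_reg"] * df["SPs_reg"]
    return df[list(WEIGHTED_COLUMNS)]


@dataclass
class WeightedMarkerTable:
    """Resolved, weighted marker sets for a scope.

    ``markers`` holds one row per (gene, cell type) with the columns of
    :data:`WEIGHTED_COLUMNS`; ``ecs_max`` is the maximum evidence-consistency
    score observed in the scoped table (the upper end of the specificity
    rescaling range).
    """

    markers: pd.DataFrame
    ecs_max: int
    scope: Optional[Scope] = None

    def __post_init__(self):
        dup = self.markers.duplicated(subset=["gene", "celltype_id"])
        if dup.any():
            raise MarkerTableError(
                "duplicate (gene, celltype_id) pairs after conflict resolution"
            )

    @property
    def celltypes(self) -> list:
        return sorted(self.markers["celltype_id"].unique())

    def markers_for(self, celltype: str, polarity: str) -> pd.DataFrame:
        m = self.markers
        return m[(m["celltype_id"] == celltype) & (m["polarity"] == polarity)]

    @property
    def max_weight_bound(self) -> float:
        return (1.0 + np.log10(self.ecs_max)) ** 2

    @classmethod
    def from_signature(
        cls,
        genes: Sequence[str],
        weights: Optional[Sequence[float]] = None,
        polarities: Optional[Sequence[str]] = None,
        name: str = "signature",
    ) -> "WeightedMarkerTable":
        """Wrap a custom gene signature as a single pseudo-cell-type.

        Unweighted signatures get weight 1 per gene (stored as ECs_reg = w,
        SPs_reg = 1 so that downstream products reproduce the weight).
        """
        genes = list(genes)
        if not genes:
            raise MarkerTableError("empty signature")
        w = [1.0] * len(genes) if weights is None else [float(x) for x in weights]
        pol = [POSITIVE] * len(genes) if polarities is None else list(polarities)
        if len(w) != len(genes) or len(pol) != len(genes):
            raise MarkerTableError("signature fields must have equal length")
        bad = sorted(set(pol) - set(POLARITIES))
        if bad:
            raise MarkerTableError(f"invalid signature polarity: {bad}")
        df = pd.DataFrame(
            {
                "gene": genes,
                "celltype_id": name,
                "polarity": pol,
                "ECs": 1,
                "SPs": 1.0,
                "ECs_reg": w,
                "SPs_reg": 1.0,
                "weight": w,
            }
        )
        return cls(markers=df, ecs_max=1, scope=None)


def build_weighted_markers(
    table: MarkerTable,
    scope: Scope,
    max_n_marker: Optional[int] = None,
) -> WeightedMarkerTable:
    """Full integration: conflict resolution, specificity, regularization.

    If ``max_n_marker`` is given, each cell type independently retains its
    top-N positive and top-N negative markers ranked by descending weight,
    ties broken alphabetically by gene symbol.
    """
    if max_n_marker is not None and max_n_marker < 1:
        raise ValueError(f"max_n_marker must be >= 1, got {max_n_marker}")
    resolved = compute_evidence_consistency(table, scope)
    if resolved.empty:
        raise ScopeError(
            f"all markers cancelled by polarity conflicts in scope ({scope})"
        )
    ecs_max = int(resolved["ECs"].max())
    spec = compute_specificity(resolved)
    weighted = regularize_scores(resolved, spec, ecs_max)
    weighted = weighted.sort_values(
        ["celltype_id", "polarity", "weight", "gene"],
        ascending=[True, True, False, True],
        ignore_index=True,
    )
    if max_n_marker is not None:
        weighted = (
            weighted.groupby(["celltype_id", "polarity"], group_keys=False)
            .head(max_n_marker)
            .reset_index(drop=True)
        )
    return WeightedMarkerTable(markers=weighted, ecs_max=ecs_max, scope=scope)


def jaccard_index(set_a: Iterable, set_b: Iterable) -> float:
    """|A ∩ B| / |A ∪ B|; both sets empty gives 0 by convention."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def database_concordance(
    db_a: MarkerTable, db_b: MarkerTable
) -> tuple[pd.DataFrame, float]:
    """Cross-database marker overlap.

    Returns the full cell-type pair Jaccard matrix (rows: A-side cell types,
    columns: B-side) and the scalar concordance: the mean Jaccard over cell
    types present in both databases (the matrix diagonal restricted to the
    shared vocabulary).
    """
    sets_a = {
        ct: set(g) for ct, g in db_a.records.groupby("celltype_id")["gene"]
    }
    sets_b = {
        ct: set(g) for ct, g in db_b.records.groupby("celltype_id")["gene"]
    }
    common = sorted(set(sets_a) & set(sets_b))
    if not common:
        raise NoCommonCellTypesError(
            "no common cell types between the two databases"
        )
    rows = sorted(sets_a)
    cols = sorted(sets_b)
    matrix = pd.DataFrame(
        [[jaccard_index(sets_a[r], sets_b[c]) for c in cols] for r in rows],
        index=rows,
        columns=cols,
    )
    average = float(np.mean([matrix.loc[ct, ct] for ct in common]))
    return matrix, average


def summarize_database(table: MarkerTable) -> pd.DataFrame:
    """Unique-entity counts per (species, category).

    Reports both unique gene symbols (``n_marker_genes``) and unique
    gene–celltype associations (``n_associations``), plus unique cell types,
    tissues and non-empty diseases.
    """
    rec = table.records

    def _one(grp: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "n_marker_genes": grp["gene"].nunique(),
                "n_associations": grp[["gene", "celltype_id"]]
                .drop_duplicates()
                .shape[0],
                "n_celltypes": grp["celltype_id"].nunique(),
                "n_tissues": grp["tissue"].nunique(),
                "n_diseases": grp.loc[grp["disease"] != "", "disease"].nunique(),
            }
        )

    if rec.empty:
        return pd.DataFrame(
            columns=[
                "n_marker_genes",
                "n_associations",
                "n_celltypes",
                "n_tissues",
                "n_diseases",
            ]
        )
    out = (
        rec.groupby(["species", "category"])
        .apply(_one, include_groups=False)
        .astype(int)
    )
    return out
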
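import numpy as np
import pandas as pd
import pytest

from markerscore import MarkerTable, OntologyGraph, Scope


def marker_record(
    gene,
    celltype,
    polarity="positive",
    source="s1",
    species="human",
    tissue="blood",
    category="physiological",
    disease="",
):
    return {
        "species": species,
        "tissue": tissue,
        "celltype_id": celltype,
        "celltype_label": celltype,
        "gene": gene,
        "polarity": polarity,
        "source_id": source,
        "category": category,
        "disease": disease,
    }


@pytest.fixture
def blood_scope():
    return Scope(species="human", tissue="blood", category="physiological")


@pytest.fixture
def conflict_table():
    """Markers exercising all three conflict-resolution outcomes.

    CD19/B-cell: 3 positive sources, never negative  -> (positive, 3)
    CD3E/B-cell: 3 positive, 1 negative              -> (positive, 2)
    NKG7/B-cell: 2 positive, 2 negative              -> removed
    CD19/plasma: 1 negative                          -> (negative, 1)
    """
    rows = []
    for s in ("s1", "s2", "s3"):
        rows.append(marker_record("CD19", "B cell", "positive", s))
        rows.append(marker_record("CD3E", "B cell", "positive", s))
    rows.append(marker_record("CD3E", "B cell", "negative", "s4"))
    for s in ("s1", "s2"):
        rows.append(marker_record("NKG7", "B cell", "positive", s))
    for s in ("s3", "s4"):
        rows.append(marker_record("NKG7", "B cell", "negative", s))
    rows.append(marker_record("CD19", "plasma cell", "negative", "s1"))
    return MarkerTable(pd.DataFrame(rows))


@pytest.fixture
def toy_ontology():
    """5-term graph: root R with children A, B; A with children A1, A2."""
    return OntologyGraph.from_edges(
        [("A", "R"), ("B", "R"), ("A1", "A"), ("A2", "A")]
    )


def random_marker_frame(rng, n_records=40, n_genes=8, n_celltypes=4, n_sources=5):
    """Random marker records (possibly duplicated/conflicting) for oracles."""
    rows = []
    for _ in range(n_records):
        rows.append(
            marker_record(
                gene=f"G{rng.integers(n_genes)}",
                celltype=f"CT{rng.integers(n_celltypes)}",
                polarity=["positive", "negative"][rng.integers(2)],
                source=f"s{rng.integers(n_sources)}",
            )
        )
    return pd.DataFrame(rows)
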
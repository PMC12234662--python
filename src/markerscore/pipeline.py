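"""End-to-end annotation pipeline: read → weight → scale → score → write.

Stages run in a fixed order; any failure raises :class:`PipelineError`
naming the stage, and partially written outputs are removed so a run
directory is either complete or absent of this run's artifacts.
"""

from __future__ import annotations

import logging
import os
from typing import Optional

import pandas as pd

from . import __version__
from .annotate import annotate
from .config import RunConfig
from .evaluate import majority_truth_label, ontology_performance
from .io import (
    read_counts,
    read_labels_tsv,
    read_marker_table,
    write_annotation_tsv,
    write_json,
    write_weighted_markers,
)
from .markerdb import Scope, build_weighted_markers
from .ontology import load_ontology
from .preprocess import lognormalize, log2fc_marker_filter, scale_markers

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


class _RunWarnings(logging.Handler):
    """Collect package warnings emitted during the run for the report."""

    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.messages: list = []

    def emit(self, record):
        self.messages.append(record.getMessage())


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a summary of written artifacts."""
    os.makedirs(config.outdir, exist_ok=True)
    written: list = []
    collector = _RunWarnings()
    logging.getLogger("markerscore").addHandler(collector)

    def _out(name: str) -> str:
        path = os.path.join(config.outdir, name)
        written.append(path)
        return path

    stage = "configure"
    try:
        stage = "read_counts"
        if config.counts is None:
            raise ValueError("no counts file configured")
        data = read_counts(config.counts, config.features, config.barcodes)

        stage = "read_clusters"
        cluster_labels: Optional[pd.Series] = None
        if config.clusters is not None:
            cluster_labels = read_labels_tsv(config.clusters).reindex(
                data.cell_ids
            )
            if cluster_labels.isna().any():
                bad = list(cluster_labels.index[cluster_labels.isna()][:5])
                raise ValueError(f"cells without cluster label: {bad}")
        elif data.cluster_labels is not None:
            cluster_labels = data.cluster_labels

        stage = "read_marker_table"
        if config.markers is None:
            raise ValueError("no marker file configured")
        markers = read_marker_table(config.markers)

        stage = "build_weighted_markers"
        scope = Scope(
            species=config.species,
            tissue=config.tissue,
            category=config.category,
        )
        weighted = build_weighted_markers(
            markers, scope, max_n_marker=config.max_n_marker
        )
        write_weighted_markers(weighted, _out("weighted_markers.csv"))

        stage = "preprocess"
        if config.se_provided:
            # caller guarantees the matrix already holds scaled expression
            se = pd.DataFrame(
                data.counts
                if not hasattr(data.counts, "todense")
                else data.counts.todense(),
                index=data.gene_ids,
                columns=data.cell_ids,
            )
            se = se.loc[se.index.intersection(weighted.markers["gene"].unique())]
            normalized = None
        else:
            normalized = lognormalize(
                data.counts, config.scale_factor, cell_ids=data.cell_ids
            )
            se = scale_markers(
                normalized,
                data.gene_ids,
                weighted.markers["gene"].unique(),
                clip=config.clip,
                cell_ids=data.cell_ids,
            )
        per_cluster = None
        if (
            cluster_labels is not None
            and config.log2fc_threshold is not None
            and normalized is not None
        ):
            per_cluster = log2fc_marker_filter(
                normalized,
                data.gene_ids,
                data.cell_ids,
                cluster_labels,
                weighted,
                threshold=config.log2fc_threshold,
            )

        stage = "annotate"
        result = annotate(
            se,
            weighted,
            cluster_labels=cluster_labels,
            q=config.quantile,
            allow_unknown=config.allow_unknown,
            k=config.top_k,
            per_cluster_markers=per_cluster,
        )
        result.cell_scores.to_csv(_out("cell_scores.csv"))
        write_annotation_tsv(
            result.cell_winners, result.cell_scores, _out("cell_annotation.tsv")
        )
        if result.cluster_scores is not None:
            result.cluster_scores.to_csv(_out("cluster_scores.csv"))
            write_annotation_tsv(
                result.cluster_winners,
                result.cluster_scores,
                _out("cluster_annotation.tsv"),
            )
            write_json(result.report, _out("impact_report.json"))

        stage = "evaluate"
        benchmark = None
        if config.truth is not None and result.cluster_winners is not None:
            truth_cells = read_labels_tsv(config.truth, "truth").reindex(
                data.cell_ids
            )
            cluster_truth = majority_truth_label(cluster_labels, truth_cells)
            if config.ontology is not None:
                graph = load_ontology(config.ontology)
                benchmark = ontology_performance(
                    result.cluster_winners.to_dict(),
                    cluster_truth.to_dict(),
                    graph,
                )
                write_json(benchmark.to_dict(), _out("benchmark.json"))

        stage = "write_report"
        report = {
            "package": "markerscore",
            "version": __version__,
            "config": config.to_dict(),
            "ecs_max": weighted.ecs_max,
            "n_cells": len(data.cell_ids),
            "n_genes": len(data.gene_ids),
            "n_weighted_markers": len(weighted.markers),
            "warnings": collector.messages,
        }
        if benchmark is not None:
            report["mean_similarity"] = benchmark.mean_similarity
        write_json(report, _out("run_report.json"))
    except Exception as exc:
        for path in written:
            if os.path.exists(path):
                os.remove(path)
        raise PipelineError(stage, exc) from exc
    finally:
        logging.getLogger("markerscore").removeHandler(collector)

    return {"outdir": config.outdir, "artifacts": sorted(written)}
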
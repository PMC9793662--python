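"""High-level orchestration: matrix in, QC report and comparisons out.

These convenience entry points wire the modules together the way the CLI
(and most users) run them: initial filter -> clustering -> per-cluster MAD
QC, and optionally the side-by-side comparison against the fixed 200-gene /
10%-mito cutoff with joint clustering and unique-cluster detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .comparison import find_unique_clusters, joint_retention_labels, standard_cutoff_filter
from .io import CountMatrix
from .metrics import (
    InitialFilterConfig,
    compute_cell_metrics,
    initial_filter,
    tag_gene_categories,
)
from .preprocess import ClusterLabels, PipelineConfig, cluster_cells
from .qc import MetricSpec, QCReport, apply_adaptive_qc, default_metric_specs

__all__ = ["AdaptiveQCResult", "ComparisonResult", "run_adaptive_qc", "compare_standard_cutoff"]


@dataclass
class AdaptiveQCResult:
    """Everything produced by one adaptive QC run."""

    matrix: CountMatrix            # after the initial filter
    cell_mask_initial: np.ndarray  # over the input matrix
    gene_mask_initial: np.ndarray
    metrics: pd.DataFrame          # per-cell QC metrics (post initial filter)
    labels: ClusterLabels
    embedding: np.ndarray
    normalized: sp.csr_matrix
    report: QCReport

    @property
    def passed(self) -> np.ndarray:
        return self.report.passed

    def filtered_matrix(self) -> CountMatrix:
        """Cells that passed adaptive QC."""
        return self.matrix.subset(self.passed)


def run_adaptive_qc(
    matrix: CountMatrix,
    pipeline: PipelineConfig | None = None,
    specs: list[MetricSpec] | None = None,
    initial: InitialFilterConfig | None = None,
    mito_pattern=None,
    ribo_pattern=None,
) -> AdaptiveQCResult:
    """Initial filter, clustering, then per-cluster MAD QC."""
    pipeline = pipeline or PipelineConfig()
    specs = specs if specs is not None else default_metric_specs()
    kw = {}
    if mito_pattern is not None:
        kw["mito_pattern"] = mito_pattern
    if ribo_pattern is not None:
        kw["ribo_pattern"] = ribo_pattern
    flags = tag_gene_categories(matrix, **kw)
    raw_metrics = compute_cell_metrics(matrix, flags)
    filtered, cell_mask, gene_mask = initial_filter(matrix, raw_metrics, initial)
    metrics = raw_metrics.loc[cell_mask]
    labels, embedding, normalized = cluster_cells(filtered, pipeline)
    report = apply_adaptive_qc(metrics, labels, specs)
    return AdaptiveQCResult(
        filtered, cell_mask, gene_mask, metrics, labels, embedding, normalized, report
    )


@dataclass
class ComparisonResult:
    """Adaptive QC versus the fixed-cutoff baseline on the same cells."""

    retention: np.ndarray          # four-way label per post-initial-filter cell
    keep_mask: np.ndarray          # cells retained by at least one method
    joint_labels: ClusterLabels    # joint clustering of the kept cells
    joint_embedding: np.ndarray
    unique_clusters: pd.DataFrame

    def retention_table(self) -> pd.Series:
        return pd.Series(self.retention).value_counts()


def compare_standard_cutoff(
    result: AdaptiveQCResult,
    min_genes: float = 200.0,
    max_mito: float = 10.0,
    unique_min_cells: int = 30,
    unique_min_frac: float = 0.85,
    pipeline: PipelineConfig | None = None,
) -> ComparisonResult:
    """Joint-cluster the union of retained cells and flag unique clusters.

    The joint clustering reuses the same pipeline hyperparameters as the
    main run; only cells are excluded ("neither"), genes are untouched.
    """
    pipeline = pipeline or PipelineConfig()
    cutoff_mask = standard_cutoff_filter(result.metrics, min_genes, max_mito)
    retention, keep = joint_retention_labels(result.passed, cutoff_mask)
    kept = result.matrix.subset(keep)
    joint_labels, joint_emb, _ = cluster_cells(kept, pipeline)
    unique = find_unique_clusters(
        joint_labels, retention[keep], unique_min_cells, unique_min_frac
    )
    return ComparisonResult(retention, keep, joint_labels, joint_emb, unique)
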
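"""Per-cell QC metrics and the minimal empty-droplet-level initial filter.

The four metrics carried through the whole package are

* ``n_counts`` — total UMI count of the droplet,
* ``n_genes``  — gene complexity (genes with count > 0),
* ``percent_mito`` — percentage (0-100) of counts in mitochondrial genes,
* ``percent_ribo`` — percentage (0-100) of counts in ribosomal-protein genes.

Metrics always describe the droplet as sequenced: they are computed once on
the raw matrix and are NOT recomputed after gene pruning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GeneFlags",
    "InitialFilterConfig",
    "EmptyFilterError",
    "tag_gene_categories",
    "compute_cell_metrics",
    "initial_filter",
    "METRIC_NAMES",
]

METRIC_NAMES = ("n_counts", "n_genes", "percent_mito", "percent_ribo")

#: default prefixes: human/mouse mitochondrial transcripts and ribosomal
#: protein genes (matched case-insensitively at the start of the symbol)
DEFAULT_MITO_PREFIXES = ("MT-",)
DEFAULT_RIBO_PREFIXES = ("RPS", "RPL")


@dataclass
class GeneFlags:
    """Boolean mito/ribo membership per gene, plus the prefix rules used."""

    is_mito: np.ndarray
    is_ribo: np.ndarray
    mito_pattern: tuple[str, ...] = DEFAULT_MITO_PREFIXES
    ribo_pattern: tuple[str, ...] = DEFAULT_RIBO_PREFIXES

    def __post_init__(self) -> None:
        self.is_mito = np.asarray(self.is_mito, bool)
        self.is_ribo = np.asarray(self.is_ribo, bool)
        if self.is_mito.shape != self.is_ribo.shape:
            raise ValueError("mito and ribo flag vectors differ in length")


@dataclass
class InitialFilterConfig:
    """Minimal filter removing obvious empty droplets / destroyed cells.

    Cells with fewer than ``min_genes_per_cell`` genes or with more than
    ``max_percent_mito`` percent mitochondrial counts are removed (strict
    inequalities), then genes expressed in fewer than ``min_cells_per_gene``
    of the remaining cells are dropped. Set ``enabled=False`` to skip the
    step entirely (e.g. when a dedicated empty-droplet method was already
    applied upstream).
    """

    min_genes_per_cell: int = 100
    max_percent_mito: float = 80.0
    min_cells_per_gene: int = 3
    enabled: bool = True

    def __post_init__(self) -> None:
        if min(self.min_genes_per_cell, self.max_percent_mito, self.min_cells_per_gene) <= 0:
            raise ValueError("initial filter thresholds must be positive")


class EmptyFilterError(RuntimeError):
    """Raised when a filter removes every cell."""


def _prefix_match(genes: list[str], prefixes) -> np.ndarray:
    pfx = tuple(p.upper() for p in (prefixes if not isinstance(prefixes, str) else (prefixes,)))
    return np.array([g.upper().startswith(pfx) for g in genes], bool)


def tag_gene_categories(
    matrix: CountMatrix,
    mito_pattern=DEFAULT_MITO_PREFIXES,
    ribo_pattern=DEFAULT_RIBO_PREFIXES,
) -> GeneFlags:
    """Flag mitochondrial and ribosomal-protein genes by symbol prefix.

    Matching is case-insensitive at the start of the symbol, so the defaults
    cover both human (``MT-CO1``, ``RPS4X``) and mouse (``mt-Nd1``,
    ``Rps19``) conventions. Zero matches is legal (a warning is logged and
    the corresponding percent metric is identically zero downstream).
    """
    if not mito_pattern or not ribo_pattern:
        raise ValueError("gene category patterns must be non-empty")
    is_mito = _prefix_match(matrix.genes, mito_pattern)
    is_ribo = _prefix_match(matrix.genes, ribo_pattern)
    if not is_mito.any():
        logger.warning("no genes matched the mitochondrial pattern %s", mito_pattern)
    if not is_ribo.any():
        logger.warning("no genes matched the ribosomal pattern %s", ribo_pattern)
    return GeneFlags(is_mito, is_ribo, tuple(mito_pattern), tuple(ribo_pattern))


def compute_cell_metrics(matrix: CountMatrix, flags: GeneFlags) -> pd.DataFrame:
    """Compute the per-cell QC metric table.

    Returns a DataFrame indexed by barcode with columns ``n_counts``,
    ``n_genes``, ``percent_mito`` and ``percent_ribo``. Cells with zero
    total counts get percent metrics defined as 0.
    """
    if len(flags.is_mito) != matrix.n_genes:
        raise ValueError("gene flags are not aligned to the matrix genes")
    X = matrix.counts
    n_counts = np.asarray(X.sum(axis=1)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    mito = np.asarray(X[:, flags.is_mito].sum(axis=1)).ravel()
    ribo = np.asarray(X[:, flags.is_ribo].sum(axis=1)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_mito = np.where(n_counts > 0, 100.0 * mito / np.maximum(n_counts, 1), 0.0)
        pct_ribo = np.where(n_counts > 0, 100.0 * ribo / np.maximum(n_counts, 1), 0.0)
    return pd.DataFrame(
        {
            "n_counts": n_counts.astype(float),
            "n_genes": n_genes.astype(int),
            "percent_mito": pct_mito,
            "percent_ribo": pct_ribo,
        },
        index=pd.Index(matrix.barcodes, name="barcode"),
    )


def initial_filter(
    matrix: CountMatrix,
    metrics: pd.DataFrame,
    config: InitialFilterConfig | None = None,
) -> tuple[CountMatrix, np.ndarray, np.ndarray]:
    """Apply the minimal initial filter; returns (matrix, cell_mask, gene_mask).

    Cells are filtered first (``n_genes < min_genes_per_cell`` OR
    ``percent_mito > max_percent_mito`` removed); genes expressed in fewer
    than ``min_cells_per_gene`` of the *remaining* cells are then dropped.
    Both masks index into the input matrix, so the filtered matrix equals
    ``matrix.subset(cell_mask, gene_mask)`` exactly.
    """
    config = config or InitialFilterConfig()
    if len(metrics) != matrix.n_cells:
        raise ValueError("metrics not aligned to matrix cells")
    if not config.enabled:
        return matrix, np.ones(matrix.n_cells, bool), np.ones(matrix.n_genes, bool)
    cell_mask = (
        (metrics["n_genes"].to_numpy() >= config.min_genes_per_cell)
        & (metrics["percent_mito"].to_numpy() <= config.max_percent_mito)
    )
    if not cell_mask.any():
        raise EmptyFilterError(
            "initial filter removed every cell; review min_genes_per_cell/"
            "max_percent_mito or disable the step"
        )
    cells_per_gene = np.asarray((matrix.counts[cell_mask] > 0).sum(axis=0)).ravel()
    gene_mask = cells_per_gene >= config.min_cells_per_gene
    logger.info(
        "initial filter: kept %d/%d cells, %d/%d genes",
        cell_mask.sum(), matrix.n_cells, gene_mask.sum(), matrix.n_genes,
    )
    return matrix.subset(cell_mask, gene_mask), cell_mask, gene_mask
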
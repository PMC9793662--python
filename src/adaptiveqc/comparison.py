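"""Comparing adaptive QC against the conventional fixed-cutoff filter.

The baseline ("standard cutoff") removes cells with fewer than 200 genes or
more than 10% mitochondrial counts, regardless of cluster. To see what each
method uniquely keeps, cells retained by at least one method are labelled
``both`` / ``adaptive_only`` / ``cutoff_only``, jointly re-clustered, and
clusters dominated by one method's exclusive cells are flagged as "unique"
to that method: at least 30 cells with at least 85% of them retained by
only one method. A cluster unique to the adaptive method is a cell
population the fixed filter would have silently deleted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .preprocess import _as_label_array

logger = logging.getLogger(__name__)

__all__ = [
    "RETENTION_LABELS",
    "standard_cutoff_filter",
    "joint_retention_labels",
    "find_unique_clusters",
    "signature_score",
]

RETENTION_LABELS = ("both", "adaptive_only", "cutoff_only", "neither")


def standard_cutoff_filter(
    metrics: pd.DataFrame,
    min_genes: float = 200.0,
    max_mito: float = 10.0,
) -> np.ndarray:
    """Fixed-threshold retention mask.

    Removal conditions are strict (< 200 genes or > 10% mito removed), so a
    cell is retained iff ``n_genes >= min_genes`` and
    ``percent_mito <= max_mito``.
    """
    return (
        (metrics["n_genes"].to_numpy(float) >= min_genes)
        & (metrics["percent_mito"].to_numpy(float) <= max_mito)
    )


def joint_retention_labels(
    adaptive_mask,
    cutoff_mask,
) -> tuple[np.ndarray, np.ndarray]:
    """Four-way retention label per cell, plus the joint-clustering subset.

    Returns ``(labels, keep_mask)`` where ``labels[i]`` is one of
    ``both``/``adaptive_only``/``cutoff_only``/``neither`` and ``keep_mask``
    selects the cells retained by at least one method (the ``neither``
    cells are excluded before joint clustering).
    """
    a = np.asarray(adaptive_mask, bool)
    c = np.asarray(cutoff_mask, bool)
    if a.shape != c.shape:
        raise ValueError("retention masks have different lengths")
    labels = np.where(a & c, "both", np.where(a, "adaptive_only",
                      np.where(c, "cutoff_only", "neither")))
    return labels, a | c


def find_unique_clusters(
    joint_clusters,
    retention_labels,
    min_cells: int = 30,
    min_frac: float = 0.85,
) -> pd.DataFrame:
    """Flag joint clusters dominated by one method's exclusive cells.

    Applied symmetrically: a cluster of at least ``min_cells`` cells with at
    least ``min_frac`` of its members labelled ``adaptive_only`` is unique
    to the adaptive method, and likewise for ``cutoff_only``. Returns one
    row per joint cluster with size, both exclusive fractions and
    ``unique_to`` in {``adaptive``, ``cutoff``, ``none``}.
    """
    labels = _as_label_array(joint_clusters)
    ret = np.asarray(retention_labels)
    if len(labels) != len(ret):
        raise ValueError("retention labels not aligned to joint clusters")
    rows = []
    for cid in np.unique(labels):
        in_c = labels == cid
        size = int(in_c.sum())
        fa = float((ret[in_c] == "adaptive_only").mean())
        fc = float((ret[in_c] == "cutoff_only").mean())
        unique_to = "none"
        if size >= min_cells:
            if fa >= min_frac:
                unique_to = "adaptive"
            elif fc >= min_frac:
                unique_to = "cutoff"
        rows.append(
            {"cluster": int(cid), "size": size, "fraction_adaptive_only": fa,
             "fraction_cutoff_only": fc, "is_unique_to": unique_to}
        )
    return pd.DataFrame(rows).set_index("cluster")


def signature_score(
    normalized: sp.spmatrix,
    gene_set,
    gene_names: list[str],
) -> np.ndarray:
    """Per-cell mean log-normalized expression over a marker gene set.

    Signature genes missing from the matrix are dropped with a warning; at
    least one must be present. Used to validate that cells rescued by the
    adaptive filter genuinely express the markers of the cell type they
    were annotated as.
    """
    wanted = set(gene_set)
    idx = [i for i, g in enumerate(gene_names) if g in wanted]
    missing = wanted - {gene_names[i] for i in idx}
    if missing:
        logger.warning("%d signature genes absent from matrix: %s",
                       len(missing), sorted(missing)[:10])
    if not idx:
        raise ValueError("no signature gene present in the matrix")
    X = sp.csc_matrix(normalized)[:, idx]
    return np.asarray(X.mean(axis=1)).ravel()
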
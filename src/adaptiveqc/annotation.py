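"""Heuristic marker-based cluster annotation and its accuracy assessment.

Clusters are labelled by (1) one-vs-rest differential expression, (2)
filtering the differentially expressed genes (DEGs) on effect size,
expression fraction and adjusted significance, (3) summing the average log
fold changes of filtered DEGs that are markers of each candidate cell type,
and (4) assigning the best-scoring type among those supported by at least
three markers — otherwise ``"Unknown"``.

A compact marker table in the style of curated marker databases (cell type
-> marker gene symbols) ships with the package for tests and demos; see
:func:`MarkerDatabase.load_builtin`.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .preprocess import _as_label_array

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerDatabase",
    "differential_expression",
    "filter_deg",
    "score_cell_types",
    "annotate_clusters",
    "majority_cluster_annotation",
    "annotation_accuracy",
]

UNKNOWN = "Unknown"


@dataclass
class MarkerDatabase:
    """Mapping from cell-type name to a set of marker gene symbols."""

    entries: dict[str, frozenset[str]]
    species: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.entries = {str(k): frozenset(v) for k, v in self.entries.items()}
        for name, markers in self.entries.items():
            if not markers:
                raise ValueError(f"cell type {name!r} has an empty marker set")

    def __len__(self) -> int:
        return len(self.entries)

    def cell_types(self) -> list[str]:
        return sorted(self.entries)

    def markers(self, cell_type: str) -> frozenset[str]:
        return self.entries[cell_type]

    @classmethod
    def from_table(cls, path: str | os.PathLike, sep: str = "\t") -> "MarkerDatabase":
        """Read a two/three-column delimited table: cell_type, gene_symbol[, species]."""
        df = pd.read_csv(path, sep=sep)
        cols = [c.lower() for c in df.columns]
        df.columns = cols
        if "cell_type" not in cols or "gene_symbol" not in cols:
            raise ValueError(f"{path}: expected columns cell_type and gene_symbol")
        entries: dict[str, set[str]] = {}
        species: dict[str, str] = {}
        for _, row in df.iterrows():
            entries.setdefault(str(row["cell_type"]), set()).add(str(row["gene_symbol"]))
            if "species" in cols:
                species[str(row["cell_type"])] = str(row["species"])
        return cls({k: frozenset(v) for k, v in entries.items()}, species or None)

    @classmethod
    def load_builtin(cls) -> "MarkerDatabase":
        """Load the packaged synthetic mini marker database (20 cell types).

        This is a hand-written synthetic stand-in using well-known canonical
        marker symbols, shipped so annotation is exercisable offline; it is
        not a copy of any published database.
        """
        from importlib.resources import files

        return cls.from_table(files("adaptiveqc.data") / "markers_synthetic.tsv")

    def without_markers(self, cell_type: str, keep: int) -> "MarkerDatabase":
        """Copy of the database with ``cell_type`` reduced to ``keep`` markers."""
        entries = dict(self.entries)
        entries[cell_type] = frozenset(sorted(entries[cell_type])[:keep])
        return MarkerDatabase(entries, self.species)


def differential_expression(
    normalized: sp.spmatrix,
    clusters,
    gene_names: list[str],
    min_cluster_size: int = 2,
) -> pd.DataFrame:
    """One-vs-rest two-sided Wilcoxon rank-sum test per gene per cluster.

    Returns one row per (cluster, gene) with ``avg_log_fold_change`` (mean
    log-normalized expression in the cluster minus the rest), ``pct_in_cluster``
    (percent of cluster cells expressing the gene) and Benjamini-Hochberg
    adjusted ``q_value`` (adjusted within each cluster's test family).
    Clusters smaller than ``min_cluster_size`` are skipped with a warning.
    """
    labels = _as_label_array(clusters)
    X = np.asarray(sp.csr_matrix(normalized).todense(), float)
    if X.shape[0] != len(labels):
        raise ValueError("cluster labels not aligned to matrix rows")
    if len(np.unique(labels)) < 2:
        raise ValueError("differential expression needs at least 2 clusters")
    frames = []
    for cid in np.unique(labels):
        in_c = labels == cid
        if in_c.sum() < min_cluster_size or (~in_c).sum() < 1:
            logger.warning("cluster %d too small for DE testing; skipped", cid)
            continue
        A, B = X[in_c], X[~in_c]
        with np.errstate(divide="ignore", invalid="ignore"):
            res = mannwhitneyu(A, B, axis=0, alternative="two-sided", method="asymptotic")
        pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        qvals = multipletests(pvals, method="fdr_bh")[1]
        frames.append(
            pd.DataFrame(
                {
                    "cluster": int(cid),
                    "gene": gene_names,
                    "avg_log_fold_change": A.mean(axis=0) - B.mean(axis=0),
                    "pct_in_cluster": 100.0 * (A > 0).mean(axis=0),
                    "p_value": pvals,
                    "q_value": qvals,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def filter_deg(
    deg: pd.DataFrame,
    min_lfc: float = 0.25,
    min_pct: float = 25.0,
    max_q: float = 0.05,
) -> pd.DataFrame:
    """Keep DEG rows with lfc > 0.25, pct > 25% and q < 0.05 (all strict)."""
    keep = (
        (deg["avg_log_fold_change"] > min_lfc)
        & (deg["pct_in_cluster"] > min_pct)
        & (deg["q_value"] < max_q)
    )
    return deg.loc[keep].reset_index(drop=True)


def score_cell_types(filtered_deg: pd.DataFrame, db: MarkerDatabase) -> pd.DataFrame:
    """Additive marker scores for one cluster's filtered DEGs.

    For each cell type, the score is the sum of ``avg_log_fold_change``
    over filtered DEGs that are markers of that type, and
    ``n_supporting_markers`` counts those genes. A DEG that is a marker of
    several types contributes to each of them. Order of DEG rows is
    irrelevant (the score is a plain sum).
    """
    if len(db) == 0:
        raise ValueError("marker database is empty")
    lfc = dict(zip(filtered_deg["gene"], filtered_deg["avg_log_fold_change"]))
    rows = []
    for cell_type in db.cell_types():
        hits = sorted(set(lfc) & db.markers(cell_type))
        rows.append(
            {
                "cell_type": cell_type,
                "score": float(sum(lfc[g] for g in hits)),
                "n_supporting_markers": len(hits),
                "markers": ";".join(hits),
            }
        )
    return pd.DataFrame(rows)


def annotate_clusters(
    filtered_deg: pd.DataFrame,
    db: MarkerDatabase,
    min_markers: int = 3,
) -> pd.DataFrame:
    """Assign each cluster the best-scoring sufficiently supported cell type.

    Types supported by fewer than ``min_markers`` filtered DEGs are
    excluded; among the rest, the highest score wins (exact score ties are
    broken lexicographically by type name and logged). If no type
    qualifies the cluster is labelled ``"Unknown"``.
    """
    rows = []
    for cid in sorted(filtered_deg["cluster"].unique()):
        scores = score_cell_types(filtered_deg[filtered_deg["cluster"] == cid], db)
        ok = scores[scores["n_supporting_markers"] >= min_markers]
        if ok.empty:
            rows.append({"cluster": int(cid), "label": UNKNOWN, "score": 0.0,
                         "n_supporting_markers": 0, "top_markers": ""})
            continue
        best_score = ok["score"].max()
        best = ok[ok["score"] == best_score].sort_values("cell_type")
        if len(best) > 1:
            logger.info("cluster %d: score tie between %s; choosing %s",
                        cid, best["cell_type"].tolist(), best.iloc[0]["cell_type"])
        top = best.iloc[0]
        rows.append(
            {"cluster": int(cid), "label": top["cell_type"], "score": float(top["score"]),
             "n_supporting_markers": int(top["n_supporting_markers"]),
             "top_markers": top["markers"]}
        )
    return pd.DataFrame(rows).set_index("cluster")


def majority_cluster_annotation(
    cell_labels,
    clusters,
    majority_frac: float = 0.75,
) -> dict[int, str]:
    """Map per-cell reference annotations to per-cluster labels.

    A cluster gets its modal annotation when that annotation covers at
    least ``majority_frac`` (inclusive) of the cluster's *annotated* cells;
    otherwise ``"unknown"``. Unlabelled cells (None/NaN/empty) are ignored
    when computing the majority.
    """
    labels = _as_label_array(clusters)
    ann = pd.Series(list(cell_labels), dtype=object).replace("", np.nan)
    out: dict[int, str] = {}
    for cid in np.unique(labels):
        sub = ann[labels == cid].dropna()
        if sub.empty:
            out[int(cid)] = "unknown"
            continue
        counts = sub.value_counts()
        if counts.iloc[0] / len(sub) >= majority_frac:
            out[int(cid)] = str(counts.index[0])
        else:
            out[int(cid)] = "unknown"
    return out


def annotation_accuracy(
    predicted,
    reference: dict[int, str],
    synonyms=(),
) -> float:
    """Percent of evaluable clusters whose predicted label matches the reference.

    Clusters whose reference label is ``"unknown"`` are excluded. A pair
    present in ``synonyms`` (unordered label pairs) counts as a match.
    """
    if isinstance(predicted, pd.DataFrame):
        predicted = predicted["label"].to_dict()
    syn = {frozenset(p) for p in synonyms}
    evaluable = [c for c, ref in reference.items() if ref != "unknown"]
    if not evaluable:
        raise ValueError("no evaluable clusters (all reference labels unknown)")
    matches = 0
    for cid in evaluable:
        pred, ref = predicted[cid], reference[cid]
        if pred == ref or frozenset((pred, ref)) in syn:
            matches += 1
    return 100.0 * matches / len(evaluable)
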
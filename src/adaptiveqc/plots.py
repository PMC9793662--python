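"""Exploratory plots around the adaptive QC workflow.

All figures carry the two conventional fixed-filter reference lines where
relevant: 10 (percent mitochondrial counts) and log2(200) ~ 7.64 (gene
complexity on a log2 axis), so per-cluster distributions can be judged
against the standard cutoff at a glance.
"""

from __future__ import annotations

import os
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .preprocess import _as_label_array

__all__ = [
    "MITO_REFERENCE",
    "GENES_REFERENCE_LOG2",
    "qc_boxplots",
    "sweep_facets",
    "composition_barplot",
    "retention_scatter",
    "eda_plots",
]

MITO_REFERENCE = 10.0
GENES_REFERENCE_LOG2 = float(np.log2(200))


def _cluster_groups(values: np.ndarray, labels: np.ndarray):
    ids = np.unique(labels)
    return ids, [values[labels == cid] for cid in ids]


def qc_boxplots(metrics: pd.DataFrame, clusters, out_dir: str | os.PathLike) -> list[Path]:
    """Per-cluster boxplots of percent_mito (red line at 10) and of
    log2(n_genes) (red line at log2(200))."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = _as_label_array(clusters)
    paths = []
    for metric, transform, refline, ylabel, fname in (
        ("percent_mito", lambda v: v, MITO_REFERENCE, "percent mito", "boxplot_percent_mito.png"),
        ("n_genes", lambda v: np.log2(np.maximum(v, 1)), GENES_REFERENCE_LOG2,
         "log2(n_genes)", "boxplot_log2_n_genes.png"),
    ):
        ids, groups = _cluster_groups(transform(metrics[metric].to_numpy(float)), labels)
        fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(ids) + 2), 4))
        ax.boxplot(groups, tick_labels=[str(i) for i in ids])
        ax.axhline(refline, color="red", linewidth=1)
        ax.set_xlabel("cluster")
        ax.set_ylabel(ylabel)
        fig.tight_layout()
        p = out / fname
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths


def sweep_facets(sweep: pd.DataFrame, out_dir: str | os.PathLike,
                 value: str = "n_filtered") -> Path:
    """One facet per cluster: cells filtered out versus the MAD multiplier."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = sorted(sweep["cluster"].unique())
    ncol = min(4, len(ids))
    nrow = int(np.ceil(len(ids) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.4 * nrow),
                             squeeze=False, sharex=True)
    for ax, cid in zip(axes.ravel(), ids):
        sub = sweep[sweep["cluster"] == cid]
        ax.plot(sub["x"], sub[value])
        ax.set_title(f"cluster {cid}", fontsize=9)
    for ax in axes.ravel()[len(ids):]:
        ax.axis("off")
    for ax in axes[-1]:
        ax.set_xlabel("MAD multiplier x")
    for row in axes:
        row[0].set_ylabel(value)
    fig.tight_layout()
    p = out / f"sweep_{value}.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    return p


def composition_barplot(joint_clusters, retention_labels,
                        out_dir: str | os.PathLike) -> Path:
    """Stacked per-cluster composition by retention label."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = _as_label_array(joint_clusters)
    ret = np.asarray(retention_labels)
    ids = np.unique(labels)
    cats = ("both", "adaptive_only", "cutoff_only")
    fracs = {c: [float((ret[labels == cid] == c).mean()) for cid in ids] for c in cats}
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(ids) + 2), 4))
    bottom = np.zeros(len(ids))
    for c in cats:
        ax.bar([str(i) for i in ids], fracs[c], bottom=bottom, label=c)
        bottom += np.array(fracs[c])
    ax.set_xlabel("joint cluster")
    ax.set_ylabel("fraction of cells")
    ax.legend(fontsize=8)
    fig.tight_layout()
    p = out / "joint_cluster_composition.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    return p


def retention_scatter(embedding: np.ndarray, retention_labels,
                      out_dir: str | os.PathLike) -> Path:
    """2-D embedding (first two components) colored by retention label."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ret = np.asarray(retention_labels)
    fig, ax = plt.subplots(figsize=(5, 4))
    for c in ("both", "adaptive_only", "cutoff_only"):
        m = ret == c
        if m.any():
            ax.scatter(embedding[m, 0], embedding[m, 1], s=4, label=c, alpha=0.6)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=8)
    fig.tight_layout()
    p = out / "retention_scatter.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    return p


def eda_plots(metrics: pd.DataFrame, clusters, out_dir: str | os.PathLike,
              sweep: pd.DataFrame | None = None) -> list[Path]:
    """Write the standard EDA figure set; returns the file paths."""
    paths = qc_boxplots(metrics, clusters, out_dir)
    if sweep is not None:
        paths.append(sweep_facets(sweep, out_dir, "n_filtered"))
        paths.append(sweep_facets(sweep, out_dir, "pct_filtered"))
    return paths
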
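"""Standard scRNA-seq preprocessing up to cluster labels.

The adaptive QC step needs transcriptional neighborhoods, obtained through
the conventional recipe: per-cell normalization to ``log(TPX+1)``, highly
variable gene (HVG) selection by mean-binned dispersion, per-gene z-scoring,
PCA, a k-nearest-neighbor graph, and Louvain community detection. Defaults
follow common practice: scale factor 10,000, 2000 HVGs, 50 PCs, k=20,
resolution 1.4.
"""

from __future__ import annotations

import logging
import random as _random
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "ClusterLabels",
    "normalize_log1p",
    "select_hvg",
    "scale_and_pca",
    "cluster_graph",
    "cluster_cells",
]


@dataclass
class PipelineConfig:
    """Hyperparameters of the preprocessing/clustering recipe.

    ``resolution`` controls Louvain granularity; ``clip_value`` bounds
    z-scored expression so extreme HVG outliers cannot dominate PCA.
    """

    scale_factor: float = 10_000.0
    n_hvg: int = 2000
    n_pcs: int = 50
    k_neighbors: int = 20
    resolution: float = 1.4
    random_seed: int = 0
    clip_value: float = 10.0
    backend: str = "louvain"  # louvain | leiden | callable

    def __post_init__(self) -> None:
        for name in ("scale_factor", "n_hvg", "n_pcs", "k_neighbors", "resolution"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Read a plain ``key = value`` config file (# comments allowed)."""
        import dataclasses
        from pathlib import Path

        types = {f.name: f.type for f in dataclasses.fields(cls)}
        casts = {"scale_factor": float, "n_hvg": int, "n_pcs": int,
                 "k_neighbors": int, "resolution": float, "random_seed": int,
                 "clip_value": float, "backend": str}
        kw = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in types:
                raise ValueError(f"unknown pipeline config key {key!r}")
            kw[key] = casts[key](value.strip())
        return cls(**kw)


@dataclass
class ClusterLabels:
    """Consecutive integer cluster ids (0..n_clusters-1), ordered by size."""

    labels: np.ndarray
    n_clusters: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.n_clusters = int(self.labels.max()) + 1 if self.labels.size else 0
        if self.labels.size and sorted(set(self.labels.tolist())) != list(range(self.n_clusters)):
            raise ValueError("cluster labels must be consecutive integers from 0")

    def __len__(self) -> int:
        return len(self.labels)


def _as_label_array(clusters) -> np.ndarray:
    if isinstance(clusters, ClusterLabels):
        return clusters.labels
    return np.asarray(clusters, dtype=int)


def normalize_log1p(matrix: CountMatrix | sp.spmatrix, scale_factor: float = 10_000.0) -> sp.csr_matrix:
    """Depth-normalize and log-transform counts.

    Entry (c, g) becomes ``ln(1 + scale_factor * count(c,g) / n_counts(c))``
    so cells are comparable regardless of sequencing depth; the sparsity
    pattern is preserved. Cells with zero total count (possible only when
    the initial filter was skipped) get an all-zero row with a warning.
    """
    X = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    X = sp.csr_matrix(X, dtype=np.float64, copy=True)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        logger.warning("%d cells have zero total counts; normalized rows set to 0", (totals == 0).sum())
    scale = np.where(totals > 0, scale_factor / np.maximum(totals, 1.0), 0.0)
    X = sp.diags(scale) @ X
    X.data = np.log1p(X.data)
    return sp.csr_matrix(X)


def select_hvg(normalized: sp.spmatrix, n_hvg: int = 2000, n_bins: int = 20) -> np.ndarray:
    """Rank genes by normalized dispersion and return the top ``n_hvg`` indices.

    The classic mean/dispersion binning rule: per gene, compute mean and
    dispersion (variance/mean) of ``expm1`` of the log-normalized values,
    cut genes into ``n_bins`` equal-width bins of mean expression, z-score
    the dispersions within each bin, and rank by that z-score (descending;
    ties broken by gene index for determinism). Genes in singleton bins or
    with zero dispersion get z-score 0 / -inf respectively, so constant
    genes always rank below any gene with nonzero variance.
    """
    X = sp.csc_matrix(normalized)
    n_cells, n_genes = X.shape
    if n_cells < 2:
        raise ValueError("HVG selection needs at least 2 cells")
    E = X.copy()
    E.data = np.expm1(E.data)
    mean = np.asarray(E.mean(axis=0)).ravel()
    sq = E.copy()
    sq.data = sq.data**2
    var = np.asarray(sq.mean(axis=0)).ravel() - mean**2
    var = var * n_cells / max(n_cells - 1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    dispersion[np.abs(dispersion) < 1e-10] = 0.0  # constant genes, up to rounding
    bins = pd.cut(mean, bins=n_bins)
    df = pd.DataFrame({"bin": bins, "disp": dispersion})
    grouped = df.groupby("bin", observed=True)["disp"]
    bin_mean = grouped.transform("mean")
    bin_std = grouped.transform(lambda s: s.std(ddof=1))
    z = (df["disp"] - bin_mean) / bin_std.replace(0.0, np.nan)
    z = z.fillna(0.0).to_numpy()
    z = np.where(dispersion <= 0, -np.inf, z)
    order = np.lexsort((np.arange(n_genes), -z))
    return order[: min(n_hvg, n_genes)]


def scale_and_pca(
    normalized: sp.spmatrix,
    hvg: np.ndarray,
    config: PipelineConfig | None = None,
) -> np.ndarray:
    """Z-score HVG expression, clip, and project onto principal components.

    Zero-variance genes are set to all-zero rather than dividing by zero;
    values are clipped to ``±clip_value``; the PCA solver is seeded so the
    embedding is deterministic for fixed input.
    """
    config = config or PipelineConfig()
    hvg = np.asarray(hvg, int)
    if hvg.size == 0:
        raise ValueError("HVG index list is empty")
    X = np.asarray(sp.csc_matrix(normalized)[:, hvg].todense(), dtype=np.float64)
    n_cells = X.shape[0]
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if n_cells > 1 else np.ones(X.shape[1])
    sd_safe = np.where(sd > 0, sd, 1.0)
    X = (X - mu) / sd_safe
    X[:, sd == 0] = 0.0
    np.clip(X, -config.clip_value, config.clip_value, out=X)
    n_pcs = min(config.n_pcs, n_cells - 1, X.shape[1])
    if n_pcs < config.n_pcs:
        logger.warning("n_pcs reduced from %d to %d (rank limit)", config.n_pcs, n_pcs)
    if n_pcs < 1:
        raise ValueError("not enough cells/genes for even one principal component")
    solver = "arpack" if 0 < n_pcs < min(X.shape) else "full"
    pca = PCA(n_components=n_pcs, svd_solver=solver, random_state=config.random_seed)
    return pca.fit_transform(X)


def _knn_graph(embedding: np.ndarray, k: int):
    """Symmetrized union of directed k-nearest-neighbor edges (Euclidean)."""
    import igraph as ig

    n = embedding.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    edges = set()
    for i in range(n):
        for j in idx[i]:
            if j != i:
                edges.add((min(i, int(j)), max(i, int(j))))
    return ig.Graph(n=n, edges=sorted(edges), directed=False)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel to consecutive ids ordered by decreasing cluster size."""
    ids, counts = np.unique(labels, return_counts=True)
    order = ids[np.lexsort((ids, -counts))]
    mapping = {old: new for new, old in enumerate(order)}
    return np.array([mapping[v] for v in labels], int)


def cluster_graph(embedding: np.ndarray, config: PipelineConfig | None = None) -> ClusterLabels:
    """Cluster cells on the kNN graph of the embedding.

    The default backend is Louvain community detection at the configured
    resolution (seeded, so results are reproducible); ``leiden`` and any
    callable ``(embedding, config) -> labels`` can be swapped in — the
    downstream QC makes no assumption about which backend produced the
    labels.
    """
    config = config or PipelineConfig()
    embedding = np.asarray(embedding, float)
    n = embedding.shape[0]
    if n < 2:
        logger.warning("fewer than 2 cells; returning a single cluster")
        return ClusterLabels(np.zeros(n, int))
    if callable(config.backend):
        return ClusterLabels(_relabel_by_size(np.asarray(config.backend(embedding, config), int)))
    g = _knn_graph(embedding, config.k_neighbors)
    if config.backend == "louvain":
        import igraph as ig

        ig.set_random_number_generator(_random.Random(config.random_seed))
        part = g.community_multilevel(resolution=config.resolution)
        labels = np.array(part.membership, int)
    elif config.backend == "leiden":
        import leidenalg

        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=config.resolution,
            seed=config.random_seed,
            n_iterations=-1,
        )
        labels = np.array(part.membership, int)
    else:
        raise ValueError(f"unknown clustering backend {config.backend!r}")
    return ClusterLabels(_relabel_by_size(labels))


def cluster_cells(
    matrix: CountMatrix,
    config: PipelineConfig | None = None,
) -> tuple[ClusterLabels, np.ndarray, sp.csr_matrix]:
    """Full recipe: normalize -> HVG -> scale+PCA -> kNN -> communities.

    Returns ``(labels, embedding, normalized_matrix)``.
    """
    config = config or PipelineConfig()
    norm = normalize_log1p(matrix, config.scale_factor)
    hvg = select_hvg(norm, config.n_hvg)
    emb = scale_and_pca(norm, hvg, config)
    labels = cluster_graph(emb, config)
    logger.info("clustered %d cells into %d clusters", matrix.n_cells, labels.n_clusters)
    return labels, emb, norm
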
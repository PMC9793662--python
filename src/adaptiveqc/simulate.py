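"""Ground-truthed synthetic scRNA-seq count matrices.

The generator emulates the structure the adaptive QC method targets:
several transcriptional clusters with cluster-specific QC-metric profiles
(e.g. a mitochondria-rich but healthy cluster, or a genuinely
low-gene-complexity cluster), optional within-cluster damaged-cell
outliers, and marker-gene programs drawn from the packaged marker table so
annotation is exercisable end to end.

Count model, per cluster: each cell draws a library size from a log-normal
distribution (median = calibrated cluster depth) and a bounded per-cell
mitochondrial and ribosomal propensity (uniform window around 1, modelling
bounded biological variation in organelle content). Generic-program genes
get independent negative-binomial counts (gamma-Poisson with quadratic
dispersion ``var = mu + phi * mu^2``); mitochondrial and ribosomal genes
share the cell's block propensity as their overdispersion factor — the
transcripts come from a common organelle pool, so their variation is
correlated across the block — with Poisson noise per gene inside the
block. The cluster depth is calibrated by bisection so the median gene
complexity hits its target, and the mitochondrial/ribosomal gene mass is
rescaled iteratively so the expected count fractions hit the percent
targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix
from .metrics import compute_cell_metrics, tag_gene_categories
from .qc import compute_mad

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterSpec",
    "SyntheticSpec",
    "SimulationSpecError",
    "generate_atlas",
    "implant_outliers",
    "preset_fixtures",
    "annotation_demo_spec",
]

OUTLIER_KINDS = ("high_mito", "low_counts", "low_genes")


class SimulationSpecError(ValueError):
    """The synthetic specification is internally inconsistent/infeasible."""


@dataclass
class ClusterSpec:
    """One simulated transcriptional cluster.

    ``cell_type`` keys into a marker database: the cluster's expression
    program then boosts that type's marker genes, so annotation can recover
    it. ``propensity_window`` is the half-width of the bounded per-cell
    mito/ribo propensity (fraction of the median), and ``library_sigma``
    the log-normal sigma of library sizes.
    """

    name: str
    n_cells: int
    target_median_n_genes: float
    target_median_percent_mito: float
    target_median_percent_ribo: float = 15.0
    cell_type: str | None = None
    library_sigma: float = 0.5
    dispersion: float = 0.5
    propensity_window: float = 0.3

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise SimulationSpecError("n_cells must be >= 1")
        for t in (self.target_median_percent_mito, self.target_median_percent_ribo):
            if not 0 <= t <= 100:
                raise SimulationSpecError("percent targets must lie in [0, 100]")
        if self.target_median_percent_mito + self.target_median_percent_ribo >= 100:
            raise SimulationSpecError("mito + ribo percent targets must stay below 100")


@dataclass
class SyntheticSpec:
    """Full description of one synthetic atlas."""

    clusters: list[ClusterSpec]
    n_genes: int = 2000
    mito_gene_frac: float = 0.015
    ribo_gene_frac: float = 0.04
    outlier_fraction: float = 0.0
    outlier_severity: float = 4.0
    marker_boost: float = 8.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not self.clusters:
            raise SimulationSpecError("at least one cluster required")
        if not (0 <= self.outlier_fraction < 0.5):
            raise SimulationSpecError("outlier_fraction must be in [0, 0.5)")
        if self.outlier_severity <= 0:
            raise SimulationSpecError("outlier_severity must be positive")
        for frac in (self.mito_gene_frac, self.ribo_gene_frac):
            if not 0 <= frac <= 1:
                raise SimulationSpecError("gene fractions must lie in [0, 1]")


def _build_vocabulary(spec: SyntheticSpec, marker_genes: list[str]):
    """Gene symbol list: mito block, ribo block, markers, generic filler."""
    n_mito = round(spec.mito_gene_frac * spec.n_genes)
    if n_mito > 0:
        n_mito = max(13, n_mito)  # a genome has at least the 13 protein-coding MT genes
    n_ribo = round(spec.ribo_gene_frac * spec.n_genes)
    mito = [f"MT-SIM{i:03d}" for i in range(n_mito)]
    ribo = [f"RPS-SIM{i:03d}" if i % 2 == 0 else f"RPL-SIM{i:03d}" for i in range(n_ribo)]
    markers = [g for g in dict.fromkeys(marker_genes)
               if not g.upper().startswith(("MT-", "RPS", "RPL"))]
    n_generic = spec.n_genes - len(mito) - len(ribo) - len(markers)
    if n_generic < 0:
        raise SimulationSpecError("n_genes too small for mito/ribo/marker blocks")
    generic = [f"GSIM{i:05d}" for i in range(n_generic)]
    genes = mito + ribo + markers + generic
    idx_mito = np.arange(len(mito))
    idx_ribo = np.arange(len(mito), len(mito) + len(ribo))
    return genes, idx_mito, idx_ribo


def _expected_fraction(f_block: float, f_other: float, window: float) -> float:
    """Mean renormalized block fraction under the uniform propensity window."""
    u = np.linspace(1 - window, 1 + window, 21)
    um, ur = np.meshgrid(u, u)
    f_rest = 1.0 - f_block - f_other
    frac = f_block * um / (f_rest + f_block * um + f_other * ur)
    return float(frac.mean())


def _calibrate_block_mass(target: float, other: float, window: float) -> float:
    """Rescale a block's mass so its expected renormalized fraction hits target.

    At most 20 multiplicative corrections, tolerance 5% relative on the
    expected fraction.
    """
    if target == 0:
        return 0.0
    mass = target
    for _ in range(20):
        got = _expected_fraction(mass, other, window)
        if abs(got - target) <= 0.05 * target:
            break
        mass *= target / max(got, 1e-12)
    return mass


def _expected_n_genes(p: np.ndarray, depth: float, phi: float) -> float:
    mu = depth * p
    if phi > 1e-12:
        zero = (1.0 + phi * mu) ** (-1.0 / phi)
    else:
        zero = np.exp(-mu)
    return float((1.0 - zero).sum())


def _calibrate_depth(p: np.ndarray, target: float, phi: float) -> float:
    """Bisection on log depth so the expected gene complexity hits target."""
    n_expressible = int((p > 0).sum())
    if target >= n_expressible:
        raise SimulationSpecError(
            f"target median n_genes {target} unreachable with "
            f"{n_expressible} expressible genes"
        )
    lo, hi = 0.0, 25.0  # log depth
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _expected_n_genes(p, np.exp(mid), phi) < target:
            lo = mid
        else:
            hi = mid
    return float(np.exp(0.5 * (lo + hi)))


def _cluster_counts(cs: ClusterSpec, spec: SyntheticSpec, genes, idx_mito, idx_ribo,
                    marker_idx: np.ndarray, shared_weights: dict[int, float],
                    rng: np.random.Generator) -> np.ndarray:
    """Sample one cluster's dense count block."""
    n_genes = len(genes)
    fm = cs.target_median_percent_mito / 100.0
    fr = cs.target_median_percent_ribo / 100.0
    if fm > 0 and idx_mito.size == 0:
        raise SimulationSpecError(f"cluster {cs.name}: mito target but no mito genes")
    if fr > 0 and idx_ribo.size == 0:
        raise SimulationSpecError(f"cluster {cs.name}: ribo target but no ribo genes")

    # cluster-specific expression program (log-normal weights). Marker genes
    # use an atlas-wide shared baseline — markers are *specifically*
    # expressed, so their background level must not vary by cluster — and
    # only this cluster's own markers are boosted on top of it.
    w = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    for j, base in shared_weights.items():
        w[j] = base
    if marker_idx.size:
        w[marker_idx] *= spec.marker_boost
    is_special = np.zeros(n_genes, bool)
    is_special[idx_mito] = True
    is_special[idx_ribo] = True

    fm_eff = _calibrate_block_mass(fm, fr, cs.propensity_window)
    fr_eff = _calibrate_block_mass(fr, fm, cs.propensity_window)
    p = np.zeros(n_genes)
    rest = ~is_special
    p[rest] = w[rest] / w[rest].sum() * (1.0 - fm_eff - fr_eff)
    if idx_mito.size:
        p[idx_mito] = w[idx_mito] / w[idx_mito].sum() * fm_eff
    if idx_ribo.size:
        p[idx_ribo] = w[idx_ribo] / w[idx_ribo].sum() * fr_eff

    depth = _calibrate_depth(p, cs.target_median_n_genes, cs.dispersion)

    lib = depth * np.exp(cs.library_sigma * rng.standard_normal(cs.n_cells))
    um = rng.uniform(1 - cs.propensity_window, 1 + cs.propensity_window, cs.n_cells)
    ur = rng.uniform(1 - cs.propensity_window, 1 + cs.propensity_window, cs.n_cells)

    P = np.tile(p, (cs.n_cells, 1))
    if idx_mito.size:
        P[:, idx_mito] *= um[:, None]
    if idx_ribo.size:
        P[:, idx_ribo] *= ur[:, None]
    P /= P.sum(axis=1, keepdims=True)
    mu = lib[:, None] * P
    phi = cs.dispersion
    lam = mu
    if phi > 1e-12:
        # independent gamma-Poisson for the generic program; mito/ribo genes
        # already carry their (block-correlated) overdispersion through the
        # per-cell propensity, so they stay Poisson around it
        lam = mu.copy()
        lam[:, rest] = rng.gamma(1.0 / phi, 1.0, size=(cs.n_cells, int(rest.sum()))) * (
            phi * mu[:, rest]
        )
    return rng.poisson(lam).astype(np.int32)


def generate_atlas(spec: SyntheticSpec, markers=None) -> tuple[CountMatrix, pd.DataFrame]:
    """Generate a synthetic atlas; returns ``(matrix, truth)``.

    ``truth`` is a DataFrame indexed by barcode with ``true_cluster``,
    ``cell_type``, ``is_outlier`` and ``outlier_kind``. Fully deterministic
    for a fixed ``spec.random_seed``. When ``spec.outlier_fraction > 0``,
    damaged-cell outliers are implanted (see :func:`implant_outliers`).
    """
    if markers is None and any(c.cell_type for c in spec.clusters):
        from .annotation import MarkerDatabase

        markers = MarkerDatabase.load_builtin()
    marker_genes: list[str] = []
    for cs in spec.clusters:
        if cs.cell_type is not None:
            if markers is None or cs.cell_type not in markers.entries:
                raise SimulationSpecError(f"unknown cell type {cs.cell_type!r}")
            marker_genes.extend(sorted(markers.markers(cs.cell_type)))
    genes, idx_mito, idx_ribo = _build_vocabulary(spec, marker_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    rng = np.random.default_rng(spec.random_seed)
    all_marker_idx = sorted(gene_pos[g] for g in marker_genes if g in gene_pos)
    shared_weights = {
        j: w for j, w in zip(all_marker_idx,
                             rng.lognormal(0.0, 1.0, size=len(all_marker_idx)))
    }
    blocks, truth_rows = [], []
    for cs in spec.clusters:
        midx = (
            np.array(sorted(gene_pos[g] for g in markers.markers(cs.cell_type)
                            if g in gene_pos), int)
            if cs.cell_type is not None
            else np.array([], int)
        )
        blocks.append(
            _cluster_counts(cs, spec, genes, idx_mito, idx_ribo, midx, shared_weights, rng)
        )
        truth_rows.extend(
            {"true_cluster": cs.name, "cell_type": cs.cell_type or "",
             "is_outlier": False, "outlier_kind": "none"}
            for _ in range(cs.n_cells)
        )
    counts = sp.csr_matrix(np.vstack(blocks))
    barcodes = [f"cell_{i:05d}" for i in range(counts.shape[0])]
    matrix = CountMatrix(counts, barcodes, genes)
    truth = pd.DataFrame(truth_rows, index=pd.Index(barcodes, name="barcode"))
    for cs in spec.clusters:
        sub = truth["true_cluster"] == cs.name
        med = compute_cell_metrics(matrix, tag_gene_categories(matrix)).loc[sub.to_numpy()]
        logger.info(
            "cluster %s: realized medians n_genes=%.0f percent_mito=%.2f",
            cs.name, med["n_genes"].median(), med["percent_mito"].median(),
        )
    if spec.outlier_fraction > 0:
        matrix, truth = implant_outliers(matrix, truth, spec, rng=rng)
    return matrix, truth


def _thin_to_counts(row: np.ndarray, bound: float, rng) -> np.ndarray:
    """Binomially thin a cell until its total count is below ``bound``."""
    target = max(1.0, 0.6 * bound)
    out = row.copy()
    for _ in range(10):
        total = out.sum()
        if total <= bound:
            break
        out = rng.binomial(out, min(1.0, target / max(total, 1.0)))
        target *= 0.8
    return out


def _thin_to_genes(row: np.ndarray, bound: float, rng) -> np.ndarray:
    """Thin a cell until its gene complexity is below ``bound``."""
    out = row.copy()
    for _ in range(60):
        if (out > 0).sum() <= bound:
            break
        out = rng.binomial(out, 0.8)
    return out


def implant_outliers(
    matrix: CountMatrix,
    truth: pd.DataFrame,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Perturb a fraction of each cluster's cells into damaged-cell outliers.

    Each selected cell is pushed at least ``spec.outlier_severity``
    clean-cluster MADs beyond the clean cluster median on one metric:
    ``high_mito`` reassigns count mass to mitochondrial genes (keeping the
    total count), ``low_counts``/``low_genes`` binomially thin the cell.
    Thinning never produces negative counts, and the clean-cluster
    statistics are computed before any cell is perturbed. Targets that are
    unreachable (e.g. ``median - severity * MAD`` below zero) are clamped
    with a warning.
    """
    if spec.outlier_fraction == 0:
        return matrix, truth
    rng = rng if rng is not None else np.random.default_rng(spec.random_seed + 1)
    flags = tag_gene_categories(matrix)
    metrics = compute_cell_metrics(matrix, flags)
    dense = np.asarray(matrix.counts.todense()).astype(np.int64)
    truth = truth.copy()
    idx_mito = np.flatnonzero(flags.is_mito)
    severity = spec.outlier_severity

    for cname in truth["true_cluster"].unique():
        in_c = (truth["true_cluster"] == cname).to_numpy()
        m = metrics.loc[in_c]
        stats = {
            k: (float(m[k].median()), compute_mad(m[k])) for k in
            ("percent_mito", "n_counts", "n_genes")
        }
        n_out = int(round(spec.outlier_fraction * in_c.sum()))
        if n_out == 0:
            continue
        cells = rng.choice(np.flatnonzero(in_c), size=n_out, replace=False)
        kinds = [OUTLIER_KINDS[i % 3] for i in range(n_out)]
        rng.shuffle(kinds)
        mito_profile = dense[in_c][:, idx_mito].sum(axis=0).astype(float)
        if idx_mito.size and mito_profile.sum() == 0:
            mito_profile = np.ones(idx_mito.size)
        for cell, kind in zip(cells, kinds):
            row = dense[cell]
            if kind == "high_mito":
                med, mad = stats["percent_mito"]
                mad = max(mad, 0.25)
                boundary = med + severity * mad
                # dying cells show a large mitochondrial fraction in absolute
                # terms, not merely relative to their cluster: damage floor 25%
                target = min(95.0, max(boundary + 1.5 * mad, 25.0))
                total = int(row.sum())
                for _ in range(6):
                    non = row.astype(float).copy()
                    non[idx_mito] = 0.0
                    if non.sum() == 0 or total == 0:
                        break
                    p = non / non.sum() * (1 - target / 100.0)
                    p[idx_mito] += mito_profile / mito_profile.sum() * (target / 100.0)
                    new = rng.multinomial(total, p / p.sum())
                    if 100.0 * new[idx_mito].sum() / max(new.sum(), 1) >= boundary:
                        row = new
                        break
                    target = min(97.0, target + 2 * mad)
                dense[cell] = row
            elif kind == "low_counts":
                med, mad = stats["n_counts"]
                boundary = med - severity * mad
                if boundary <= 0.15 * med:
                    # severity*MAD below the median would be non-positive for a
                    # wide library-size spread; clamp to a deep but expressible
                    # depth loss so the cell stays recognizably its own type
                    logger.warning("cluster %s: low_counts target clamped", cname)
                    boundary = max(2.0, 0.15 * med)
                dense[cell] = _thin_to_counts(row, boundary, rng)
            else:  # low_genes
                med, mad = stats["n_genes"]
                boundary = med - severity * mad
                if boundary <= 1:
                    logger.warning("cluster %s: low_genes target clamped", cname)
                    boundary = max(2.0, 0.35 * med)
                dense[cell] = _thin_to_genes(row, boundary, rng)
            truth.iloc[cell, truth.columns.get_loc("is_outlier")] = True
            truth.iloc[cell, truth.columns.get_loc("outlier_kind")] = kind
    new_matrix = CountMatrix(sp.csr_matrix(dense.astype(np.int32)),
                             matrix.barcodes, list(matrix.genes))
    return new_matrix, truth


def preset_fixtures(name: str, seed: int = 0) -> SyntheticSpec:
    """Named study fixtures.

    * ``heart_like`` — three separable clusters including a healthy but
      mitochondria-rich cardiomyocyte-like cluster (median percent_mito
      target 15.178, median gene complexity target 2428); the population a
      fixed 10%-mito cutoff deletes but cluster-adaptive QC keeps.
    * ``lung_like`` — four clusters including a genuinely low-complexity
      neutrophil-like cluster (median gene complexity target 150, below the
      conventional 200-gene cutoff).
    * ``null_uniform`` — four transcriptionally distinct clusters with
      identical QC-metric profiles; a negative control under which adaptive
      and fixed filtering should treat all clusters alike.
    """
    if name == "heart_like":
        return SyntheticSpec(
            clusters=[
                ClusterSpec("cardiomyocyte", 500, 2428, 15.178, 8.0,
                            cell_type="Cardiomyocytes"),
                ClusterSpec("fibroblast", 400, 1800, 4.0, 15.0,
                            cell_type="Fibroblasts"),
                ClusterSpec("endothelial", 350, 1500, 5.0, 18.0,
                            cell_type="Endothelial cells"),
            ],
            n_genes=4000,
            mito_gene_frac=0.01,
            ribo_gene_frac=0.025,
            random_seed=seed,
        )
    if name == "lung_like":
        return SyntheticSpec(
            clusters=[
                ClusterSpec("neutrophil", 300, 150, 3.0, 20.0, cell_type="Neutrophils"),
                ClusterSpec("macrophage", 350, 1600, 5.0, 15.0, cell_type="Macrophages"),
                ClusterSpec("epithelial", 350, 2100, 6.0, 12.0, cell_type="Epithelial cells"),
                ClusterSpec("t_cell", 300, 900, 4.0, 25.0, cell_type="T cells"),
            ],
            n_genes=3000,
            mito_gene_frac=0.012,
            ribo_gene_frac=0.03,
            random_seed=seed,
        )
    if name == "null_uniform":
        return SyntheticSpec(
            clusters=[
                ClusterSpec(f"program_{i}", 250, 1200, 5.0, 15.0) for i in range(4)
            ],
            n_genes=2000,
            mito_gene_frac=0.015,
            ribo_gene_frac=0.04,
            random_seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}")


def annotation_demo_spec(seed: int = 0, n_cells: int = 200) -> SyntheticSpec:
    """Five immune cell types with marker-driven programs, clean.

    Used to demonstrate that the DEG -> marker-score pipeline recovers the
    generating cell type of every cluster.
    """
    types = ["T cells", "B cells", "NK cells", "Monocytes", "Dendritic cells"]
    return SyntheticSpec(
        clusters=[
            ClusterSpec(t.lower().replace(" ", "_"), n_cells, 1000, 5.0, 15.0, cell_type=t)
            for t in types
        ],
        n_genes=1500,
        mito_gene_frac=0.015,
        ribo_gene_frac=0.04,
        random_seed=seed,
    )
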
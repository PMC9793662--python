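"""Cluster-adaptive MAD thresholding — the core of the package.

Within each transcriptional cluster, a cell is an outlier on a QC metric if
it lies more than ``x`` median absolute deviations (MADs) from the cluster
median of that metric. Cutoffs are one-sided by default (lower for
``n_counts``/``n_genes``, upper for ``percent_mito``) and two permissive
safety bounds keep the adaptive rule from becoming stricter than the
conventional fixed filter: the per-cluster lower ``n_genes`` cutoff is
capped at 200 and the upper ``percent_mito`` cutoff is floored at 10%.
A cell passes overall iff it passes every enabled metric (AND rule).

The MAD here is unscaled — ``median(|v - median(v)|)`` with no normal
consistency constant — because the default multiplier ``x = 2`` is defined
on that raw scale. A consistency-constant option exists for users who want
MADs comparable to standard deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .metrics import METRIC_NAMES
from .preprocess import _as_label_array

logger = logging.getLogger(__name__)

__all__ = [
    "MetricSpec",
    "ClusterCutoffs",
    "QCReport",
    "compute_mad",
    "compute_cluster_cutoffs",
    "apply_adaptive_qc",
    "threshold_sweep",
    "classify_cluster_trends",
    "default_metric_specs",
    "DEFAULT_X_GRID",
]

#: multiplier grid used by the threshold sweep: 1.0 to 3.5 in steps of 0.1
DEFAULT_X_GRID = np.round(np.arange(1.0, 3.5 + 1e-9, 0.1), 10)


@dataclass(frozen=True)
class MetricSpec:
    """Which side(s) of a QC metric to threshold, and its safety bound."""

    metric_name: str
    side: str = "lower"  # lower | upper | both
    mad_multiplier: float = 2.0
    bound_value: float | None = None
    bound_kind: str = "none"  # cap_lower_cutoff | floor_upper_cutoff | none

    def __post_init__(self) -> None:
        if self.metric_name not in METRIC_NAMES:
            raise ValueError(f"unknown metric {self.metric_name!r}")
        if self.side not in ("lower", "upper", "both"):
            raise ValueError(f"unknown side {self.side!r}")
        if self.mad_multiplier <= 0:
            raise ValueError("mad_multiplier must be positive")
        if self.bound_kind not in ("cap_lower_cutoff", "floor_upper_cutoff", "none"):
            raise ValueError(f"unknown bound_kind {self.bound_kind!r}")
        if self.bound_kind != "none" and self.bound_value is None:
            raise ValueError("bound_kind set but bound_value missing")


def default_metric_specs(
    x: float = 2.0,
    include_ribo: bool = False,
    min_genes_bound: float = 200.0,
    max_mito_bound: float = 10.0,
) -> list[MetricSpec]:
    """The shipped presets.

    Three metrics by default (``n_counts`` lower, ``n_genes`` lower capped
    at 200, ``percent_mito`` upper floored at 10); ``include_ribo=True``
    adds ``percent_ribo`` as a two-sided unbounded metric.
    """
    specs = [
        MetricSpec("n_counts", "lower", x),
        MetricSpec("n_genes", "lower", x, min_genes_bound, "cap_lower_cutoff"),
        MetricSpec("percent_mito", "upper", x, max_mito_bound, "floor_upper_cutoff"),
    ]
    if include_ribo:
        specs.append(MetricSpec("percent_ribo", "both", x))
    return specs


def compute_mad(values, consistency: bool = False) -> float:
    """Median absolute deviation, unscaled by default.

    ``consistency=True`` multiplies by 1.4826 (normal-consistent scale).
    """
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("MAD of an empty vector is undefined")
    return float(median_abs_deviation(values, scale=1 / 1.4826 if consistency else 1.0))


@dataclass
class ClusterCutoffs:
    """Resolved cutoffs for one (cluster, metric) pair."""

    cluster_id: int
    metric_name: str
    median: float
    mad: float
    lower_cutoff: float | None
    upper_cutoff: float | None
    bound_applied: bool = False


def compute_cluster_cutoffs(
    values,
    spec: MetricSpec,
    cluster_id: int = 0,
    consistency: bool = False,
) -> ClusterCutoffs:
    """Cutoffs ``median ± x·MAD`` for one cluster, with the bound rules.

    Bounds are permissive only: ``cap_lower_cutoff`` replaces the lower
    cutoff with ``min(lower, bound)`` and ``floor_upper_cutoff`` replaces
    the upper cutoff with ``max(upper, bound)``. A disabled side is
    reported as ``None`` (treated as ±infinity when testing cells).

    Degenerate clusters (MAD == 0, at least half the cells share the
    median) would otherwise delete every off-median cell; for those, sides
    without a safety bound fall back to no cutoff (±infinity) with a
    warning, while bounded sides keep the formula, which collapses to the
    permissive ``min(median, bound)`` / ``max(median, bound)``.
    """
    values = np.asarray(values, float)
    med = float(np.median(values))
    mad = compute_mad(values, consistency=consistency)
    x = spec.mad_multiplier
    lower = upper = None
    bound_applied = False
    degenerate = mad == 0.0

    if spec.side in ("lower", "both"):
        if degenerate and spec.bound_kind != "cap_lower_cutoff":
            logger.warning(
                "cluster %s metric %s has MAD 0; lower cutoff disabled",
                cluster_id, spec.metric_name,
            )
            lower = None
        else:
            lower = med - x * mad
            if spec.bound_kind == "cap_lower_cutoff" and lower > spec.bound_value:
                lower = float(spec.bound_value)
                bound_applied = True
    if spec.side in ("upper", "both"):
        if degenerate and spec.bound_kind != "floor_upper_cutoff":
            logger.warning(
                "cluster %s metric %s has MAD 0; upper cutoff disabled",
                cluster_id, spec.metric_name,
            )
            upper = None
        else:
            upper = med + x * mad
            if spec.bound_kind == "floor_upper_cutoff" and upper < spec.bound_value:
                upper = float(spec.bound_value)
                bound_applied = True
    return ClusterCutoffs(cluster_id, spec.metric_name, med, mad, lower, upper, bound_applied)


@dataclass
class QCReport:
    """Per-cell pass/fail record plus the per-cluster cutoff table.

    ``cells`` has one row per cell (index = barcode) with columns
    ``passed``, ``cluster`` and, per enabled metric ``m``: ``m``,
    ``m_lower_cutoff``, ``m_upper_cutoff``, ``m_passed``. ``cutoffs`` has
    one row per (cluster, metric).
    """

    cells: pd.DataFrame
    cutoffs: pd.DataFrame

    @property
    def passed(self) -> np.ndarray:
        return self.cells["passed"].to_numpy(bool)


def apply_adaptive_qc(
    metrics: pd.DataFrame,
    clusters,
    specs: list[MetricSpec] | None = None,
    consistency: bool = False,
) -> QCReport:
    """Run per-cluster MAD thresholding and combine metrics with AND.

    Cutoffs for each enabled metric are computed on that cluster's cells
    only; a cell passes a metric iff ``lower <= value <= upper`` with
    ``None`` meaning ±infinity — values exactly equal to a cutoff pass
    (only cells strictly outside the bounds are outliers). The overall
    ``passed`` flag is the conjunction over enabled metrics, and every cell
    entering the step appears in exactly one report row.
    """
    specs = specs if specs is not None else default_metric_specs()
    labels = _as_label_array(clusters)
    if len(labels) != len(metrics):
        raise ValueError("cluster labels not aligned to metrics rows")
    n = len(metrics)
    cells = pd.DataFrame(index=metrics.index)
    cells["passed"] = True
    cells["cluster"] = labels
    cutoff_rows = []
    for spec in specs:
        values = metrics[spec.metric_name].to_numpy(float)
        lo = np.full(n, -np.inf)
        hi = np.full(n, np.inf)
        lo_col = np.full(n, np.nan)
        hi_col = np.full(n, np.nan)
        for cid in np.unique(labels):
            in_c = labels == cid
            cut = compute_cluster_cutoffs(values[in_c], spec, int(cid), consistency)
            cutoff_rows.append(cut)
            if cut.lower_cutoff is not None:
                lo[in_c] = cut.lower_cutoff
                lo_col[in_c] = cut.lower_cutoff
            if cut.upper_cutoff is not None:
                hi[in_c] = cut.upper_cutoff
                hi_col[in_c] = cut.upper_cutoff
        ok = (values >= lo) & (values <= hi)
        cells[spec.metric_name] = values
        cells[f"{spec.metric_name}_lower_cutoff"] = lo_col
        cells[f"{spec.metric_name}_upper_cutoff"] = hi_col
        cells[f"{spec.metric_name}_passed"] = ok
        cells["passed"] &= ok
    cutoffs = pd.DataFrame(
        [
            {
                "cluster": c.cluster_id,
                "metric": c.metric_name,
                "median": c.median,
                "mad": c.mad,
                "lower_cutoff": np.nan if c.lower_cutoff is None else c.lower_cutoff,
                "upper_cutoff": np.nan if c.upper_cutoff is None else c.upper_cutoff,
                "bound_applied": c.bound_applied,
            }
            for c in cutoff_rows
        ]
    )
    return QCReport(cells, cutoffs)


def threshold_sweep(
    metrics: pd.DataFrame,
    clusters,
    specs: list[MetricSpec] | None = None,
    x_grid=DEFAULT_X_GRID,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sweep the MAD multiplier and count filtered cells per cluster.

    Returns ``(sweep, stats)``: ``sweep`` holds one row per (cluster, x)
    with ``n_filtered`` and ``pct_filtered`` (consistent with
    :func:`apply_adaptive_qc` at that x, so ``n_filtered`` is non-increasing
    in x within each cluster); ``stats`` holds per (cluster, metric) the
    median, MAD, standard deviation, and MAD/SD ratio, to help judge how
    far each cluster's spread is from the MAD scale.
    """
    specs = specs if specs is not None else default_metric_specs()
    x_grid = np.asarray(x_grid, float)
    if x_grid.size == 0 or (x_grid <= 0).any() or (np.diff(x_grid) < 0).any():
        raise ValueError("x_grid must be non-empty, positive and sorted")
    labels = _as_label_array(clusters)
    rows = []
    for x in x_grid:
        at_x = [replace(s, mad_multiplier=float(x)) for s in specs]
        report = apply_adaptive_qc(metrics, labels, at_x)
        failed = ~report.passed
        for cid in np.unique(labels):
            in_c = labels == cid
            nf = int(failed[in_c].sum())
            rows.append(
                {"cluster": int(cid), "x": float(x), "n_filtered": nf,
                 "pct_filtered": 100.0 * nf / in_c.sum()}
            )
    sweep = pd.DataFrame(rows)
    stat_rows = []
    for cid in np.unique(labels):
        in_c = labels == cid
        for spec in specs:
            v = metrics.loc[in_c, spec.metric_name].to_numpy(float)
            mad = compute_mad(v)
            sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
            stat_rows.append(
                {"cluster": int(cid), "metric": spec.metric_name,
                 "median": float(np.median(v)), "mad": mad, "sd": sd,
                 "mad_sd_ratio": mad / sd if sd > 0 else np.nan}
            )
    return sweep, pd.DataFrame(stat_rows)


def classify_cluster_trends(metrics: pd.DataFrame, clusters) -> pd.DataFrame:
    """Classify clusters by their median QC metric profiles.

    Five base criteria (all strict inequalities): median ``n_genes`` < 200
    or > 2000, median ``percent_mito`` > 10, median ``percent_ribo`` < 10
    or > 20; plus the composite categories used when summarizing trends:
    low/high transcriptional complexity and low/high ribosomal fraction,
    each additionally requiring median mito < 10 so damaged-looking
    clusters are not classified.
    """
    labels = _as_label_array(clusters)
    rows = []
    for cid in np.unique(labels):
        sub = metrics.loc[labels == cid]
        mg = float(sub["n_genes"].median())
        mm = float(sub["percent_mito"].median())
        mr = float(sub["percent_ribo"].median())
        rows.append(
            {
                "cluster": int(cid),
                "median_n_genes": mg,
                "median_percent_mito": mm,
                "median_percent_ribo": mr,
                "genes_below_200": mg < 200,
                "genes_above_2000": mg > 2000,
                "mito_above_10": mm > 10,
                "ribo_below_10": mr < 10,
                "ribo_above_20": mr > 20,
                "low_complexity": (mg < 200) and (mm < 10),
                "high_complexity": (mg > 2000) and (mm < 10),
                "ribo_low": (mr < 10) and (mm < 10),
                "ribo_high": (mr > 20) and (mm < 10),
            }
        )
    return pd.DataFrame(rows).set_index("cluster")
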
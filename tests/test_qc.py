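import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adaptiveqc import (
    MetricSpec,
    apply_adaptive_qc,
    classify_cluster_trends,
    compute_cluster_cutoffs,
    compute_mad,
    default_metric_specs,
    threshold_sweep,
)
from adaptiveqc.qc import DEFAULT_X_GRID


def brute_force_mask(metrics: pd.DataFrame, labels, specs):
    """Loop-based re-derivation of every median, MAD, bound and comparison."""
    labels = list(labels)
    n = len(metrics)
    passed = [True] * n
    for spec in specs:
        vals = [float(v) for v in metrics[spec.metric_name]]
        for cid in sorted(set(labels)):
            idx = [i for i in range(n) if labels[i] == cid]
            v = [vals[i] for i in idx]
            med = statistics.median(v)
            mad = statistics.median([abs(x - med) for x in v])
            lo, hi = float("-inf"), float("inf")
            if spec.side in ("lower", "both"):
                if mad == 0 and spec.bound_kind != "cap_lower_cutoff":
                    lo = float("-inf")
                else:
                    lo = med - spec.mad_multiplier * mad
                    if spec.bound_kind == "cap_lower_cutoff" and lo > spec.bound_value:
                        lo = spec.bound_value
            if spec.side in ("upper", "both"):
                if mad == 0 and spec.bound_kind != "floor_upper_cutoff":
                    hi = float("inf")
                else:
                    hi = med + spec.mad_multiplier * mad
                    if spec.bound_kind == "floor_upper_cutoff" and hi < spec.bound_value:
                        hi = spec.bound_value
            for i in idx:
                if not (lo <= vals[i] <= hi):
                    passed[i] = False
    return np.array(passed)


def random_instance(rng):
    n = int(rng.integers(20, 500))
    k = int(rng.integers(1, 10))
    labels = rng.integers(0, k, n)
    metrics = pd.DataFrame(
        {
            "n_counts": rng.lognormal(8, 0.8, n),
            "n_genes": rng.integers(50, 5000, n).astype(float),
            "percent_mito": rng.uniform(0, 50, n),
            "percent_ribo": rng.uniform(0, 60, n),
        },
        index=[f"bc{i}" for i in range(n)],
    )
    x = float(rng.uniform(1.0, 3.5))
    return metrics, labels, default_metric_specs(x, include_ribo=bool(rng.integers(0, 2)))


class TestMAD:
    def test_textbook_example(self):
        assert compute_mad([1, 2, 3, 4, 100]) == 1.0

    def test_constant_vector_is_zero(self):
        assert compute_mad([7, 7, 7]) == 0.0

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            compute_mad([])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-1e4, 1e4), min_size=1, max_size=40),
        st.floats(-100, 100),
        st.floats(-10, 10),
    )
    def test_affine_equivariance(self, v, b, a):
        """MAD(a*v + b) == |a| * MAD(v), checked against the definition."""
        v = np.asarray(v)
        med = statistics.median(v.tolist())
        expected = statistics.median([abs(x - med) for x in v.tolist()])
        assert compute_mad(v) == pytest.approx(expected)
        assert compute_mad(a * v + b) == pytest.approx(abs(a) * expected, abs=1e-6)


class TestClusterCutoffs:
    def test_gene_lower_cutoff_capped_at_200(self):
        spec = MetricSpec("n_genes", "lower", 2.0, 200.0, "cap_lower_cutoff")
        # median 2500, MAD 400: raw lower 1700 -> bounded to 200
        values = [1700, 2100, 2500, 2900, 3300]
        cut = compute_cluster_cutoffs(values, spec)
        assert (cut.median, cut.mad) == (2500, 400)
        assert cut.lower_cutoff == 200.0 and cut.bound_applied

    def test_mito_upper_cutoff_floored_at_10(self):
        spec = MetricSpec("percent_mito", "upper", 2.0, 10.0, "floor_upper_cutoff")
        cut = compute_cluster_cutoffs([3, 4, 5, 6, 7], spec)  # median 5, MAD 1
        assert cut.upper_cutoff == 10.0 and cut.bound_applied

    def test_mito_bound_inactive_when_raw_cutoff_above_10(self):
        spec = MetricSpec("percent_mito", "upper", 2.0, 10.0, "floor_upper_cutoff")
        cut = compute_cluster_cutoffs([9, 12, 15, 18, 21], spec)  # median 15, MAD 3
        assert cut.upper_cutoff == 21.0 and not cut.bound_applied

    def test_gene_bound_inactive_when_raw_cutoff_below_200(self):
        spec = MetricSpec("n_genes", "lower", 2.0, 200.0, "cap_lower_cutoff")
        cut = compute_cluster_cutoffs([90, 120, 150, 180, 210], spec)  # median 150, MAD 30
        assert cut.lower_cutoff == 90.0 and not cut.bound_applied

    def test_disabled_side_reported_as_none(self):
        cut = compute_cluster_cutoffs([1, 2, 3], MetricSpec("n_counts", "lower"))
        assert cut.upper_cutoff is None and cut.lower_cutoff is not None


class TestApplyAdaptiveQC:
    def test_and_rule_across_metrics(self):
        metrics = pd.DataFrame(
            {
                "n_counts": [1000.0] * 5,
                "n_genes": [100.0, 1500, 1500, 1500, 1500],  # first fails lower
                "percent_mito": [5.0] * 5,
            },
            index=[f"c{i}" for i in range(5)],
        )
        report = apply_adaptive_qc(metrics, np.zeros(5, int))
        row = report.cells.iloc[0]
        assert row["percent_mito_passed"] and not row["n_genes_passed"]
        assert not row["passed"]

    def test_degenerate_identical_values_all_pass(self):
        metrics = pd.DataFrame({"n_genes": [150.0] * 6}, index=[f"c{i}" for i in range(6)])
        specs = [MetricSpec("n_genes", "lower", 2.0, 200.0, "cap_lower_cutoff")]
        report = apply_adaptive_qc(metrics, np.zeros(6, int), specs)
        assert report.passed.all()

    def test_boundary_value_exactly_at_cutoff_passes(self):
        # median 10, MAD 2 -> lower 6, upper 14; values 6 and 14 must pass
        metrics = pd.DataFrame(
            {"percent_ribo": [6.0, 8, 10, 12, 14]}, index=[f"c{i}" for i in range(5)]
        )
        report = apply_adaptive_qc(metrics, np.zeros(5, int), [MetricSpec("percent_ribo", "both")])
        assert report.passed.all()

    def test_matches_brute_force_oracle_on_randomized_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            metrics, labels, specs = random_instance(rng)
            got = apply_adaptive_qc(metrics, labels, specs).passed
            expected = brute_force_mask(metrics, labels, specs)
            assert np.array_equal(got, expected)

    def test_permuting_cells_permutes_report_rows(self, random_metrics):
        metrics, labels = random_metrics
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(metrics))
        base = apply_adaptive_qc(metrics, labels)
        shuffled = apply_adaptive_qc(metrics.iloc[perm], labels[perm])
        assert np.array_equal(base.passed[perm], shuffled.passed)

    def test_passed_equals_conjunction_of_metric_flags(self, random_metrics):
        metrics, labels = random_metrics
        report = apply_adaptive_qc(metrics, labels)
        flag_cols = [c for c in report.cells.columns if c.endswith("_passed")]
        conj = report.cells[flag_cols].all(axis=1)
        assert (report.cells["passed"] == conj).all()

    def test_misaligned_labels_rejected(self, random_metrics):
        metrics, labels = random_metrics
        with pytest.raises(ValueError):
            apply_adaptive_qc(metrics, labels[:-1])


class TestThresholdSweep:
    def test_filtered_counts_non_increasing_in_x(self, random_metrics):
        metrics, labels = random_metrics
        sweep, _ = threshold_sweep(metrics, labels)
        for _, sub in sweep.groupby("cluster"):
            assert (np.diff(sub.sort_values("x")["n_filtered"]) <= 0).all()

    def test_consistent_with_apply_at_x2(self, random_metrics):
        metrics, labels = random_metrics
        sweep, _ = threshold_sweep(metrics, labels, x_grid=[2.0])
        report = apply_adaptive_qc(metrics, labels, default_metric_specs(2.0))
        failed = ~report.passed
        for _, row in sweep.iterrows():
            assert row["n_filtered"] == failed[labels == row["cluster"]].sum()

    def test_matches_brute_force_recount_on_grid(self, random_metrics):
        metrics, labels = random_metrics
        grid = [1.0, 2.0, 3.0]
        sweep, _ = threshold_sweep(metrics, labels, x_grid=grid)
        for x in grid:
            failed = ~brute_force_mask(metrics, labels, default_metric_specs(x))
            for cid in np.unique(labels):
                got = sweep.query("cluster == @cid and x == @x")["n_filtered"].iloc[0]
                assert got == failed[labels == cid].sum()

    def test_stats_table_reports_mad_sd_ratio(self, random_metrics):
        metrics, labels = random_metrics
        _, stats = threshold_sweep(metrics, labels)
        row = stats.iloc[0]
        v = metrics.loc[labels == row["cluster"], row["metric"]]
        assert row["median"] == pytest.approx(v.median())
        assert row["mad_sd_ratio"] == pytest.approx(compute_mad(v) / v.std(ddof=1))

    def test_invalid_grid_rejected(self, random_metrics):
        metrics, labels = random_metrics
        with pytest.raises(ValueError):
            threshold_sweep(metrics, labels, x_grid=[2.0, 1.0])

    def test_default_grid_spans_1_to_3_5_in_tenths(self):
        assert DEFAULT_X_GRID[0] == 1.0 and DEFAULT_X_GRID[-1] == 3.5
        assert len(DEFAULT_X_GRID) == 26


class TestClusterTrends:
    def _trends(self, n_genes, mito, ribo=15.0):
        metrics = pd.DataFrame(
            {"n_genes": [n_genes] * 4, "percent_mito": [mito] * 4,
             "percent_ribo": [ribo] * 4},
            index=[f"c{i}" for i in range(4)],
        )
        return classify_cluster_trends(metrics, np.zeros(4, int)).iloc[0]

    def test_low_complexity_cluster(self):
        row = self._trends(150, 5)
        assert row["low_complexity"] and row["genes_below_200"]
        assert not row["high_complexity"]

    def test_high_complexity_and_ribo_high(self):
        row = self._trends(2500, 4, ribo=25)
        assert row["high_complexity"] and row["ribo_high"]
        assert not row["ribo_low"]

    def test_boundary_median_exactly_200_is_neither(self):
        row = self._trends(200, 5)
        assert not row["genes_below_200"] and not row["genes_above_2000"]
        assert not row["low_complexity"] and not row["high_complexity"]

    def test_high_mito_cluster_excluded_from_composites(self):
        row = self._trends(2500, 15)
        assert row["mito_above_10"] and not row["high_complexity"]
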
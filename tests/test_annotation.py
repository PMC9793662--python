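import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from adaptiveqc import (
    MarkerDatabase,
    annotate_clusters,
    annotation_accuracy,
    differential_expression,
    filter_deg,
    majority_cluster_annotation,
    score_cell_types,
)


@pytest.fixture()
def two_cluster_expression():
    """100 cells, 2 clusters; gene 0 expressed at 5.0 only in cluster A."""
    rng = np.random.default_rng(0)
    X = rng.poisson(1.0, (100, 30)).astype(float)
    labels = np.array([0] * 50 + [1] * 50)
    X[:, 0] = 0.0
    X[labels == 0, 0] = 5.0
    genes = [f"G{j}" for j in range(30)]
    return sp.csr_matrix(np.log1p(X)), labels, genes


class TestDifferentialExpression:
    def test_constructed_marker_dominates(self, two_cluster_expression):
        X, labels, genes = two_cluster_expression
        deg = differential_expression(X, labels, genes)
        a = deg[deg["cluster"] == 0].set_index("gene")
        assert a["avg_log_fold_change"].idxmax() == "G0"
        assert a.loc["G0", "q_value"] < 1e-6
        assert a.loc["G0", "pct_in_cluster"] == 100.0

    def test_null_gene_rarely_significant(self):
        rng = np.random.default_rng(1)
        qs = []
        for _ in range(5):
            X = np.log1p(rng.poisson(2.0, (80, 10)).astype(float))
            labels = np.array([0] * 40 + [1] * 40)
            deg = differential_expression(sp.csr_matrix(X), labels, [f"G{j}" for j in range(10)])
            qs.append(deg["q_value"].to_numpy())
        assert np.mean(np.concatenate(qs) < 0.05) < 0.2

    def test_all_zero_gene_pct_is_zero(self):
        X = np.log1p(np.ones((20, 3)))
        X[:, 2] = 0.0
        labels = np.array([0] * 10 + [1] * 10)
        deg = differential_expression(sp.csr_matrix(X), labels, ["A", "B", "C"])
        assert (deg[deg["gene"] == "C"]["pct_in_cluster"] == 0).all()

    def test_singleton_cluster_skipped(self, two_cluster_expression):
        X, labels, genes = two_cluster_expression
        labels = labels.copy()
        labels[0] = 2  # singleton cluster
        deg = differential_expression(X, labels, genes)
        assert 2 not in deg["cluster"].unique()

    def test_single_cluster_rejected(self, two_cluster_expression):
        X, _, genes = two_cluster_expression
        with pytest.raises(ValueError):
            differential_expression(X, np.zeros(X.shape[0], int), genes)


def _deg_table(rows):
    return pd.DataFrame(rows, columns=["cluster", "gene", "avg_log_fold_change",
                                       "pct_in_cluster", "q_value"])


class TestFilterDEG:
    def test_strict_boundaries(self):
        deg = _deg_table(
            [
                (0, "A", 0.25, 30.0, 0.01),   # lfc exactly at threshold -> dropped
                (0, "B", 0.40, 26.0, 0.049),  # all pass
                (0, "C", 0.40, 25.0, 0.01),   # pct exactly at threshold -> dropped
                (0, "D", 0.40, 30.0, 0.05),   # q exactly at threshold -> dropped
            ]
        )
        kept = filter_deg(deg)
        assert kept["gene"].tolist() == ["B"]

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        deg = _deg_table(
            [(0, f"G{i}", rng.uniform(-1, 1), rng.uniform(0, 100), rng.uniform(0, 1))
             for i in range(30)]
        )
        once = filter_deg(deg)
        assert filter_deg(once).equals(once)

    def test_matches_row_scan(self):
        rng = np.random.default_rng(3)
        deg = _deg_table(
            [(0, f"G{i}", rng.uniform(-1, 1), rng.uniform(0, 100), rng.uniform(0, 1))
             for i in range(30)]
        )
        kept = set(filter_deg(deg)["gene"])
        expected = {
            r.gene for r in deg.itertuples()
            if r.avg_log_fold_change > 0.25 and r.pct_in_cluster > 25 and r.q_value < 0.05
        }
        assert kept == expected


class TestScoring:
    DB = MarkerDatabase({"T": {"A", "B", "C"}, "U": {"A", "B"}})

    def _deg(self):
        return _deg_table([(0, "A", 1.0, 50, 0.01), (0, "B", 0.5, 50, 0.01),
                           (0, "C", 0.3, 50, 0.01)])

    def test_hand_summed_scores(self):
        scores = score_cell_types(self._deg(), self.DB).set_index("cell_type")
        assert scores.loc["T", "score"] == pytest.approx(1.8)
        assert scores.loc["T", "n_supporting_markers"] == 3
        assert scores.loc["U", "score"] == pytest.approx(1.5)
        assert scores.loc["U", "n_supporting_markers"] == 2

    def test_no_matches_gives_zero_scores(self):
        deg = _deg_table([(0, "ZZZ", 1.0, 50, 0.01)])
        scores = score_cell_types(deg, self.DB)
        assert (scores["score"] == 0).all() and (scores["n_supporting_markers"] == 0).all()

    def test_shared_marker_contributes_to_both_types(self):
        scores = score_cell_types(self._deg(), self.DB).set_index("cell_type")
        # gene A is a marker of both T and U
        assert scores.loc["T", "score"] >= 1.0 and scores.loc["U", "score"] >= 1.0

    def test_order_independence(self):
        deg = self._deg()
        rev = deg.iloc[::-1].reset_index(drop=True)
        a = score_cell_types(deg, self.DB).set_index("cell_type")["score"]
        b = score_cell_types(rev, self.DB).set_index("cell_type")["score"]
        assert a.equals(b)


class TestAnnotateClusters:
    def test_under_supported_type_excluded(self):
        deg = _deg_table([(0, "A", 1.0, 50, 0.01), (0, "B", 0.5, 50, 0.01),
                          (0, "C", 0.3, 50, 0.01)])
        db = MarkerDatabase({"T": {"A", "B", "C"}, "U": {"A", "B"}})
        ann = annotate_clusters(deg, db)
        assert ann.loc[0, "label"] == "T" and ann.loc[0, "score"] == pytest.approx(1.8)

    def test_unknown_when_no_type_qualifies(self):
        deg = _deg_table([(0, "A", 1.0, 50, 0.01)])
        db = MarkerDatabase({"T": {"A", "B", "C"}})
        ann = annotate_clusters(deg, db)
        assert ann.loc[0, "label"] == "Unknown"

    def test_score_tie_broken_lexicographically(self):
        deg = _deg_table([(0, "A", 1.0, 50, 0.01), (0, "B", 0.5, 50, 0.01),
                          (0, "C", 0.3, 50, 0.01)])
        db = MarkerDatabase({"Zeta": {"A", "B", "C"}, "Alpha": {"A", "B", "C"}})
        ann = annotate_clusters(deg, db)
        assert ann.loc[0, "label"] == "Alpha"


class TestMajorityAnnotation:
    def _labels(self, n_modal, n_other, modal="T cell"):
        return [modal] * n_modal + ["B cell"] * n_other

    def test_clear_majority_assigned(self):
        out = majority_cluster_annotation(self._labels(80, 20), np.zeros(100, int))
        assert out[0] == "T cell"

    def test_below_threshold_unknown(self):
        out = majority_cluster_annotation(self._labels(60, 40), np.zeros(100, int))
        assert out[0] == "unknown"

    def test_exactly_75_percent_is_assigned(self):
        out = majority_cluster_annotation(self._labels(75, 25), np.zeros(100, int))
        assert out[0] == "T cell"

    def test_unlabelled_cells_ignored(self):
        labels = ["T cell"] * 6 + [None] * 10 + ["B cell"] * 2
        out = majority_cluster_annotation(labels, np.zeros(18, int))
        assert out[0] == "T cell"  # 6/8 annotated = 75%

    def test_fully_unlabelled_cluster_unknown(self):
        out = majority_cluster_annotation([None] * 5, np.zeros(5, int))
        assert out[0] == "unknown"


class TestAccuracy:
    def test_synonym_pair_not_a_mismatch(self):
        acc = annotation_accuracy(
            {0: "NK cells"},
            {0: "Natural Killer cells"},
            synonyms=[("NK cells", "Natural Killer cells")],
        )
        assert acc == 100.0

    def test_identical_labelings_are_perfect(self):
        acc = annotation_accuracy({0: "A", 1: "B"}, {0: "A", 1: "B"})
        assert acc == 100.0

    def test_four_of_five_is_eighty_percent(self):
        pred = {i: "A" for i in range(5)}
        ref = {i: "A" for i in range(4)} | {4: "X"}
        assert annotation_accuracy(pred, ref) == 80.0

    def test_unknown_reference_clusters_excluded(self):
        pred = {0: "A", 1: "B"}
        ref = {0: "A", 1: "unknown"}
        assert annotation_accuracy(pred, ref) == 100.0


class TestMarkerDatabase:
    def test_builtin_has_twenty_nonempty_types(self, marker_db):
        assert len(marker_db) == 20
        assert all(len(marker_db.markers(t)) >= 8 for t in marker_db.cell_types())

    def test_empty_marker_set_rejected(self):
        with pytest.raises(ValueError):
            MarkerDatabase({"T": set()})

    def test_from_table_roundtrip(self, tmp_path, marker_db):
        p = tmp_path / "markers.tsv"
        rows = ["cell_type\tgene_symbol"]
        for t in marker_db.cell_types():
            rows += [f"{t}\t{g}" for g in sorted(marker_db.markers(t))]
        p.write_text("\n".join(rows) + "\n")
        back = MarkerDatabase.from_table(p)
        assert back.entries == marker_db.entries

    def test_without_markers_reduces_one_type(self, marker_db):
        reduced = marker_db.without_markers("T cells", 2)
        assert len(reduced.markers("T cells")) == 2
        assert reduced.markers("B cells") == marker_db.markers("B cells")
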
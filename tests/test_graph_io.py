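import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hubnet._errors import DataError
from hubnet import graph_io
from hubnet.graph_io import (
    ExpressionMatrix,
    clean_network,
    collapse_probes,
    filter_detection,
    knn_impute,
    read_edge_list,
    read_gmt,
)

from conftest import make_two_group


class TestReadEdgeList:
    def test_tsv_duplicate_collapse(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("A\tB\nB\tC\nA\tB\n")
        g = read_edge_list(p, "tsv")
        assert set(map(frozenset, g.edges)) == {frozenset("AB"), frozenset("BC")}

    def test_sif_fanout(self, tmp_path):
        p = tmp_path / "e.sif"
        p.write_text("A pp B C\n")
        g = read_edge_list(p, "sif")
        assert set(map(frozenset, g.edges)) == {frozenset("AB"), frozenset("AC")}

    def test_malformed_line_number(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("A\n")
        with pytest.raises(DataError, match="line 1"):
            read_edge_list(p, "tsv")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("")
        with pytest.raises(DataError, match="empty"):
            read_edge_list(p, "tsv")

    def test_unknown_dialect(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("A\tB\n")
        with pytest.raises(DataError):
            read_edge_list(p, "gml")

    def test_roundtrip(self, tmp_path, triangle_plus_edge):
        p = tmp_path / "e.tsv"
        graph_io.write_edge_list(triangle_plus_edge, p)
        g = read_edge_list(p, "tsv")
        assert set(map(frozenset, g.edges)) == set(
            map(frozenset, triangle_plus_edge.edges)
        )


class TestCleanNetwork:
    def test_largest_component(self, triangle_plus_edge):
        g = clean_network(triangle_plus_edge, {"A", "B", "C", "D", "E"})
        assert set(g.nodes) == {"A", "B", "C"}

    def test_self_loop_removed(self):
        g = nx.Graph([("A", "A"), ("A", "B")])
        out = clean_network(g, {"A", "B"})
        assert set(map(frozenset, out.edges)) == {frozenset("AB")}

    def test_degenerate_single_node_errors(self, triangle_plus_edge):
        with pytest.raises(DataError):
            clean_network(triangle_plus_edge, {"A"})

    def test_empty_measured_errors(self, triangle_plus_edge):
        with pytest.raises(DataError):
            clean_network(triangle_plus_edge, set())

    def test_no_overlap_errors(self, triangle_plus_edge):
        with pytest.raises(DataError, match="no measured genes"):
            clean_network(triangle_plus_edge, {"Z1", "Z2"})

    def test_tie_break_lexicographic(self):
        g = nx.Graph([("X", "Y"), ("A", "B")])
        out = clean_network(g, {"A", "B", "X", "Y"})
        assert set(out.nodes) == {"A", "B"}

    def test_idempotent(self, triangle_plus_edge):
        measured = {"A", "B", "C", "D", "E"}
        once = clean_network(triangle_plus_edge, measured)
        twice = clean_network(once, measured)
        assert set(once.nodes) == set(twice.nodes)
        assert set(map(frozenset, once.edges)) == set(map(frozenset, twice.edges))


class TestFilterDetection:
    def _calls(self, present_counts, n_samples=10):
        rows = []
        for c in present_counts:
            rows.append([1] * c + [0] * (n_samples - c))
        return pd.DataFrame(rows)

    def test_boundary_exactly_at_fraction_kept(self):
        m = make_two_group(np.zeros((3, 10)), 5, 5)
        calls = self._calls([0, 1, 10])
        calls.index = m.values.index
        calls.columns = m.values.columns
        out = filter_detection(m, calls, 0.10)
        # present in 0 -> dropped; present in exactly 10% -> kept; all -> kept
        assert out.gene_ids == ["g1", "g2"]

    def test_zero_fraction_is_identity(self, two_group_matrix):
        calls = pd.DataFrame(
            0, index=two_group_matrix.values.index,
            columns=two_group_matrix.values.columns,
        )
        out = filter_detection(two_group_matrix, calls, 0.0)
        pd.testing.assert_frame_equal(out.values, two_group_matrix.values)

    def test_shape_mismatch(self, two_group_matrix):
        with pytest.raises(DataError, match="shape"):
            filter_detection(two_group_matrix, pd.DataFrame([[1]]), 0.1)


class TestCollapseProbes:
    def test_max_variance_keeps_highest(self):
        df = pd.DataFrame(
            [[0.0, 1.0, 0.0, 1.0], [0.0, 4.0, 0.0, 4.0]],
            index=["p1", "p2"], columns=["s1", "s2", "s3", "s4"],
        )
        m = ExpressionMatrix(df)
        out = collapse_probes(m, {"p1": "G", "p2": "G"}, "max_variance")
        assert out.gene_ids == ["G"]
        assert list(out.values.loc["G"]) == [0.0, 4.0, 0.0, 4.0]

    def test_single_probe_identity(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["p1"], columns=list("abc"))
        out = collapse_probes(ExpressionMatrix(df), {"p1": "G"}, "max_variance")
        assert list(out.values.loc["G"]) == [1.0, 2.0, 3.0]

    def test_best_correlation_prefers_matching_probe(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=["s1", "s2", "s3", "s4"])
        df = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0]],
            index=["p1", "p2"], columns=scores.index,
        )
        out = collapse_probes(
            ExpressionMatrix(df), {"p1": "G", "p2": "G"},
            "best_correlation", scores=scores,
        )
        assert list(out.values.loc["G"]) == [1.0, 2.0, 3.0, 4.0]

    def test_best_correlation_requires_scores(self):
        df = pd.DataFrame([[1.0]], index=["p1"], columns=["s1"])
        with pytest.raises(DataError):
            collapse_probes(ExpressionMatrix(df), {"p1": "G"}, "best_correlation")

    def test_unmapped_probe_dropped(self):
        df = pd.DataFrame([[1.0], [2.0]], index=["p1", "px"], columns=["s1"])
        out = collapse_probes(ExpressionMatrix(df), {"p1": "G"}, "max_variance")
        assert out.gene_ids == ["G"]

    def test_unique_gene_ids(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            rng.normal(size=(6, 4)),
            index=[f"p{i}" for i in range(6)], columns=list("abcd"),
        )
        pm = {f"p{i}": f"G{i % 3}" for i in range(6)}
        out = collapse_probes(ExpressionMatrix(df), pm, "max_variance")
        assert sorted(out.gene_ids) == ["G0", "G1", "G2"]
        assert not out.values.index.has_duplicates


class TestKnnImpute:
    def test_simple_imputation(self):
        df = pd.DataFrame(
            [[1.0, 1.0, np.nan, 1.0],
             [1.0, 1.0, 1.0, 1.0],
             [1.0, 1.0, 1.0, 1.0]],
            index=["a", "b", "c"], columns=list("wxyz"),
        )
        out = knn_impute(ExpressionMatrix(df), k=2, max_missing_fraction=0.3)
        assert out.values.loc["a", "y"] == 1.0

    def test_heavy_missing_row_removed(self):
        vals = np.ones((5, 10))
        vals[0, :2] = np.nan  # 20% missing > 10%
        df = pd.DataFrame(vals, index=[f"g{i}" for i in range(5)])
        out = knn_impute(ExpressionMatrix(df), k=2)
        assert "g0" not in out.gene_ids

    def test_no_missing_identity(self, two_group_matrix):
        out = knn_impute(two_group_matrix, k=2)
        pd.testing.assert_frame_equal(out.values, two_group_matrix.values)

    def test_observed_entries_bit_identical(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(20, 10))
        mask = rng.random((20, 10)) < 0.08
        vals_missing = vals.copy()
        vals_missing[mask] = np.nan
        df = pd.DataFrame(vals_missing)
        out = knn_impute(ExpressionMatrix(df), k=3)
        kept = out.values.index
        observed = ~np.isnan(df.loc[kept].to_numpy())
        assert np.array_equal(
            out.values.to_numpy()[observed], df.loc[kept].to_numpy()[observed]
        )
        assert not np.isnan(out.values.to_numpy()).any()

    def test_k_too_large(self):
        df = pd.DataFrame([[1.0, 1.0], [np.nan, 1.0]])
        with pytest.raises(DataError, match="complete rows"):
            knn_impute(ExpressionMatrix(df), k=5, max_missing_fraction=0.6)


class TestReadGmt:
    def test_duplicates_within_set_collapse(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("S1\tdesc\tA\tB\tA\n")
        assert read_gmt(p) == {"S1": {"A", "B"}}

    def test_empty_members_error(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("S1\tdesc\t\n")
        with pytest.raises(DataError):
            read_gmt(p)

    def test_duplicate_name_error(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("S1\td\tA\nS1\td\tB\n")
        with pytest.raises(DataError, match="duplicate"):
            read_gmt(p)


class TestExpressionTsv:
    def test_roundtrip_with_missing(self, tmp_path):
        df = pd.DataFrame(
            [[1.5, np.nan], [-2.0, 3.0]], index=["g1", "g2"], columns=["s1", "s2"]
        )
        m = ExpressionMatrix(df)
        path = tmp_path / "expr.tsv"
        graph_io.write_expression_tsv(m, path)
        back = graph_io.read_expression_tsv(path)
        pd.testing.assert_frame_equal(back.values, df)

    def test_negative_as_missing_flag(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text("id\ts1\ts2\ng1\t-1.0\t2.0\n")
        m = graph_io.read_expression_tsv(path, negative_as_missing=True)
        assert np.isnan(m.values.loc["g1", "s1"])
        assert m.values.loc["g1", "s2"] == 2.0


@settings(max_examples=25, deadline=None)
@given(
    edges=st.lists(
        st.tuples(st.sampled_from("ABCDEFGH"), st.sampled_from("ABCDEFGH")),
        min_size=1, max_size=15,
    )
)
def test_clean_network_idempotent_property(edges):
    g = nx.Graph()
    g.add_edges_from(edges)
    measured = set(g.nodes)
    try:
        once = clean_network(g, measured)
    except DataError:
        return
    twice = clean_network(once, measured)
    assert nx.utils.graphs_equal(once, twice)
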
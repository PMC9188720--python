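import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scgrn.data_io import (
    ExpressionMatrix,
    GoldNetwork,
    read_edge_scores,
    read_expression,
    read_network,
    write_edge_scores,
    write_expression,
    write_network,
)


def _write_tsv(path, text):
    path.write_text(text)
    return path


class TestReadExpression:
    def test_roundtrip_preserves_values_and_order(self, tmp_path):
        path = _write_tsv(
            tmp_path / "m.tsv",
            "gene\tcA\tcB\nG1\t1\t0\nG2\t2\t3\nG3\t0\t0\n",
        )
        expr = read_expression(path)
        assert expr.gene_ids == ("G1", "G2", "G3")
        assert expr.cell_ids == ("cA", "cB")
        np.testing.assert_array_equal(expr.values, [[1, 0], [2, 3], [0, 0]])

    def test_orientation_transposes(self, tmp_path):
        path = _write_tsv(
            tmp_path / "m.tsv",
            "gene\tcA\tcB\nG1\t1\t0\nG2\t2\t3\nG3\t0\t0\n",
        )
        a = read_expression(path, "genes_by_cells")
        b = read_expression(path, "cells_by_genes")
        assert b.values.shape == (2, 3)
        np.testing.assert_array_equal(a.values, b.values.T)
        assert b.gene_ids == a.cell_ids

    def test_csv_separator_sniffed(self, tmp_path):
        path = _write_tsv(tmp_path / "m.csv", "gene,c1\nG1,1\nG2,2\n")
        assert read_expression(path).values.tolist() == [[1.0], [2.0]]

    def test_duplicate_gene_id_names_duplicate(self, tmp_path):
        path = _write_tsv(tmp_path / "m.tsv", "gene\tc1\nG1\t1\nG1\t2\n")
        with pytest.raises(ValueError, match="G1"):
            read_expression(path)

    def test_negative_entry_reports_coordinates(self, tmp_path):
        path = _write_tsv(tmp_path / "m.tsv", "gene\tc1\tc2\nG1\t1\t2\nG2\t3\t-4\n")
        with pytest.raises(ValueError, match="G2.*c2"):
            read_expression(path)

    def test_non_numeric_entry_rejected(self, tmp_path):
        path = _write_tsv(tmp_path / "m.tsv", "gene\tc1\nG1\tfoo\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_expression(path)

    def test_missing_value_rejected_not_imputed(self, tmp_path):
        path = _write_tsv(tmp_path / "m.tsv", "gene\tc1\tc2\nG1\t1\t\nG2\t3\t4\n")
        with pytest.raises(ValueError, match="missing"):
            read_expression(path)

    def test_empty_matrix_rejected(self, tmp_path):
        path = _write_tsv(tmp_path / "m.tsv", "gene\tc1\n")
        with pytest.raises(ValueError, match="empty"):
            read_expression(path)

    def test_mtx_with_sidecars(self, tmp_path):
        expr = ExpressionMatrix(("G1", "G2"), ("c1", "c2", "c3"), np.arange(6.0).reshape(2, 3))
        write_expression(expr, tmp_path / "m.mtx")
        back = read_expression(tmp_path / "m.mtx")
        assert back.gene_ids == expr.gene_ids and back.cell_ids == expr.cell_ids
        np.testing.assert_array_equal(back.values, expr.values)


class TestReadNetwork:
    def test_parse_and_tf_set(self, tmp_path):
        path = _write_tsv(tmp_path / "n.tsv", "A\tg1\nA\tg2\nB\tg1\n")
        net = read_network(path, {"A", "B", "g1", "g2"})
        assert net.edges == {("A", "g1"), ("A", "g2"), ("B", "g1")}
        assert net.tf_set == {"A", "B"}

    def test_duplicate_lines_collapse(self, tmp_path):
        path = _write_tsv(tmp_path / "n.tsv", "A\tg1\nA\tg1\n")
        assert len(read_network(path, {"A", "g1"}).edges) == 1

    def test_unknown_gene_strict_raises(self, tmp_path):
        path = _write_tsv(tmp_path / "n.tsv", "C\tg1\n")
        with pytest.raises(ValueError, match="'C'"):
            read_network(path, {"A", "g1"})

    def test_unknown_gene_permissive_drops_with_warning(self, tmp_path):
        path = _write_tsv(tmp_path / "n.tsv", "C\tg1\nA\tg1\n")
        with pytest.warns(UserWarning, match="dropping edge"):
            net = read_network(path, {"A", "g1"}, strict=False)
        assert net.edges == {("A", "g1")}

    def test_empty_file_gives_empty_network(self, tmp_path):
        path = _write_tsv(tmp_path / "n.tsv", "")
        net = read_network(path, {"A"})
        assert net.edges == frozenset() and net.tf_set == frozenset()

    def test_network_roundtrip(self, tmp_path):
        net = GoldNetwork(frozenset({("A", "g1"), ("B", "g2")}), frozenset("ABg1g2".split()) | {"A", "B", "g1", "g2"})
        write_network(net, tmp_path / "n.tsv")
        assert read_network(tmp_path / "n.tsv", net.gene_universe).edges == net.edges


class TestEdgeScores:
    def test_sorted_by_score_descending(self, tmp_path):
        table = pd.DataFrame(
            {"tf": ["A", "A"], "target": ["g1", "g2"], "score": [0.2, 0.9], "label": [1, -1]}
        )
        write_edge_scores(table, tmp_path / "e.tsv")
        lines = (tmp_path / "e.tsv").read_text().splitlines()
        assert lines[0] == "tf\ttarget\tscore\tlabel"
        assert lines[1].startswith("A\tg2\t0.900000")
        assert lines[2].startswith("A\tg1\t0.200000")

    def test_tie_break_is_lexicographic(self, tmp_path):
        table = pd.DataFrame(
            {"tf": ["B", "A", "A"], "target": ["g1", "g2", "g1"], "score": [0.5, 0.5, 0.5]}
        )
        write_edge_scores(table, tmp_path / "e.tsv")
        rows = [l.split("\t")[:2] for l in (tmp_path / "e.tsv").read_text().splitlines()[1:]]
        assert rows == [["A", "g1"], ["A", "g2"], ["B", "g1"]]

    def test_empty_table_header_only(self, tmp_path):
        table = pd.DataFrame({"tf": [], "target": [], "score": []})
        write_edge_scores(table, tmp_path / "e.tsv")
        assert (tmp_path / "e.tsv").read_text().strip() == "tf\ttarget\tscore"

    def test_random_table_roundtrip_to_6dp(self, tmp_path):
        rng = np.random.default_rng(42)
        table = pd.DataFrame(
            {
                "tf": [f"T{i % 7}" for i in range(100)],
                "target": [f"g{i}" for i in range(100)],
                "score": rng.random(100),
                "label": rng.choice([-1, 1], 100),
                "fold": rng.integers(0, 5, 100),
            }
        )
        write_edge_scores(table, tmp_path / "e.tsv")
        back = read_edge_scores(tmp_path / "e.tsv")
        merged = table.merge(back, on=["tf", "target"], suffixes=("", "_rt"))
        assert len(merged) == 100
        assert (merged["label"] == merged["label_rt"]).all()
        np.testing.assert_allclose(merged["score"], merged["score_rt"], atol=5e-7)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    scores=st.lists(st.floats(0, 1, allow_nan=False, width=32), min_size=1, max_size=30),
    labels_seed=st.integers(0, 10_000),
)
def test_edge_table_roundtrip_property(tmp_path_factory, scores, labels_seed):
    """Any valid table survives write/read with scores equal to 6 decimals."""
    rng = np.random.default_rng(labels_seed)
    n = len(scores)
    table = pd.DataFrame(
        {
            "tf": ["T"] * n,
            "target": [f"g{i}" for i in range(n)],
            "score": np.asarray(scores, dtype=float),
            "label": rng.choice([-1, 1], n),
        }
    )
    path = tmp_path_factory.mktemp("rt") / "e.tsv"
    write_edge_scores(table, path)
    back = read_edge_scores(path).sort_values("target").reset_index(drop=True)
    orig = table.sort_values("target").reset_index(drop=True)
    assert list(back["target"]) == list(orig["target"])
    np.testing.assert_allclose(back["score"], orig["score"], atol=5e-7)
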
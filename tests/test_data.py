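"""Dataset loading/validation, level coding, constraints, and graph I/O."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mixdag as m
from mixdag.data import _pair


CSV = "g1,g2,status\n0.5,1.2,case\n-0.3,0.8,control\n1.1,-0.4,case\n0.0,2.2,control\n"
TYPES = {"g1": "continuous", "g2": "continuous", "status": "categorical"}


def test_load_small_csv(tmp_path):
    f = tmp_path / "t.csv"
    f.write_text(CSV)
    data = m.load_mixed_dataset(f, TYPES)
    assert (data.n, data.d, data.p, data.q) == (4, 3, 2, 1)
    assert data.n_levels("status") == 2
    # first-appearance coding: case=1, control=2
    assert data.levels["status"] == ["case", "control"]
    assert data.codes("status").tolist() == [1, 2, 1, 2]


def test_four_level_column_codes():
    df = pd.DataFrame({"x": np.linspace(0, 1, 8),
                       "c": list("bacdabcd")})
    data = m.MixedDataset.from_dataframe(
        df, {"x": "continuous", "c": "categorical"})
    assert data.n_levels("c") == 4
    assert sorted(np.unique(data.codes("c"))) == [1, 2, 3, 4]
    assert data.levels["c"] == ["b", "a", "c", "d"]  # appearance order


def test_missing_cell_error_names_position(tmp_path):
    f = tmp_path / "t.csv"
    f.write_text("a,b\n1.0,2.0\n,3.0\n4.0,5.0\n")
    with pytest.raises(m.DataError, match="row 2.*'a'"):
        m.load_mixed_dataset(f, {"a": "continuous", "b": "continuous"})


def test_undeclared_and_constant_column_errors(tmp_path):
    f = tmp_path / "t.csv"
    f.write_text("a,b\n1.0,2.0\n1.0,3.0\n")
    with pytest.raises(m.DataError, match="undeclared"):
        m.load_mixed_dataset(f, {"a": "continuous"})
    with pytest.raises(m.DataError, match="'a' is constant"):
        m.load_mixed_dataset(f, {"a": "continuous", "b": "continuous"})


def test_dataset_roundtrip_identity(tmp_path):
    f = tmp_path / "t.csv"
    f.write_text(CSV)
    data = m.load_mixed_dataset(f, TYPES)
    out = tmp_path / "out.tsv"
    m.write_mixed_dataset(data, out)
    again = m.load_mixed_dataset(out, TYPES)
    np.testing.assert_array_equal(data.values, again.values)
    assert data.node_types == again.node_types
    assert data.levels == again.levels


def test_parse_types_string_and_file(tmp_path):
    assert m.parse_types("a:continuous, b:categorical") == {
        "a": "continuous", "b": "categorical"}
    f = tmp_path / "types.yaml"
    f.write_text("a: continuous\nb: categorical\n")
    assert m.parse_types(f) == {"a": "continuous", "b": "categorical"}


def test_as_mixed_dataset_dtype_inference():
    df = pd.DataFrame({
        "x": np.random.default_rng(0).normal(size=10),
        "c": pd.Categorical(["u", "v"] * 5),
    })
    data = m.as_mixed_dataset(df)
    assert data.type_of("x") == "continuous"
    assert data.type_of("c") == "categorical"
    arr = np.random.default_rng(1).normal(size=(6, 2))
    data2 = m.as_mixed_dataset(arr)
    assert data2.node_names == ["X1", "X2"]
    assert all(t == "continuous" for t in data2.node_types)


# -- graphs -----------------------------------------------------------------

def test_directed_graph_rejects_cycles_and_self_loops():
    with pytest.raises(m.DataError, match="cycle"):
        m.DirectedGraph(["a", "b"], [("a", "b"), ("b", "a")])
    with pytest.raises(m.DataError, match="self-loop"):
        m.DirectedGraph(["a"], [("a", "a")])
    # undetermined mark suspends the acyclicity requirement
    g = m.DirectedGraph(["a", "b", "c"], [("a", "b")], [("b", "c")])
    assert g.skeleton().edges == {("a", "b"), ("b", "c")}


def test_write_graph_formats(tmp_path):
    empty = m.UndirectedGraph(["A", "B"])
    f = tmp_path / "g.tsv"
    m.write_graph(empty, f)
    assert f.read_text() == "source\ttarget\tkind\n"
    one = m.DirectedGraph(["A", "B"], [("A", "B")])
    m.write_graph(one, f)
    assert f.read_text() == "source\ttarget\tkind\nA\tB\tdirected\n"
    dot = tmp_path / "g.dot"
    m.write_graph(one, dot, format="dot")
    assert '"A" -> "B";' in dot.read_text()


def test_graph_roundtrip_10_edges(tmp_path):
    rng = np.random.default_rng(3)
    nodes = [f"n{i}" for i in range(8)]
    edges = set()
    while len(edges) < 10:
        i, j = rng.choice(8, 2, replace=False)
        if i < j:
            edges.add((nodes[i], nodes[j]))
    g = m.DirectedGraph(nodes, edges)
    f = tmp_path / "g.tsv"
    m.write_graph(g, f)
    back = m.read_graph(f, nodes=nodes)
    assert back.directed_edges == g.directed_edges


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.sets(st.tuples(st.integers(0, 6), st.integers(0, 6)).filter(
    lambda t: t[0] != t[1]), max_size=12))
def test_graph_roundtrip_property(tmp_path_factory, pairs):
    nodes = [f"v{i}" for i in range(7)]
    und = {_pair(nodes[a], nodes[b]) for a, b in pairs}
    g = m.UndirectedGraph(nodes, und)
    f = tmp_path_factory.mktemp("g") / "g.tsv"
    m.write_graph(g, f)
    back = m.read_graph(f, nodes=nodes, directed=False)
    assert back.edges == g.edges


def test_constraints_validation_and_allows():
    c = m.DirectionConstraints(source_only={"snp"}, forbidden={("a", "b")})
    c.validate(["snp", "a", "b"])
    assert not c.allows("a", "snp")   # nothing points into a source
    assert not c.allows("a", "b")     # forbidden pair
    assert c.allows("snp", "a")
    with pytest.raises(m.DataError, match="not in dataset"):
        c.validate(["a", "b"])


def test_load_constraints_yaml(tmp_path):
    f = tmp_path / "c.yaml"
    f.write_text("source_only: [snp]\nforbidden: [[a, b]]\n")
    c = m.load_constraints(f)
    assert c.source_only == {"snp"}
    assert c.forbidden == {("a", "b")}
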
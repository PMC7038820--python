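"""Containers and I/O for mixed-type tabular data and graphs.

A *mixed dataset* is an n x d table in which every column is declared either
continuous (real-valued) or categorical (a finite, unordered set of levels).
Categorical columns are stored internally as integer level codes 1..L_j, with
the label <-> code mapping retained, so that downstream regressions can build
reference-coded indicator columns deterministically.
"""
from __future__ import annotations

import dataclasses
import pathlib
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"
_TYPES = (CONTINUOUS, CATEGORICAL)


class DataError(ValueError):
    """Raised when an input table violates the mixed-dataset contract."""


def _pair(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) form of an unordered node pair."""
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# MixedDataset
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MixedDataset:
    """n x d value table with per-column type metadata.

    Parameters
    ----------
    values : ndarray of shape (n, d)
        Float matrix; categorical columns hold integer level codes ``1..L_j``.
    node_names : list of str
        Column labels; the unit of identity throughout the package.
    node_types : list of str
        ``"continuous"`` or ``"categorical"`` per column.
    levels : dict
        For each categorical column, the ordered list of level labels;
        code ``k`` corresponds to ``levels[name][k - 1]``.
    """

    values: np.ndarray
    node_names: list[str]
    node_types: list[str]
    levels: dict[str, list[str]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.node_names = list(self.node_names)
        self.node_types = list(self.node_types)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D table")
        n, d = self.values.shape
        if d != len(self.node_names) or d != len(self.node_types):
            raise DataError("node_names/node_types length mismatch with values")
        if len(set(self.node_names)) != d:
            raise DataError("duplicate column names")
        if n < 2:
            raise DataError(f"need at least 2 samples, got {n}")
        for t in self.node_types:
            if t not in _TYPES:
                raise DataError(f"unknown node type {t!r}")
        bad = np.argwhere(~np.isfinite(self.values))
        if bad.size:
            i, j = bad[0]
            raise DataError(
                f"missing/non-finite value at row {i + 1}, column "
                f"{self.node_names[j]!r}"
            )
        self._index = {name: k for k, name in enumerate(self.node_names)}
        for name, t in zip(self.node_names, self.node_types):
            col = self.values[:, self._index[name]]
            if t == CONTINUOUS:
                if np.ptp(col) == 0.0:
                    raise DataError(f"continuous column {name!r} is constant")
            else:
                if name not in self.levels:
                    raise DataError(f"no levels declared for {name!r}")
                L = len(self.levels[name])
                if L < 2:
                    raise DataError(f"categorical column {name!r} has L < 2")
                codes = col.astype(int)
                if not np.array_equal(codes, col):
                    raise DataError(f"non-integer level code in {name!r}")
                if codes.min() < 1 or codes.max() > L:
                    raise DataError(f"level code out of range in {name!r}")
                if np.unique(codes).size < 2:
                    raise DataError(
                        f"categorical column {name!r} has fewer than 2 "
                        "observed levels"
                    )

    # -- basic accessors ----------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def p(self) -> int:
        """Number of continuous columns."""
        return sum(t == CONTINUOUS for t in self.node_types)

    @property
    def q(self) -> int:
        """Number of categorical columns."""
        return self.d - self.p

    def index(self, name: str) -> int:
        return self._index[name]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self._index[name]]

    def codes(self, name: str) -> np.ndarray:
        """Integer level codes 1..L for a categorical column."""
        if not self.is_categorical(name):
            raise DataError(f"{name!r} is not categorical")
        return self.column(name).astype(int)

    def is_categorical(self, name: str) -> bool:
        return self.node_types[self._index[name]] == CATEGORICAL

    def n_levels(self, name: str) -> int:
        return len(self.levels[name])

    def type_of(self, name: str) -> str:
        return self.node_types[self._index[name]]

    def types_dict(self) -> dict[str, str]:
        return dict(zip(self.node_names, self.node_types))

    # -- converters ---------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, types: Mapping[str, str]) -> "MixedDataset":
        """Build a dataset from a DataFrame plus a column-type declaration.

        Categorical labels are coded 1..L in first-appearance order; labels
        are compared as exact strings.
        """
        undeclared = [c for c in df.columns if c not in types]
        if undeclared:
            raise DataError(f"undeclared column(s): {undeclared}")
        unknown = [c for c in types if c not in df.columns]
        if unknown:
            raise DataError(f"declared column(s) not in table: {unknown}")
        values = np.empty(df.shape, dtype=float)
        levels: dict[str, list[str]] = {}
        names = list(df.columns)
        ntypes = []
        for j, name in enumerate(names):
            t = types[name]
            if t not in _TYPES:
                raise DataError(f"unknown type {t!r} for column {name!r}")
            ntypes.append(t)
            col = df[name]
            na = col.isna()
            if na.any():
                raise DataError(
                    f"missing value at row {int(np.argmax(na.to_numpy())) + 1},"
                    f" column {name!r}"
                )
            if t == CONTINUOUS:
                try:
                    values[:, j] = pd.to_numeric(col).to_numpy(dtype=float)
                except (ValueError, TypeError) as exc:
                    raise DataError(
                        f"non-numeric value in continuous column {name!r}"
                    ) from exc
            else:
                labels = col.astype(str).to_numpy()
                order = list(dict.fromkeys(labels))  # first-appearance order
                code = {lab: k + 1 for k, lab in enumerate(order)}
                values[:, j] = [code[lab] for lab in labels]
                levels[name] = order
        return cls(values, names, ntypes, levels)

    def to_dataframe(self) -> pd.DataFrame:
        """Restore a DataFrame with categorical codes decoded to labels."""
        cols = {}
        for name, t in zip(self.node_names, self.node_types):
            if t == CONTINUOUS:
                cols[name] = self.column(name)
            else:
                labs = self.levels[name]
                cols[name] = [labs[c - 1] for c in self.codes(name)]
        return pd.DataFrame(cols, columns=self.node_names)

    def subset_rows(self, idx: np.ndarray) -> "MixedDataset":
        return MixedDataset(
            self.values[idx], self.node_names, self.node_types, dict(self.levels)
        )


def coerce_to_continuous(data: MixedDataset) -> MixedDataset:
    """Re-declare every column continuous (level codes become plain numbers).

    This mimics structure-learning methods that cannot distinguish variable
    types and treat categorical codes as measurements.
    """
    return MixedDataset(
        data.values.copy(), data.node_names, [CONTINUOUS] * data.d, {}
    )


# ---------------------------------------------------------------------------
# type declarations & constraints
# ---------------------------------------------------------------------------

def parse_types(spec) -> dict[str, str]:
    """Normalize a type declaration.

    Accepts a mapping, a ``"name:continuous,name2:categorical"`` string, or a
    path to a YAML/JSON file with a flat ``{name: type}`` mapping.
    """
    if isinstance(spec, Mapping):
        return {str(k): str(v) for k, v in spec.items()}
    if isinstance(spec, (str, pathlib.Path)):
        s = str(spec)
        if ":" in s and not pathlib.Path(s).exists():
            out = {}
            for item in s.split(","):
                name, _, t = item.strip().partition(":")
                out[name.strip()] = t.strip()
            return out
        with open(s) as fh:
            loaded = yaml.safe_load(fh)
        if not isinstance(loaded, Mapping):
            raise DataError("type file must contain a name -> type mapping")
        return {str(k): str(v) for k, v in loaded.items()}
    raise DataError(f"cannot interpret type declaration {spec!r}")


def load_mixed_dataset(path, types) -> MixedDataset:
    """Read a delimited text table (CSV, or TSV for ``.tsv``) into a dataset."""
    path = pathlib.Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=False)
    return MixedDataset.from_dataframe(df, parse_types(types))


def write_mixed_dataset(data: MixedDataset, path) -> None:
    path = pathlib.Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    data.to_dataframe().to_csv(path, sep=sep, index=False)


@dataclasses.dataclass(frozen=True)
class DirectionConstraints:
    """Prior direction knowledge for orientation.

    ``source_only`` nodes (e.g. SNPs, which cannot be caused by expression or
    phenotype) may only emit edges; ``forbidden`` ordered pairs (i, j) mean
    the directed edge i -> j may never appear.
    """

    source_only: frozenset = frozenset()
    forbidden: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "source_only", frozenset(self.source_only))
        object.__setattr__(
            self, "forbidden", frozenset(tuple(p) for p in self.forbidden)
        )
        for u, v in self.forbidden:
            if u == v:
                raise DataError(f"forbidden self-pair {u!r}")

    def validate(self, nodes: Iterable[str]) -> None:
        known = set(nodes)
        missing = (self.source_only | {x for p in self.forbidden for x in p}) - known
        if missing:
            raise DataError(f"constraint names not in dataset: {sorted(missing)}")

    def allows(self, u: str, v: str) -> bool:
        """May a directed edge u -> v exist?"""
        return v not in self.source_only and (u, v) not in self.forbidden


def load_constraints(spec) -> DirectionConstraints:
    if isinstance(spec, DirectionConstraints):
        return spec
    if spec is None:
        return DirectionConstraints()
    if isinstance(spec, Mapping):
        d = spec
    else:
        with open(spec) as fh:
            d = yaml.safe_load(fh) or {}
    return DirectionConstraints(
        source_only=frozenset(d.get("source_only", ())),
        forbidden=frozenset(tuple(p) for p in d.get("forbidden", ())),
    )


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------

class UndirectedGraph:
    """Simple undirected graph over named nodes (no self-loops)."""

    __slots__ = ("nodes", "edges")

    def __init__(self, nodes: Sequence[str], edges: Iterable[tuple[str, str]] = ()):
        self.nodes = list(nodes)
        known = set(self.nodes)
        self.edges: set[tuple[str, str]] = set()
        for a, b in edges:
            if a == b:
                raise DataError(f"self-loop on {a!r}")
            if a not in known or b not in known:
                raise DataError(f"edge endpoint not a node: {(a, b)}")
            self.edges.add(_pair(a, b))

    def has_edge(self, a: str, b: str) -> bool:
        return _pair(a, b) in self.edges

    def neighbors(self, v: str) -> list[str]:
        return sorted(
            (b if a == v else a) for a, b in self.edges if v in (a, b)
        )

    def remove_edge(self, a: str, b: str) -> None:
        self.edges.discard(_pair(a, b))

    def copy(self) -> "UndirectedGraph":
        return UndirectedGraph(self.nodes, self.edges)

    def __len__(self) -> int:
        return len(self.edges)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, UndirectedGraph)
            and set(self.nodes) == set(other.nodes)
            and self.edges == other.edges
        )

    def __repr__(self) -> str:
        return f"UndirectedGraph({len(self.nodes)} nodes, {len(self.edges)} edges)"


class DirectedGraph:
    """Directed graph; may carry undetermined (unordered) edge marks.

    The output of the full pipeline has ``undetermined_edges == set()`` and is
    acyclic; nonempty undetermined sets arise only when representing a
    partially directed graph produced by another method for evaluation.
    """

    __slots__ = ("nodes", "directed_edges", "undetermined_edges")

    def __init__(
        self,
        nodes: Sequence[str],
        directed_edges: Iterable[tuple[str, str]] = (),
        undetermined_edges: Iterable[tuple[str, str]] = (),
    ):
        self.nodes = list(nodes)
        known = set(self.nodes)
        self.directed_edges = {tuple(e) for e in directed_edges}
        self.undetermined_edges = {_pair(*e) for e in undetermined_edges}
        for u, v in self.directed_edges | self.undetermined_edges:
            if u == v:
                raise DataError(f"self-loop on {u!r}")
            if u not in known or v not in known:
                raise DataError(f"edge endpoint not a node: {(u, v)}")
        overlap = {
            _pair(u, v) for u, v in self.directed_edges
        } & self.undetermined_edges
        if overlap:
            raise DataError(f"pair both directed and undetermined: {overlap}")
        if not self.undetermined_edges and not self.is_acyclic():
            raise DataError("directed graph contains a cycle")

    def is_acyclic(self) -> bool:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed_edges)
        return nx.is_directed_acyclic_graph(g)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed_edges)
        return g

    def topological_order(self) -> list[str]:
        if self.undetermined_edges:
            raise DataError("topological order undefined with undetermined edges")
        return list(nx.topological_sort(self.to_networkx()))

    def parents(self, v: str) -> list[str]:
        return sorted(u for u, w in self.directed_edges if w == v)

    def skeleton(self) -> UndirectedGraph:
        pairs = {_pair(u, v) for u, v in self.directed_edges}
        return UndirectedGraph(self.nodes, pairs | self.undetermined_edges)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DirectedGraph)
            and set(self.nodes) == set(other.nodes)
            and self.directed_edges == other.directed_edges
            and self.undetermined_edges == other.undetermined_edges
        )

    def __repr__(self) -> str:
        und = f", {len(self.undetermined_edges)} undetermined" if self.undetermined_edges else ""
        return (
            f"DirectedGraph({len(self.nodes)} nodes, "
            f"{len(self.directed_edges)} directed{und})"
        )


_HEADER = "source\ttarget\tkind"


def write_graph(g, path, format: str = "edgelist") -> None:
    """Serialize a graph as a sorted TSV edge list or as DOT text."""
    rows: list[tuple[str, str, str]] = []
    if isinstance(g, UndirectedGraph):
        rows = [(a, b, "undirected") for a, b in g.edges]
    elif isinstance(g, DirectedGraph):
        rows = [(u, v, "directed") for u, v in g.directed_edges]
        rows += [(a, b, "undirected") for a, b in g.undetermined_edges]
    else:
        raise DataError(f"cannot write object of type {type(g).__name__}")
    rows.sort()
    path = pathlib.Path(path)
    if format == "edgelist":
        with open(path, "w") as fh:
            fh.write(_HEADER + "\n")
            for r in rows:
                fh.write("\t".join(r) + "\n")
    elif format == "dot":
        with open(path, "w") as fh:
            fh.write("digraph G {\n")
            for v in sorted(g.nodes):
                fh.write(f'  "{v}";\n')
            for u, v, kind in rows:
                attr = "" if kind == "directed" else " [dir=none]"
                fh.write(f'  "{u}" -> "{v}"{attr};\n')
            fh.write("}\n")
    else:
        raise DataError(f"unknown graph format {format!r}")


def read_graph(path, nodes: Sequence[str] | None = None, directed: bool | None = None):
    """Read an edge-list TSV written by :func:`write_graph`."""
    rows = []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != _HEADER:
            raise DataError(f"unexpected edge-list header {header!r}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3 or parts[2] not in {"directed", "undirected"}:
                raise DataError(f"malformed edge-list line {line!r}")
            rows.append(tuple(parts))
    seen = sorted({x for r in rows for x in r[:2]})
    nodes = list(nodes) if nodes is not None else seen
    dir_edges = [(u, v) for u, v, k in rows if k == "directed"]
    und_edges = [(u, v) for u, v, k in rows if k == "undirected"]
    if directed is None:
        directed = bool(dir_edges)
    if directed:
        return DirectedGraph(nodes, dir_edges, und_edges)
    if dir_edges:
        raise DataError("directed edges present in an undirected read")
    return UndirectedGraph(nodes, und_edges)


def as_mixed_dataset(X, types=None) -> MixedDataset:
    """Coerce estimator input to a :class:`MixedDataset`.

    Accepts a MixedDataset (returned as-is), a pandas DataFrame (column dtypes
    decide the types unless ``types`` is given: category/object/bool columns
    are categorical), or a plain array (all columns continuous, named X1..Xd).
    """
    if isinstance(X, MixedDataset):
        return X
    if isinstance(X, pd.DataFrame):
        if types is None:
            types = {
                c: CATEGORICAL
                if (
                    isinstance(X[c].dtype, pd.CategoricalDtype)
                    or X[c].dtype == object
                    or X[c].dtype == bool
                )
                else CONTINUOUS
                for c in X.columns
            }
        return MixedDataset.from_dataframe(X, parse_types(types))
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise DataError("expected a 2-D array")
    names = [f"X{j + 1}" for j in range(arr.shape[1])]
    if types is None:
        types = {c: CONTINUOUS for c in names}
    df = pd.DataFrame(arr, columns=names)
    t = parse_types(types)
    for c in names:
        if t.get(c) == CATEGORICAL:
            df[c] = df[c].astype(int).astype(str)
    return MixedDataset.from_dataframe(df, t)
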
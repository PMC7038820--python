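"""Random DAGs and mixed data from the structural-equation sampler.

The generative model draws a uniformly random topological order over d
nodes, samples a fixed number of distinct order-respecting edges uniformly,
marks a random subset of nodes categorical (L levels each, unordered), and
then samples in topological order:

* parentless continuous node:   X_i ~ Normal(0, 1)
* parentless categorical node:  X_i ~ Uniform{1, ..., L}
* continuous with parents:      X_i ~ Normal(sum_{j in pa(i)} X_j, 1)
* categorical with parents:     X_i ~ Multinomial(1, p) with
    p_l proportional to exp(l * sum_{j in pa(i)} X_j),  l = 1..L,
  computed with log-sum-exp stabilization.

Categorical parents contribute their integer level codes 1..L to children's
linear sums; this imposes an artificial ordering on nominally unordered
levels, and is exactly how the data model defines the mechanism. Each node
draws from its own RNG substream keyed by node index, so adding nodes never
shifts the draws of earlier nodes.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import logsumexp

from .data import CATEGORICAL, CONTINUOUS, DirectedGraph, MixedDataset


def node_names(d: int) -> list[str]:
    """Zero-padded labels X01..Xd so lexicographic order equals index order."""
    w = len(str(d))
    return [f"X{i:0{w}d}" for i in range(1, d + 1)]


@dataclasses.dataclass
class DatasetSchema:
    """Node-type assignment produced before any data are drawn."""

    node_names: list[str]
    node_types: list[str]  # continuous | categorical per node
    n_levels: int

    @property
    def categorical_nodes(self) -> list[str]:
        return [v for v, t in zip(self.node_names, self.node_types)
                if t == CATEGORICAL]


@dataclasses.dataclass
class ScenarioConfig:
    """One simulation scenario (sample size, graph size, mixing, levels)."""

    n: int
    d: int
    n_edges: int
    frac_categorical: float
    n_levels: int = 4
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.frac_categorical <= 1.0:
            raise ValueError("frac_categorical must lie in [0, 1]")
        if self.n_edges > self.d * (self.d - 1) // 2 or self.n_edges < 0:
            raise ValueError("infeasible edge count")
        if self.n_levels < 2:
            raise ValueError("need at least 2 levels")


# The varied factors each take two settings (n: 100/1000, d: 100/500,
# edges: 100/500, categorical fraction: 10%/20%); the eight presets are the
# even-parity half fraction of the full 2^4 grid, which contains both the
# all-low and all-high corners.
SCENARIOS: dict[str, ScenarioConfig] = {
    "s1": ScenarioConfig(n=100, d=100, n_edges=100, frac_categorical=0.10),
    "s2": ScenarioConfig(n=100, d=100, n_edges=500, frac_categorical=0.20),
    "s3": ScenarioConfig(n=100, d=500, n_edges=100, frac_categorical=0.20),
    "s4": ScenarioConfig(n=100, d=500, n_edges=500, frac_categorical=0.10),
    "s5": ScenarioConfig(n=1000, d=100, n_edges=100, frac_categorical=0.20),
    "s6": ScenarioConfig(n=1000, d=100, n_edges=500, frac_categorical=0.10),
    "s7": ScenarioConfig(n=1000, d=500, n_edges=100, frac_categorical=0.10),
    "s8": ScenarioConfig(n=1000, d=500, n_edges=500, frac_categorical=0.20),
}


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_random_dag(d: int, n_edges: int, seed=0) -> DirectedGraph:
    """Uniform random DAG: random topological order, then uniform edges.

    Samples ``n_edges`` distinct ordered pairs respecting a uniformly drawn
    topological order, without replacement; the result is acyclic by
    construction with exactly ``n_edges`` edges.
    """
    max_edges = d * (d - 1) // 2
    if not 0 <= n_edges <= max_edges:
        raise ValueError(f"n_edges must lie in [0, {max_edges}]")
    rng = _as_rng(seed)
    names = node_names(d)
    order = rng.permutation(d)
    chosen = rng.choice(max_edges, size=n_edges, replace=False)
    # decode triangular index t -> (a, b), 0 <= a < b < d
    edges = []
    for t in np.sort(chosen):
        t = int(t)
        b = int((1 + np.sqrt(1 + 8 * t)) // 2)
        while b * (b - 1) // 2 > t:  # guard float rounding at square 1+8t
            b -= 1
        while (b + 1) * b // 2 <= t:
            b += 1
        a = t - b * (b - 1) // 2
        edges.append((names[order[a]], names[order[b]]))
    return DirectedGraph(names, edges)


def assign_node_types(
    g: DirectedGraph, frac_categorical: float, n_levels: int = 4, seed=0
) -> DatasetSchema:
    """Mark a uniformly random subset of nodes categorical.

    The categorical count is frac * d rounded half up.
    """
    if not 0.0 <= frac_categorical <= 1.0:
        raise ValueError("frac_categorical must lie in [0, 1]")
    rng = _as_rng(seed)
    names = list(g.nodes)
    d = len(names)
    n_cat = int(np.floor(frac_categorical * d + 0.5))
    cat = set(rng.choice(d, size=n_cat, replace=False).tolist())
    types = [CATEGORICAL if i in cat else CONTINUOUS for i in range(d)]
    return DatasetSchema(names, types, n_levels)


def categorical_probs(parent_sum: np.ndarray, L: int) -> np.ndarray:
    """Level probabilities p_l proportional to exp(l * parent_sum), stabilized."""
    ell = np.arange(1, L + 1)
    logits = np.outer(np.asarray(parent_sum, float), ell)
    return np.exp(logits - logsumexp(logits, axis=1, keepdims=True))


def simulate_data(g: DirectedGraph, schema: DatasetSchema, n: int, seed=0
                  ) -> MixedDataset:
    """Draw n samples from the structural-equation model on DAG g."""
    names = list(g.nodes)
    idx = {v: i for i, v in enumerate(names)}
    types = dict(zip(schema.node_names, schema.node_types))
    L = schema.n_levels
    base = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    values = np.empty((n, len(names)))
    parents = {v: g.parents(v) for v in names}
    for v in g.topological_order():
        i = idx[v]
        rng = np.random.default_rng(
            np.random.SeedSequence(
                entropy=base.entropy, spawn_key=tuple(base.spawn_key) + (i,)
            )
        )
        pa = parents[v]
        s = values[:, [idx[u] for u in pa]].sum(axis=1) if pa else None
        if types[v] == CONTINUOUS:
            mean = s if s is not None else 0.0
            values[:, i] = rng.normal(mean, 1.0, size=n)
        else:
            if s is None:
                values[:, i] = rng.integers(1, L + 1, size=n)
            else:
                P = categorical_probs(s, L)
                u = rng.random(n)
                values[:, i] = 1 + (u[:, None] >= np.cumsum(P, axis=1)).sum(axis=1)
    levels = {
        v: [str(k) for k in range(1, L + 1)]
        for v, t in types.items() if t == CATEGORICAL
    }
    return MixedDataset(values, names, list(types[v] for v in names), levels)


def simulate_scenario(cfg: ScenarioConfig) -> tuple[DirectedGraph, MixedDataset]:
    """Generate the ground-truth DAG and one dataset for a scenario.

    Graph, type assignment, and data draw from three substreams of the
    scenario seed, so each stage is individually reproducible.
    """
    ss = np.random.SeedSequence(cfg.seed)
    s_graph, s_types, s_data = ss.spawn(3)
    g = generate_random_dag(cfg.d, cfg.n_edges, np.random.default_rng(s_graph))
    schema = assign_node_types(
        g, cfg.frac_categorical, cfg.n_levels, np.random.default_rng(s_types)
    )
    data = simulate_data(g, schema, cfg.n, s_data)
    return g, data
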
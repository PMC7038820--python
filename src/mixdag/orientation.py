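"""Orient the skeleton into a DAG by greedy BIC hill climbing.

Every node j is scored by the BIC of the unpenalized GLM regressing it on
its current parent set,

    BIC(j) = -2 loglik_j + ||beta_j||_0 log n,

with ||beta_j||_0 counting non-intercept coefficients (indicator columns
individually; multinomial across level blocks; the gaussian variance is not
counted). The overall score is the sum over nodes — it decomposes, so a move
touching edge (j, k) only rescores j and/or k.

Search starts from the empty graph and repeatedly applies the single legal
move (add, delete, or reverse, restricted to skeleton pairs) with the
largest BIC decrease, rejecting moves that create a cycle or violate
direction constraints, until no move strictly decreases the score. The
result is a fully directed acyclic graph.
"""
from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np

from . import _glm
from .data import (DirectedGraph, DirectionConstraints, MixedDataset,
                   UndirectedGraph, _pair)
from .skeleton import SkeletonWithSepsets

_MOVE_RANK = {"add": 0, "delete": 1, "reverse": 2}
_EPS = 1e-9  # minimum decrease counted as an improvement
_TIE_TOL = 1e-6  # relative width within which move scores count as tied


@dataclasses.dataclass
class ScoredDag:
    """Hill-climbing result: DAG, per-node BIC scores, and the move trace."""

    graph: DirectedGraph
    node_scores: dict[str, float]
    overall: float
    move_trace: list[tuple[str, tuple[str, str], float]]


def node_bic(
    data: MixedDataset,
    node: str,
    parents,
    cache: dict | None = None,
) -> float:
    """BIC of the unpenalized GLM of ``node`` on ``parents``.

    Collinear design columns are dropped (and not counted in the penalty);
    a separated multinomial fit falls back to a ridge-stabilized fit with
    penalty 1e-6.
    """
    parents = frozenset(parents)
    if node in parents:
        raise ValueError(f"{node!r} cannot be its own parent")
    if cache is not None and (node, parents) in cache:
        return cache[(node, parents)]
    n = data.n
    X, _, _, _, _ = _glm.design_matrix(data, sorted(parents), standardize=False)
    keep = _glm.drop_collinear(X)
    Xk = X[:, keep]

    if data.is_categorical(node):
        codes = data.codes(node)
        L = data.n_levels(node)
        if Xk.shape[1] == 0:
            _, loglik = _glm.multinomial_intercept_mle(codes, L)
        else:
            W, loglik = _glm.fit_multinomial(Xk, codes, L, l1=0.0)
            if _glm.separation_suspected(W):
                warnings.warn(
                    f"separation fitting {node!r} on {sorted(parents)}; "
                    "ridge-stabilized refit",
                    RuntimeWarning,
                )
                W, _ = _glm.fit_multinomial(Xk, codes, L, l1=0.0, ridge=1e-6)
                X1 = np.column_stack([np.ones(n), Xk])
                Y = _glm.one_hot(codes, L)
                loglik = _glm.multinomial_loglik(X1, Y, W)
        k = (L - 1) * Xk.shape[1]
    else:
        y = data.column(node)
        if Xk.shape[1] == 0:
            rss = float(np.sum((y - y.mean()) ** 2))
        else:
            _, _, fitted, _ = _glm.lstsq_fit(Xk, y)
            rss = float(np.sum((y - fitted) ** 2))
        loglik = _glm.gaussian_loglik(rss, n)
        k = Xk.shape[1]

    bic = -2.0 * loglik + k * np.log(n)
    if cache is not None:
        cache[(node, parents)] = bic
    return bic


# ---------------------------------------------------------------------------
# search machinery
# ---------------------------------------------------------------------------

def _reachable(children: dict[str, set], src: str, dst: str,
               skip_edge=None) -> bool:
    """DFS: is there a directed path src -> ... -> dst?"""
    stack = [src]
    seen = {src}
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        for w in children[u]:
            if skip_edge is not None and (u, w) == skip_edge:
                continue
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return False


def _candidate_moves(pairs, edges, children, constraints):
    """Yield (kind, (u, v)) for every structurally legal single move."""
    for a, b in pairs:
        if (a, b) in edges or (b, a) in edges:
            if (a, b) in edges:
                u, v = a, b
            else:
                u, v = b, a
            yield "delete", (u, v)
            # reverse u->v to v->u: inbound edge to u; cycle iff an
            # alternative directed path u ~> v survives the removal
            if constraints.allows(v, u) and not _reachable(
                children, u, v, skip_edge=(u, v)
            ):
                yield "reverse", (u, v)
        else:
            for u, v in ((a, b), (b, a)):
                if constraints.allows(u, v) and not _reachable(children, v, u):
                    yield "add", (u, v)


def _move_delta(kind, u, v, parents, scores, data, cache):
    """Score change of a move, touching only the affected node scores."""
    if kind == "add":
        new_v = node_bic(data, v, parents[v] | {u}, cache)
        return new_v - scores[v], {v: new_v}
    if kind == "delete":
        new_v = node_bic(data, v, parents[v] - {u}, cache)
        return new_v - scores[v], {v: new_v}
    # reverse: v loses parent u, u gains parent v; both endpoints rescored
    new_v = node_bic(data, v, parents[v] - {u}, cache)
    new_u = node_bic(data, u, parents[u] | {v}, cache)
    return (new_v - scores[v]) + (new_u - scores[u]), {v: new_v, u: new_u}


def hill_climb(
    skeleton,
    data: MixedDataset,
    constraints: DirectionConstraints | None = None,
    search_mode: str = "best_move",
) -> ScoredDag:
    """Greedy BIC minimization over orientations of the skeleton.

    ``search_mode="best_move"`` (default) applies the globally best move each
    iteration. Score ties (within a relative 1e-6) are resolved by a
    deterministic one-step lookahead — Markov-equivalent orientations of the
    same pair have *identical* single-move scores, and the lookahead picks
    the orientation whose best follow-up move descends furthest (this is what
    lets the search commit to a collider instead of stalling on the
    equivalent fork); residual ties break by move type (add < delete <
    reverse) then lexicographic edge. ``search_mode="nodewise_sweep"`` sweeps
    node pairs in order and applies the best improving move per pair
    immediately. Both modes accept only strictly decreasing moves and
    terminate at a local optimum.
    """
    if search_mode not in ("best_move", "nodewise_sweep"):
        raise ValueError(f"unknown search_mode {search_mode!r}")
    graph = skeleton.graph if isinstance(skeleton, SkeletonWithSepsets) else skeleton
    if not isinstance(graph, UndirectedGraph):
        raise TypeError("skeleton must be an UndirectedGraph or SkeletonWithSepsets")
    constraints = constraints or DirectionConstraints()
    constraints.validate(graph.nodes)
    nodes = list(graph.nodes)
    pairs = sorted(graph.edges)

    cache: dict = {}
    parents: dict[str, set] = {v: set() for v in nodes}
    children: dict[str, set] = {v: set() for v in nodes}
    scores = {v: node_bic(data, v, frozenset(), cache) for v in nodes}
    edges: set[tuple[str, str]] = set()
    trace: list[tuple[str, tuple[str, str], float]] = []

    def apply(kind, u, v, new_scores, delta):
        if kind == "add":
            edges.add((u, v))
            parents[v].add(u)
            children[u].add(v)
        elif kind == "delete":
            edges.discard((u, v))
            parents[v].discard(u)
            children[u].discard(v)
        else:  # reverse
            edges.discard((u, v))
            parents[v].discard(u)
            children[u].discard(v)
            edges.add((v, u))
            parents[u].add(v)
            children[v].add(u)
        scores.update(new_scores)
        trace.append((kind, (u, v), float(delta)))

    def unapply(kind, u, v, old_scores):
        if kind == "add":
            edges.discard((u, v))
            parents[v].discard(u)
            children[u].discard(v)
        elif kind == "delete":
            edges.add((u, v))
            parents[v].add(u)
            children[u].add(v)
        else:
            edges.discard((v, u))
            parents[u].discard(v)
            children[v].discard(u)
            edges.add((u, v))
            parents[v].add(u)
            children[u].add(v)
        scores.update(old_scores)

    def candidate_deltas():
        out = []
        for kind, (u, v) in _candidate_moves(pairs, edges, children,
                                             constraints):
            delta, new_scores = _move_delta(kind, u, v, parents, scores,
                                            data, cache)
            out.append((delta, _MOVE_RANK[kind], (u, v), kind, new_scores))
        return out

    def lookahead(delta, kind, u, v, new_scores):
        """Best follow-up delta after virtually applying a move.

        Markov-equivalent orientations score identically, so single-move
        deltas tie exactly; the follow-up score separates, e.g., the
        collider-forming orientation from the plateau-bound one.
        """
        old_scores = {w: scores[w] for w in new_scores}
        apply(kind, u, v, new_scores, delta)
        trace.pop()
        nxt = candidate_deltas()
        unapply(kind, u, v, old_scores)
        return min((c[0] for c in nxt), default=0.0)

    if search_mode == "best_move":
        while True:
            cands = [c for c in candidate_deltas() if c[0] < -_EPS]
            if not cands:
                break
            d_star = min(c[0] for c in cands)
            tol = _TIE_TOL * max(1.0, abs(d_star))
            tied = sorted(c for c in cands if c[0] <= d_star + tol)
            if len(tied) > 1:
                tied.sort(key=lambda c: (lookahead(c[0], c[3], *c[2], c[4]),
                                         c[1], c[2]))
            delta, _, (u, v), kind, new_scores = tied[0]
            apply(kind, u, v, new_scores, delta)
    else:  # nodewise sweep
        changed = True
        while changed:
            changed = False
            for a, b in pairs:
                best = None
                for kind, (u, v) in _candidate_moves([(a, b)], edges,
                                                     children, constraints):
                    delta, new_scores = _move_delta(kind, u, v, parents,
                                                    scores, data, cache)
                    key = (delta, _MOVE_RANK[kind], (u, v))
                    if delta < -_EPS and (best is None or key < best[0]):
                        best = (key, kind, u, v, new_scores, delta)
                if best is not None:
                    _, kind, u, v, new_scores, delta = best
                    apply(kind, u, v, new_scores, delta)
                    changed = True

    dag = DirectedGraph(nodes, edges)
    overall = float(sum(scores.values()))
    return ScoredDag(dag, dict(scores), overall, trace)


def best_move_delta(
    scored: ScoredDag,
    skeleton,
    data: MixedDataset,
    constraints: DirectionConstraints | None = None,
) -> float:
    """Smallest score change over all legal single moves from a ScoredDag.

    A verified local optimum has ``best_move_delta >= 0`` (up to the search
    epsilon); used to assert termination correctness.
    """
    graph = skeleton.graph if isinstance(skeleton, SkeletonWithSepsets) else skeleton
    constraints = constraints or DirectionConstraints()
    pairs = sorted(graph.edges)
    edges = set(scored.graph.directed_edges)
    parents = {v: set(scored.graph.parents(v)) for v in scored.graph.nodes}
    children: dict[str, set] = {v: set() for v in scored.graph.nodes}
    for u, v in edges:
        children[u].add(v)
    cache: dict = {}
    best = np.inf
    for kind, (u, v) in _candidate_moves(pairs, edges, children, constraints):
        delta, _ = _move_delta(kind, u, v, parents, scored.node_scores, data,
                               cache)
        best = min(best, delta)
    return float(best) if np.isfinite(best) else 0.0


def exhaustive_minimum(
    skeleton,
    data: MixedDataset,
    constraints: DirectionConstraints | None = None,
) -> tuple[DirectedGraph, float]:
    """Brute-force minimum-BIC DAG over all orientations of a small skeleton.

    Every skeleton pair independently takes one of three states (absent,
    a->b, b->a); acyclic, constraint-respecting assignments are scored
    exhaustively. Complexity 3^(#edges) — intended as a test oracle for tiny
    graphs, not for real use.
    """
    graph = skeleton.graph if isinstance(skeleton, SkeletonWithSepsets) else skeleton
    constraints = constraints or DirectionConstraints()
    pairs = sorted(graph.edges)
    if len(pairs) > 12:
        raise ValueError("exhaustive search is limited to <= 12 skeleton edges")
    nodes = list(graph.nodes)
    cache: dict = {}
    best_graph, best_score = None, np.inf
    for states in itertools.product(range(3), repeat=len(pairs)):
        edges = set()
        ok = True
        for (a, b), s in zip(pairs, states):
            if s == 1:
                u, v = a, b
            elif s == 2:
                u, v = b, a
            else:
                continue
            if not constraints.allows(u, v):
                ok = False
                break
            edges.add((u, v))
        if not ok:
            continue
        try:
            dag = DirectedGraph(nodes, edges)
        except Exception:
            continue  # cyclic assignment
        total = sum(
            node_bic(data, v, frozenset(dag.parents(v)), cache) for v in nodes
        )
        if total < best_score:
            best_graph, best_score = dag, float(total)
    return best_graph, best_score
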
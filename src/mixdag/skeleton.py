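"""Prune the mixed graphical model to the DAG skeleton (modified PC-stable).

The MGM is a superset of the skeleton: co-parents of v-structures are
connected through moralization but are conditionally independent given their
common children's other parents. The pruning loop is the order-independent
PC-stable scheme restricted to MGM edges: for conditioning-set sizes
s = 0, 1, ..., with adjacency sets frozen at the start of each level, every
surviving edge {j, l} is tested against all size-s subsets of adj(j)\\{l} and
adj(l)\\{j}; the first subset certifying independence removes the edge and is
recorded as its d-separation set.

Restricting candidate conditioning sets to MGM adjacencies (Markov-blanket
supersets) is what makes the step "modified": no test is ever run for a pair
that the MGM already separates.
"""
from __future__ import annotations

import dataclasses
import itertools

from .ci_test import CITestResult, permutation_ci_test
from .data import MixedDataset, UndirectedGraph, _pair


@dataclasses.dataclass
class SkeletonWithSepsets:
    """Estimated skeleton plus the separation set of each removed pair."""

    graph: UndirectedGraph
    sepsets: dict[tuple[str, str], tuple]
    test_log: list[CITestResult]

    def to_records(self):
        """Test log as plain dicts (for TSV export)."""
        return [
            {
                "j": t.j,
                "l": t.l,
                "conditioning_set": ",".join(t.conditioning_set),
                "rho": t.rho_obs,
                "pvalue": t.pvalue,
                "n_permutations": t.n_permutations,
                "decision": t.decision,
            }
            for t in self.test_log
        ]


def estimate_skeleton(
    mgm,
    data: MixedDataset,
    alpha: float = 0.05,
    n_permutations: int = 200,
    max_cond_size: int = 3,
    seed: int = 0,
) -> SkeletonWithSepsets:
    """PC-stable pruning of the MGM edge set via the permutation CI test.

    Parameters
    ----------
    mgm : fitted MixedGraphicalModel estimator or UndirectedGraph.
    alpha : significance level; an edge is removed when the permutation
        p-value exceeds alpha for some conditioning subset.
    n_permutations : permutations per test (B).
    max_cond_size : largest conditioning-set size attempted.
    seed : global seed; per-test seeds are derived from the canonical pair
        and subset so results are independent of column order.
    """
    if max_cond_size < 0:
        raise ValueError("max_cond_size must be >= 0")
    graph = mgm if isinstance(mgm, UndirectedGraph) else mgm.graph_
    graph = graph.copy()
    sepsets: dict[tuple[str, str], tuple] = {}
    test_log: list[CITestResult] = []
    residual_cache: dict = {}

    for s in range(max_cond_size + 1):
        adj = {v: set(graph.neighbors(v)) for v in graph.nodes}  # frozen
        any_candidate = False
        for a, b in sorted(graph.edges):
            if not graph.has_edge(a, b):  # removed earlier this level
                continue
            tried: set[tuple] = set()
            removed = False
            for side in (a, b):
                pool = sorted(adj[side] - {a, b})
                if len(pool) < s:
                    continue
                any_candidate = True
                for K in itertools.combinations(pool, s):
                    if K in tried:
                        continue
                    tried.add(K)
                    res = permutation_ci_test(
                        data, a, b, K,
                        n_permutations=n_permutations,
                        alpha=alpha, seed=seed, cache=residual_cache,
                    )
                    test_log.append(res)
                    if res.independent:
                        graph.remove_edge(a, b)
                        sepsets[_pair(a, b)] = K
                        removed = True
                        break
                if removed:
                    break
        if not any_candidate and s > 0:
            break

    return SkeletonWithSepsets(graph, sepsets, test_log)
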
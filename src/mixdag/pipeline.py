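"""End-to-end estimator: mixed graphical model -> skeleton -> oriented DAG."""
from __future__ import annotations

from sklearn.base import BaseEstimator

from .data import DirectionConstraints, as_mixed_dataset, load_constraints
from .mgm import MixedGraphicalModel
from .orientation import hill_climb
from .skeleton import estimate_skeleton


class MixedDAG(BaseEstimator):
    """Hybrid DAG structure learner for mixed continuous/categorical data.

    Three stages run in sequence on :meth:`fit`:

    1. nodewise L1-penalized GLMs with EBIC penalty selection give an
       undirected mixed graphical model (a Markov-blanket superset of the
       skeleton);
    2. a modified PC-stable loop with a permutation conditional-independence
       test on GLM residuals prunes moralization edges and records
       d-separation sets;
    3. greedy BIC hill climbing (add/delete/reverse moves restricted to
       skeleton pairs, honoring direction constraints) orients the skeleton.

    Parameters
    ----------
    gamma : EBIC constant for penalty selection (stage 1).
    n_lambdas, lambda_min_ratio, rule : penalty path and symmetrization
        (stage 1).
    alpha : CI-test significance level (stage 2).
    n_permutations : permutations per CI test (stage 2).
    max_cond_size : largest conditioning-set size (stage 2).
    constraints : DirectionConstraints, mapping, or path (stage 3);
        e.g. SNP nodes declared source-only can never receive an edge.
    search_mode : "best_move" or "nodewise_sweep" (stage 3).
    random_state : seed for the permutation tests; all other stages are
        deterministic.

    Attributes
    ----------
    graph_ : DirectedGraph — the estimated DAG (no undetermined edges).
    mgm_ : fitted MixedGraphicalModel.
    skeleton_ : SkeletonWithSepsets.
    sepsets_ : dict, removed pair -> certifying conditioning set.
    score_, node_scores_, move_trace_ : hill-climbing outcome.
    """

    def __init__(self, gamma: float = 0.5, n_lambdas: int = 50,
                 lambda_min_ratio: float = 0.01, rule: str = "or",
                 alpha: float = 0.05, n_permutations: int = 200,
                 max_cond_size: int = 3, constraints=None,
                 search_mode: str = "best_move", random_state: int = 0,
                 tol: float = 1e-7, max_iter: int = 5000):
        self.gamma = gamma
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.rule = rule
        self.alpha = alpha
        self.n_permutations = n_permutations
        self.max_cond_size = max_cond_size
        self.constraints = constraints
        self.search_mode = search_mode
        self.random_state = random_state
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None, types=None):
        data = as_mixed_dataset(X, types)
        constraints = (
            self.constraints
            if isinstance(self.constraints, DirectionConstraints)
            else load_constraints(self.constraints)
        )
        constraints.validate(data.node_names)

        self.mgm_ = MixedGraphicalModel(
            gamma=self.gamma, n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio, rule=self.rule,
            tol=self.tol, max_iter=self.max_iter,
        ).fit(data)
        self.skeleton_ = estimate_skeleton(
            self.mgm_, data, alpha=self.alpha,
            n_permutations=self.n_permutations,
            max_cond_size=self.max_cond_size, seed=self.random_state,
        )
        scored = hill_climb(self.skeleton_, data, constraints,
                            search_mode=self.search_mode)
        self.graph_ = scored.graph
        self.score_ = scored.overall
        self.node_scores_ = scored.node_scores
        self.move_trace_ = scored.move_trace
        self.sepsets_ = self.skeleton_.sepsets
        self.test_log_ = self.skeleton_.test_log
        self.nodes_ = list(data.node_names)
        self.n_features_in_ = data.d
        return self
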
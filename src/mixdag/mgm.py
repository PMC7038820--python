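"""Markov-blanket identification by nodewise L1-penalized GLMs.

Each node is regressed on all other nodes (continuous predictors
standardized, categorical predictors expanded to reference-coded indicator
columns) under an L1 penalty on the sum-form negative log-likelihood,

    minimize  -loglik(beta_j) + lambda_j * ||beta_j||_1,

with lambda_j chosen per node by minimizing the extended BIC

    EBIC_gamma = -2 loglik + ||beta_j||_0 log n + 2 gamma ||beta_j||_0 log(d-1).

Nodes i and j are connected in the mixed graphical model when the nodewise
active sets select each other under the symmetrization rule (OR by default).
The resulting undirected graph is a superset of the DAG skeleton: every
Markov blanket is covered, but co-parents of v-structures are spuriously
connected (moralization) and are removed by the skeleton step.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.linear_model import Lasso

from . import _glm
from .data import MixedDataset, UndirectedGraph, as_mixed_dataset, _pair

GAUSSIAN = "gaussian"
MULTINOMIAL = "multinomial"


@dataclasses.dataclass
class NodewiseModel:
    """One fitted conditional model (a node regressed on all others).

    Coefficients are reported on the original data scale; ``active_set`` and
    ``df`` are determined on the solver (standardized) scale with exact-zero
    thresholding at 1e-8. For a multinomial node, ``coef`` has one column per
    non-reference level (levels 2..L; level-1 weights are fixed at zero) and
    ``df`` counts nonzeros across all level blocks.
    """

    node: str
    family: str
    colnames: list[str]
    coef: np.ndarray
    intercept: np.ndarray | float
    sigma2: float | None
    lambda_: float
    loglik: float
    active_set: frozenset
    df: int
    n: int
    path: list[tuple[float, int, float]] | None = None  # (lambda, df, ebic)


def _active_from_std(coef_std: np.ndarray, groups: dict[str, list[int]]):
    """Active node set and df from solver-scale coefficients."""
    nz = np.abs(coef_std) > _glm.ZERO_TOL
    if coef_std.ndim == 2:
        col_nz = nz.any(axis=1)
        df = int(nz.sum())
    else:
        col_nz = nz
        df = int(nz.sum())
    active = frozenset(
        name for name, idx in groups.items() if any(col_nz[i] for i in idx)
    )
    return active, df


def fit_penalized_node(
    data: MixedDataset,
    node: str,
    lam: float,
    tol: float = 1e-7,
    max_iter: int = 5000,
    _warm=None,
) -> NodewiseModel:
    """Solve the L1-penalized nodewise regression at a single penalty.

    ``lam`` is on the sum-form loss; for a gaussian node this is the plain
    lasso (profile sigma^2), solved through scikit-learn's coordinate descent
    with ``alpha = lam / n``. ``lam = 0`` gives the unpenalized MLE.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    others = [v for v in data.node_names if v != node]
    X, colnames, groups, scales, centers = _glm.design_matrix(
        data, others, standardize=True
    )
    n = data.n

    if data.is_categorical(node):
        codes = data.codes(node)
        L = data.n_levels(node)
        try:
            W, loglik = _glm.fit_multinomial(
                X, codes, L, l1=lam, W0=_warm, tol=tol, max_iter=max_iter
            )
        except _glm.ConvergenceError as exc:
            raise _glm.ConvergenceError(
                f"node {node!r} at lambda={lam:g}: {exc}"
            ) from exc
        if lam == 0.0 and _glm.separation_suspected(W):
            warnings.warn(
                f"separation suspected in unpenalized fit of {node!r}; "
                "use lambda > 0",
                RuntimeWarning,
            )
        coef_std = W[1:]
        active, df = _active_from_std(coef_std, groups)
        coef = coef_std / scales[:, None] if coef_std.size else coef_std
        intercept = W[0] - (coef_std * (centers / scales)[:, None]).sum(axis=0)
        m = NodewiseModel(
            node, MULTINOMIAL, colnames, coef, intercept, None, lam, loglik,
            active, df, n, None,
        )
        m._solver_state = W  # warm start for the next path point
        return m

    y = data.column(node)
    if lam == 0.0:
        coef_std, b0, fitted, _ = _glm.lstsq_fit(X, y)
    else:
        est = _warm if isinstance(_warm, Lasso) else Lasso(
            alpha=lam / n, fit_intercept=True, warm_start=True,
            max_iter=max_iter, tol=tol,
        )
        est.set_params(alpha=lam / n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # benign duality-gap warnings
            est.fit(X, y)
        coef_std, b0 = est.coef_.copy(), float(est.intercept_)
        fitted = est.predict(X)
    coef_std[np.abs(coef_std) < _glm.ZERO_TOL] = 0.0
    rss = float(np.sum((y - fitted) ** 2))
    loglik = _glm.gaussian_loglik(rss, n)
    sigma2 = max(rss / n, 1e-12)
    active, df = _active_from_std(coef_std, groups)
    coef = coef_std / scales if coef_std.size else coef_std
    intercept = float(b0 - np.sum(coef_std * centers / scales)) if coef_std.size else float(b0)
    return NodewiseModel(
        node, GAUSSIAN, colnames, coef, intercept, sigma2, lam, loglik,
        active, df, n, None,
    )


def ebic_score(model: NodewiseModel, n: int, d: int, gamma: float) -> float:
    """Extended BIC of a fitted nodewise model.

    Uses the unpenalized log-likelihood at the fitted coefficients; the
    model-space term penalizes each selected coefficient by 2*gamma*log(d-1).
    With gamma = 0 this is exactly the BIC used for orientation scoring.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    return (
        -2.0 * model.loglik
        + model.df * np.log(n)
        + 2.0 * gamma * model.df * np.log(d - 1)
    )


def lambda_max(data: MixedDataset, node: str) -> float:
    """Smallest penalty at which the nodewise active set is empty.

    Computed as the max absolute gradient of the sum-form loss at the
    null (intercept-only) model.
    """
    others = [v for v in data.node_names if v != node]
    X, _, _, _, _ = _glm.design_matrix(data, others, standardize=True)
    if data.is_categorical(node):
        codes = data.codes(node)
        L = data.n_levels(node)
        freq, _ = _glm.multinomial_intercept_mle(codes, L)
        Y = _glm.one_hot(codes, L)
        P = np.tile(freq, (data.n, 1))
        G = X.T @ (P[:, 1:] - Y[:, 1:])
        return float(np.max(np.abs(G))) if G.size else 0.0
    y = data.column(node)
    g = X.T @ (y - y.mean())
    return float(np.max(np.abs(g))) if g.size else 0.0


def default_lambda_path(
    data: MixedDataset, node: str, n_lambdas: int = 50,
    lambda_min_ratio: float = 0.01,
) -> np.ndarray:
    lmax = lambda_max(data, node)
    if lmax <= 0:
        return np.array([0.0])
    return np.geomspace(lmax, lmax * lambda_min_ratio, n_lambdas)


def select_lambda(
    data: MixedDataset,
    node: str,
    lambda_path: np.ndarray | None = None,
    gamma: float = 0.5,
    n_lambdas: int = 50,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-7,
    max_iter: int = 5000,
) -> NodewiseModel:
    """Fit the nodewise L1 path with warm starts and pick the EBIC minimizer.

    Ties are broken toward the larger penalty (the sparser model), because the
    path is traversed from large to small lambda and only a strictly smaller
    EBIC displaces the incumbent.
    """
    if lambda_path is None:
        lambda_path = default_lambda_path(data, node, n_lambdas, lambda_min_ratio)
    lambda_path = np.asarray(lambda_path, dtype=float)
    if len(lambda_path) == 0:
        raise ValueError("empty lambda path")
    if len(lambda_path) > 1:
        if np.any(np.diff(lambda_path) >= 0) or np.any(lambda_path <= 0):
            raise ValueError("lambda path must be strictly positive descending")
    n, d = data.n, data.d
    best = None
    best_score = np.inf
    records = []
    warm = None
    is_cat = data.is_categorical(node)
    if not is_cat:
        warm = Lasso(fit_intercept=True, warm_start=True, max_iter=max_iter,
                     tol=tol, alpha=1.0)
    for lam in lambda_path:
        model = fit_penalized_node(data, node, float(lam), tol=tol,
                                   max_iter=max_iter, _warm=warm)
        if is_cat:
            warm = model._solver_state
        score = ebic_score(model, n, d, gamma)
        records.append((float(lam), model.df, float(score)))
        if score < best_score:
            best, best_score = model, score
    best.path = records
    return best


class MixedGraphicalModel(BaseEstimator):
    """Undirected mixed graphical model by nodewise penalized regression.

    Parameters
    ----------
    gamma : float, default 0.5
        EBIC model-space constant used to tune each node's penalty.
    n_lambdas, lambda_min_ratio : path specification; 50 log-spaced values
        from lambda_max down to ``lambda_min_ratio * lambda_max``.
    rule : {"or", "and"}, default "or"
        Symmetrization: OR connects i and j if either nodewise regression
        selects the other (preserves Markov-blanket supersets); AND requires
        both.
    tol, max_iter : solver controls.

    Attributes
    ----------
    graph_ : UndirectedGraph
    models_ : dict mapping node name -> NodewiseModel
    nodes_ : list of node names
    """

    def __init__(self, gamma: float = 0.5, n_lambdas: int = 50,
                 lambda_min_ratio: float = 0.01, rule: str = "or",
                 tol: float = 1e-7, max_iter: int = 5000):
        self.gamma = gamma
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.rule = rule
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None, types=None):
        if self.rule not in ("or", "and"):
            raise ValueError(f"rule must be 'or' or 'and', got {self.rule!r}")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        data = as_mixed_dataset(X, types)
        models = {}
        for node in data.node_names:
            try:
                models[node] = select_lambda(
                    data, node, gamma=self.gamma, n_lambdas=self.n_lambdas,
                    lambda_min_ratio=self.lambda_min_ratio, tol=self.tol,
                    max_iter=self.max_iter,
                )
            except Exception as exc:
                raise RuntimeError(f"nodewise fit failed for {node!r}") from exc
        edges = set()
        for j, mj in models.items():
            for i in mj.active_set:
                if self.rule == "or" or j in models[i].active_set:
                    edges.add(_pair(i, j))
        self.nodes_ = list(data.node_names)
        self.models_ = models
        self.graph_ = UndirectedGraph(self.nodes_, edges)
        self.n_features_in_ = data.d
        return self


def build_mgm(data, gamma: float = 0.5, types=None, **params) -> MixedGraphicalModel:
    """Thin functional wrapper over :class:`MixedGraphicalModel`."""
    return MixedGraphicalModel(gamma=gamma, **params).fit(data, types=types)
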
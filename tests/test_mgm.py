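"""Nodewise penalized regression, EBIC selection, and MGM construction."""
import numpy as np
import pandas as pd
import pytest

import mixdag as m
from mixdag import _glm
from mixdag.mgm import default_lambda_path


def _univariate(n=50, seed=0, slope=0.7):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std()
    y = slope * x + rng.normal(size=n)
    data = m.as_mixed_dataset(pd.DataFrame({"Y": y, "X": x}))
    ols = float(np.dot(x, y - y.mean()) / np.dot(x, x))
    return data, ols


def test_lambda_zero_equals_ols_closed_form():
    data, ols = _univariate()
    model = m.fit_penalized_node(data, "Y", 0.0)
    assert model.coef[0] == pytest.approx(ols, abs=1e-6)


@pytest.mark.parametrize("lam", [2.0, 5.0, 20.0])
def test_univariate_lasso_soft_threshold(lam):
    data, ols = _univariate()
    model = m.fit_penalized_node(data, "Y", lam)
    expected = np.sign(ols) * max(abs(ols) - lam / data.n, 0.0)
    assert model.coef[0] == pytest.approx(expected, abs=1e-6)


def test_multiple_regression_lambda_zero_matches_lstsq():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(120, 3))
    y = X @ [1.0, -0.5, 0.25] + rng.normal(size=120)
    df = pd.DataFrame(np.column_stack([y, X]), columns=["Y", "A", "B", "C"])
    data = m.as_mixed_dataset(df)
    model = m.fit_penalized_node(data, "Y", 0.0)
    X1 = np.column_stack([np.ones(120), X])
    beta = np.linalg.lstsq(X1, y, rcond=None)[0]
    np.testing.assert_allclose(model.coef, beta[1:], atol=1e-6)


def test_full_shrinkage_at_ten_lambda_max(mixed_small):
    for node in mixed_small.node_names:
        lam = 10.0 * m.lambda_max(mixed_small, node)
        model = m.fit_penalized_node(mixed_small, node, lam)
        assert model.active_set == frozenset()
        assert model.df == 0


def test_multinomial_unpenalized_matches_sklearn_loglik(mixed_small):
    from sklearn.linear_model import LogisticRegression

    model = m.fit_penalized_node(mixed_small, "C", 0.0)
    X = np.column_stack([mixed_small.column("A"), mixed_small.column("B")])
    sk = LogisticRegression(C=np.inf, max_iter=2000).fit(
        X, mixed_small.codes("C"))
    ll_sk = np.sum(np.log(
        sk.predict_proba(X)[np.arange(80), mixed_small.codes("C") - 1]))
    assert model.loglik == pytest.approx(ll_sk, abs=1e-3)


def test_ebic_formula_values():
    model = m.NodewiseModel("Y", "gaussian", [], np.array([]), 0.0, 1.0,
                            0.0, -100.0, frozenset(), 0, 100)
    assert m.ebic_score(model, 100, 21, 0.0) == pytest.approx(200.0)
    model3 = m.NodewiseModel("Y", "gaussian", [], np.array([]), 0.0, 1.0,
                             0.0, -100.0, frozenset(), 3, 100)
    expected = 200.0 + 3 * np.log(100) + 2 * 0.5 * 3 * np.log(20)
    assert m.ebic_score(model3, 100, 21, 0.5) == pytest.approx(expected)
    # adding one selected coefficient at equal loglik costs log n + 2g log(d-1)
    model4 = m.NodewiseModel("Y", "gaussian", [], np.array([]), 0.0, 1.0,
                             0.0, -100.0, frozenset(), 4, 100)
    diff = m.ebic_score(model4, 100, 21, 0.5) - m.ebic_score(model3, 100, 21, 0.5)
    assert diff == pytest.approx(np.log(100) + 2 * 0.5 * np.log(20))
    with pytest.raises(ValueError):
        m.ebic_score(model3, 100, 21, -0.1)


def test_ebic_gamma_zero_equals_orientation_bic(mixed_small):
    model = m.fit_penalized_node(mixed_small, "B", 0.0)
    ebic0 = m.ebic_score(model, mixed_small.n, mixed_small.d, 0.0)
    bic = m.node_bic(mixed_small, "B", {"A", "C"})
    assert ebic0 == pytest.approx(bic, abs=1e-6)


def test_select_lambda_single_point_path(mixed_small):
    model = m.select_lambda(mixed_small, "B", lambda_path=np.array([0.5]))
    assert model.lambda_ == 0.5
    assert len(model.path) == 1


def test_select_lambda_rejects_bad_path(mixed_small):
    with pytest.raises(ValueError):
        m.select_lambda(mixed_small, "B", lambda_path=np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        m.select_lambda(mixed_small, "B", lambda_path=np.array([]))


@pytest.mark.parametrize("node", ["B", "C"])
def test_active_set_size_monotone_along_path(mixed_small, node):
    """Sparsity is (weakly) decreasing in lambda, up to solver tolerance."""
    model = m.select_lambda(mixed_small, node)
    dfs = [df for _, df, _ in model.path]  # path ordered large -> small lambda
    assert all(b >= a - 1 for a, b in zip(dfs, dfs[1:]))
    assert dfs[0] == 0  # path starts at lambda_max


def test_pure_noise_node_selects_empty(chain_1000):
    rng = np.random.default_rng(99)
    df = chain_1000.to_dataframe()
    df["N"] = rng.normal(size=1000)
    data = m.as_mixed_dataset(df)
    model = m.select_lambda(data, "N")
    assert model.active_set == frozenset()


def test_signal_node_selects_parent():
    hits = 0
    for seed in range(5):
        rng = np.random.default_rng(200 + seed)
        Xi = rng.normal(size=1000)
        Xj = Xi + rng.normal(size=1000)
        data = m.as_mixed_dataset(pd.DataFrame({"Xi": Xi, "Xj": Xj}))
        if "Xi" in m.select_lambda(data, "Xj").active_set:
            hits += 1
    assert hits == 5


def test_build_mgm_chain_edges(chain_1000):
    est = m.build_mgm(chain_1000)
    assert est.graph_.has_edge("X1", "X2")
    assert est.graph_.has_edge("X2", "X3")


def test_build_mgm_independent_variables_empty():
    empty = 0
    for seed in range(3):
        rng = np.random.default_rng(400 + seed)
        df = pd.DataFrame(rng.normal(size=(1000, 5)),
                          columns=list("ABCDE"))
        est = m.build_mgm(m.as_mixed_dataset(df))
        empty += not est.graph_.edges
    assert empty >= 2


def test_mgm_contains_moralization_edge(vstruct_1000):
    est = m.build_mgm(vstruct_1000)
    assert est.graph_.has_edge("X", "Z")  # co-parents linked in the MGM


def test_mgm_invariant_to_column_order(mixed_small):
    df = mixed_small.to_dataframe()
    types = mixed_small.types_dict()
    a = m.build_mgm(m.as_mixed_dataset(df, types=types))
    b = m.build_mgm(m.as_mixed_dataset(df[["C", "A", "B"]], types=types))
    assert a.graph_.edges == b.graph_.edges


def test_and_rule_is_subset_of_or_rule(mixed_small):
    g_or = m.build_mgm(mixed_small, rule="or").graph_
    g_and = m.build_mgm(mixed_small, rule="and").graph_
    assert g_and.edges <= g_or.edges


def test_invalid_rule_and_gamma():
    with pytest.raises(ValueError, match="rule"):
        m.MixedGraphicalModel(rule="xor").fit(
            np.random.default_rng(0).normal(size=(20, 3)))
    with pytest.raises(ValueError, match="gamma"):
        m.MixedGraphicalModel(gamma=-1).fit(
            np.random.default_rng(0).normal(size=(20, 3)))


def test_default_lambda_path_shape(mixed_small):
    path = default_lambda_path(mixed_small, "B", n_lambdas=50,
                               lambda_min_ratio=0.01)
    assert len(path) == 50
    assert path[0] == pytest.approx(m.lambda_max(mixed_small, "B"))
    assert path[-1] == pytest.approx(0.01 * path[0])
    assert np.all(np.diff(path) < 0)
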
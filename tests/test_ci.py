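"""Residual construction, partial correlation, and the permutation CI test."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mixdag as m
from mixdag.ci_test import derive_test_seed
from tests.conftest import make_vstructure


def test_continuous_residuals_empty_set_center():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"A": rng.normal(size=30), "B": rng.normal(size=30)})
    data = m.as_mixed_dataset(df)
    r = m.residuals(data, "A", ())
    np.testing.assert_allclose(r, data.column("A") - data.column("A").mean())


def test_binary_pearson_residuals_hand_computed():
    # 4 observations of a binary variable, intercept-only model:
    # mu-hat for the level-2 indicator is its frequency 1/4
    df = pd.DataFrame({
        "Y": ["a", "a", "b", "a"],
        "X": [0.1, 0.2, 0.3, 0.5],
    })
    data = m.as_mixed_dataset(
        df, types={"Y": "categorical", "X": "continuous"})
    r = m.residuals(data, "Y", ())
    mu = 0.25
    s = np.sqrt(mu * (1 - mu))
    expected = np.array([(0 - mu) / s, (0 - mu) / s, (1 - mu) / s, (0 - mu) / s])
    np.testing.assert_allclose(r, expected, atol=1e-10)


def test_four_level_null_residuals_sum_to_zero():
    rng = np.random.default_rng(1)
    codes = rng.integers(1, 5, size=200)
    df = pd.DataFrame({"C": [str(c) for c in codes],
                       "X": rng.normal(size=200)})
    data = m.as_mixed_dataset(
        df, types={"C": "categorical", "X": "continuous"})
    r = m.residuals(data, "C", ())
    # each indicator's Pearson residual sums to zero at the MLE frequencies
    assert abs(r.sum()) < 1e-8
    # check one subject against the marginal-frequency closed form
    # (levels are recoded in first-appearance order; use the internal codes)
    ic = data.codes("C")
    freq = np.array([(ic == k).mean() for k in range(1, 5)])
    mu = freq[1:]
    ind = np.array([1.0 if ic[0] == k else 0.0 for k in (2, 3, 4)])
    expected0 = np.sum((ind - mu) / np.sqrt(mu * (1 - mu)))
    assert r[0] == pytest.approx(expected0)


def test_residuals_regress_out_conditioning():
    rng = np.random.default_rng(2)
    Z = rng.normal(size=300)
    X = 2.0 * Z + rng.normal(size=300)
    data = m.as_mixed_dataset(pd.DataFrame({"X": X, "Z": Z}))
    r = m.residuals(data, "X", ("Z",))
    # residuals orthogonal to the conditioning variable and the intercept
    assert abs(r.sum()) < 1e-8
    assert abs(np.dot(r, Z)) < 1e-6


def test_partial_correlation_basic_values():
    assert m.partial_correlation(np.array([1.0, 2, 3, 4]),
                                 np.array([1.0, 2, 3, 4])) == pytest.approx(1.0)
    assert m.partial_correlation(np.array([1.0, -1, 1, -1]),
                                 np.array([1.0, 1, -1, -1])) == pytest.approx(0.0)
    a = np.array([1.0, 2, 3, 4])
    b = np.array([1.0, 2, 4, 3])
    assert m.partial_correlation(a, b) == pytest.approx(np.corrcoef(a, b)[0, 1])


def test_partial_correlation_constant_vector_warns():
    with pytest.warns(RuntimeWarning, match="constant"):
        out = m.partial_correlation(np.ones(5), np.arange(5.0))
    assert out == 0.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_partial_correlation_bounded(seed):
    rng = np.random.default_rng(seed)
    a, b = rng.normal(size=(2, 10))
    assert abs(m.partial_correlation(a, b)) <= 1.0 + 1e-12


def test_permutation_test_deterministic_under_seed(vstruct_1000):
    r1 = m.permutation_ci_test(vstruct_1000, "X", "Z", (), seed=3)
    r2 = m.permutation_ci_test(vstruct_1000, "X", "Z", (), seed=3)
    assert r1.pvalue == r2.pvalue
    # near-null statistic: mid-range p-value shifts with the permutations
    r3 = m.permutation_ci_test(vstruct_1000, "X", "Z", (), seed=4)
    assert r3.pvalue != r1.pvalue


def test_permutation_test_symmetric_in_pair_order(vstruct_1000):
    a = m.permutation_ci_test(vstruct_1000, "X", "W", (), seed=0)
    b = m.permutation_ci_test(vstruct_1000, "W", "X", (), seed=0)
    assert a.pvalue == b.pvalue
    assert a.rho_obs == b.rho_obs


def test_strong_dependence_gives_floor_pvalue():
    rng = np.random.default_rng(5)
    X = rng.normal(size=200)
    Y = 0.9 * X + np.sqrt(1 - 0.81) * rng.normal(size=200)
    data = m.as_mixed_dataset(pd.DataFrame({"X": X, "Y": Y}))
    res = m.permutation_ci_test(data, "X", "Y", (), n_permutations=100, seed=0)
    assert res.decision == "dependent"
    assert res.pvalue == pytest.approx(1.0 / 101.0)  # add-one floor


def test_pvalue_bounds_and_decision_rule(vstruct_1000):
    res = m.permutation_ci_test(vstruct_1000, "X", "Z", (), n_permutations=50,
                                seed=1)
    assert 1.0 / 51.0 <= res.pvalue <= 1.0
    assert res.independent == (res.pvalue > 0.05)


def test_collider_conditioning_induces_dependence(vstruct_1000):
    # X and Z marginally independent, but dependent given the collider W
    marg = m.permutation_ci_test(vstruct_1000, "X", "Z", (), seed=0)
    cond = m.permutation_ci_test(vstruct_1000, "X", "Z", ("W",), seed=0)
    assert marg.independent
    assert not cond.independent


def test_invalid_arguments(vstruct_1000):
    with pytest.raises(ValueError):
        m.permutation_ci_test(vstruct_1000, "X", "X", ())
    with pytest.raises(ValueError):
        m.permutation_ci_test(vstruct_1000, "X", "Z", ("X",))
    with pytest.raises(ValueError):
        m.permutation_ci_test(vstruct_1000, "X", "Z", (), n_permutations=0)


def test_derived_seed_canonical():
    assert derive_test_seed(1, "a", "b", ("k",)) == \
        derive_test_seed(1, "b", "a", ("k",))
    assert derive_test_seed(1, "a", "b", ()) != \
        derive_test_seed(1, "a", "b", ("k",))
    assert derive_test_seed(1, "a", "b", ()) != derive_test_seed(2, "a", "b", ())


def test_fisher_z_agrees_on_strong_signal():
    data = make_vstructure(500, 21)
    r, p, decision = m.fisher_z_test(data, "X", "W", ())
    assert decision == "dependent"
    assert p < 1e-6
    r2, p2, d2 = m.fisher_z_test(data, "X", "Z", ())
    assert d2 == "independent"
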
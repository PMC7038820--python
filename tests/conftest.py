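import numpy as np
import pandas as pd
import pytest

import mixdag as m


def make_vstructure(n: int, seed: int) -> m.MixedDataset:
    """Collider X -> W <- Z with W = X + Z + noise (all continuous)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=n)
    Z = rng.normal(size=n)
    W = X + Z + rng.normal(size=n)
    return m.as_mixed_dataset(pd.DataFrame({"X": X, "W": W, "Z": Z}))


def make_chain(n: int, seed: int) -> m.MixedDataset:
    """Chain X1 -> X2 -> X3 with unit effects and unit noise."""
    rng = np.random.default_rng(seed)
    X1 = rng.normal(size=n)
    X2 = X1 + rng.normal(size=n)
    X3 = X2 + rng.normal(size=n)
    return m.as_mixed_dataset(pd.DataFrame({"X1": X1, "X2": X2, "X3": X3}))


def make_binary_conditional(n: int, seed: int) -> m.MixedDataset:
    """Continuous X and binary Y, conditionally independent given Z."""
    rng = np.random.default_rng(seed)
    Z = rng.normal(size=n)
    X = Z + rng.normal(size=n)
    p = 1.0 / (1.0 + np.exp(-Z))
    Y = (rng.random(n) < p).astype(int) + 1
    df = pd.DataFrame({"X": X, "Y": [str(v) for v in Y], "Z": Z})
    return m.as_mixed_dataset(
        df, types={"X": "continuous", "Y": "categorical", "Z": "continuous"}
    )


@pytest.fixture
def vstruct_1000():
    return make_vstructure(1000, 7)


@pytest.fixture
def chain_1000():
    return make_chain(1000, 11)


@pytest.fixture
def mixed_small():
    """Small mixed dataset: 2 continuous, one 3-level categorical, n=80."""
    rng = np.random.default_rng(5)
    A = rng.normal(size=80)
    B = A + rng.normal(size=80)
    codes = rng.integers(1, 4, size=80)
    df = pd.DataFrame({"A": A, "B": B, "C": [str(c) for c in codes]})
    return m.as_mixed_dataset(
        df, types={"A": "continuous", "B": "continuous", "C": "categorical"}
    )
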
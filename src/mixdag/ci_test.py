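"""Permutation test of conditional independence for mixed variable pairs.

For a candidate pair (X_j, X_l) conditioned on a set X_K, each variable is
regressed on X_K with a GLM matched to its type and reduced to a single
residual vector per subject:

* continuous target: ordinary residual x_ij - xhat_ij from linear regression
  (intercept-only when K is empty);
* categorical target with L levels: the summed Pearson residual of a
  reference-coded multinomial logit,
  r_i = sum_{k=1}^{L-1} (x_ik - mu_ik) / sqrt(mu_ik (1 - mu_ik)),
  where x_ik is the k-th indicator (levels 2..L) and mu_ik its fitted
  probability. For a binary target this is the usual logistic Pearson
  residual.

The observed statistic is the Pearson correlation of the two residual
vectors. Its null distribution is obtained by permuting the second residual
vector B times; the two-sided, add-one-corrected p-value is

    p = (1 + #{b : |rho^(b)| >= |rho|}) / (B + 1),

and the pair is declared conditionally independent when p > alpha. Permuting
one vector suffices for exchangeability under the null, and the add-one
correction keeps p > 0.
"""
from __future__ import annotations

import dataclasses
import hashlib
import warnings

import numpy as np
import scipy.stats

from . import _glm
from .data import MixedDataset


@dataclasses.dataclass
class CITestResult:
    """Outcome of one permutation conditional-independence test."""

    j: str
    l: str
    conditioning_set: tuple
    rho_obs: float
    pvalue: float
    n_permutations: int
    decision: str  # "independent" | "dependent"
    seed: int

    @property
    def independent(self) -> bool:
        return self.decision == "independent"


def residuals(
    data: MixedDataset,
    target: str,
    conditioning,
    cache: dict | None = None,
) -> np.ndarray:
    """Residual vector of ``target`` regressed on the conditioning set."""
    K = tuple(sorted(conditioning))
    if target in K:
        raise ValueError(f"target {target!r} inside conditioning set")
    if cache is not None and (target, K) in cache:
        return cache[(target, K)]
    X, _, _, _, _ = _glm.design_matrix(data, list(K), standardize=False)

    if not data.is_categorical(target):
        y = data.column(target)
        if X.shape[1] == 0:
            r = y - y.mean()
        else:
            keep = _glm.drop_collinear(X)
            if len(keep) < X.shape[1]:
                warnings.warn(
                    f"collinear conditioning columns dropped for {target!r}",
                    RuntimeWarning,
                )
            _, _, fitted, _ = _glm.lstsq_fit(X[:, keep], y)
            r = y - fitted
    else:
        codes = data.codes(target)
        L = data.n_levels(target)
        if X.shape[1] == 0:
            freq, _ = _glm.multinomial_intercept_mle(codes, L)
            P = np.tile(freq, (data.n, 1))
        else:
            keep = _glm.drop_collinear(X)
            if len(keep) < X.shape[1]:
                warnings.warn(
                    f"collinear conditioning columns dropped for {target!r}",
                    RuntimeWarning,
                )
            W, _ = _glm.fit_multinomial(X[:, keep], codes, L, l1=0.0)
            if _glm.separation_suspected(W):
                W, _ = _glm.fit_multinomial(
                    X[:, keep], codes, L, l1=0.0, ridge=1e-6
                )
            X1 = np.column_stack([np.ones(data.n), X[:, keep]])
            P = _glm.softmax_probs(X1, W)
        mu = np.clip(P[:, 1:], _glm.PROB_EPS, 1.0 - _glm.PROB_EPS)
        ind = _glm.one_hot(codes, L)[:, 1:]
        r = ((ind - mu) / np.sqrt(mu * (1.0 - mu))).sum(axis=1)

    if cache is not None:
        cache[(target, K)] = r
    return r


def partial_correlation(r_j: np.ndarray, r_l: np.ndarray) -> float:
    """Pearson correlation of two centered residual vectors.

    A constant vector makes the correlation undefined; 0.0 is returned with a
    warning so the caller can fall back to an independence decision.
    """
    r_j = np.asarray(r_j, float)
    r_l = np.asarray(r_l, float)
    if r_j.shape != r_l.shape or r_j.ndim != 1:
        raise ValueError("residual vectors must be 1-D of equal length")
    if len(r_j) < 3:
        raise ValueError("need at least 3 observations")
    a = r_j - r_j.mean()
    b = r_l - r_l.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0.0:
        warnings.warn("constant residual vector; correlation undefined",
                      RuntimeWarning)
        return 0.0
    return float(np.dot(a, b) / denom)


def derive_test_seed(seed: int, j: str, l: str, K) -> int:
    """Deterministic per-test seed keyed by canonical pair identity.

    Ensures PC-stable results do not depend on column order: the same
    (pair, conditioning set) always draws the same permutations.
    """
    a, b = sorted((j, l))
    key = f"{int(seed)}|{a}|{b}|{','.join(sorted(K))}".encode()
    return int.from_bytes(hashlib.blake2b(key, digest_size=4).digest(), "little")


def permutation_ci_test(
    data: MixedDataset,
    j: str,
    l: str,
    K=(),
    n_permutations: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    cache: dict | None = None,
) -> CITestResult:
    """Permutation test of X_j independent of X_l given X_K."""
    if j == l:
        raise ValueError("j and l must differ")
    Kt = tuple(sorted(K))
    if j in Kt or l in Kt:
        raise ValueError("j, l must not belong to the conditioning set")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    # canonicalize so that the same unordered pair permutes the same vector
    a, b = sorted((j, l))
    r_a = residuals(data, a, Kt, cache)
    r_b = residuals(data, b, Kt, cache)
    test_seed = derive_test_seed(seed, a, b, Kt)

    ca = r_a - r_a.mean()
    cb = r_b - r_b.mean()
    na, nb = np.linalg.norm(ca), np.linalg.norm(cb)
    if na == 0.0 or nb == 0.0:
        warnings.warn(
            f"constant residuals for pair ({a}, {b}) given {Kt}; "
            "declaring independence",
            RuntimeWarning,
        )
        return CITestResult(a, b, Kt, 0.0, 1.0, n_permutations,
                            "independent", test_seed)
    rho = float(np.dot(ca, cb) / (na * nb))

    # Permutations preserve the mean and norm of the permuted vector, so only
    # the cross product changes; vectorize as a (B, n) gather + matvec.
    rng = np.random.default_rng(test_seed)
    n = len(ca)
    perms = rng.permuted(
        np.broadcast_to(np.arange(n), (n_permutations, n)), axis=1
    )
    rho_b = (cb[perms] @ ca) / (na * nb)
    exceed = int(np.count_nonzero(np.abs(rho_b) >= abs(rho)))
    pvalue = (1.0 + exceed) / (n_permutations + 1.0)
    decision = "independent" if pvalue > alpha else "dependent"
    return CITestResult(a, b, Kt, rho, pvalue, n_permutations, decision,
                        test_seed)


def fisher_z_test(
    data: MixedDataset, j: str, l: str, K=(), alpha: float = 0.05
) -> tuple[float, float, str]:
    """Classical Fisher-z partial-correlation test (continuous data only).

    Reference procedure used to benchmark the permutation test on
    all-continuous data; not part of the estimation pipeline.
    """
    Kt = tuple(sorted(K))
    r_j = residuals(data, j, Kt)
    r_l = residuals(data, l, Kt)
    r = partial_correlation(r_j, r_l)
    n = data.n
    dof = n - len(Kt) - 3
    if dof <= 0:
        raise ValueError("too few samples for Fisher-z")
    r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    z = np.sqrt(dof) * np.arctanh(r)
    pvalue = 2.0 * scipy.stats.norm.sf(abs(z))
    decision = "independent" if pvalue > alpha else "dependent"
    return float(r), float(pvalue), decision
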
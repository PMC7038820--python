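"""Internal GLM machinery shared by the graphical-model, CI-test, and
scoring modules: design-matrix construction with reference-coded indicators,
rank-safe least squares, and a multinomial logit solver.

The multinomial solver uses reference coding: the weight vector of level 1 is
fixed at zero, so the free parameters are an (m+1) x (L-1) matrix (intercept
row first). The L1 path solver is plain proximal gradient with Nesterov
acceleration (FISTA); the unpenalized fit goes through L-BFGS on the smooth
loss. Both operate on the sum-form negative log-likelihood.
"""
from __future__ import annotations

import warnings

import numpy as np
import scipy.linalg
import scipy.optimize
from scipy.special import logsumexp

from .data import CATEGORICAL, MixedDataset

ZERO_TOL = 1e-8  # coefficients below this magnitude are exact zeros
PROB_EPS = 1e-8  # fitted-probability clamp


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def design_matrix(
    data: MixedDataset,
    predictors: list[str],
    standardize: bool = False,
):
    """Build the regression design for a set of predictor nodes.

    Continuous nodes contribute one column (optionally standardized to mean 0,
    sd 1 with ddof=0); categorical nodes contribute L-1 reference-coded
    indicator columns for levels 2..L (level 1 is the reference). Indicator
    columns are never standardized.

    Returns
    -------
    X : ndarray (n, m)
    colnames : list of str
    groups : dict mapping node name -> list of column indices
    scales : ndarray (m,) divisors applied (1.0 for indicators)
    centers : ndarray (m,) offsets subtracted (0.0 for indicators)
    """
    cols, colnames, scales, centers = [], [], [], []
    groups: dict[str, list[int]] = {}
    for name in predictors:
        start = len(cols)
        if data.is_categorical(name):
            codes = data.codes(name)
            L = data.n_levels(name)
            for k in range(2, L + 1):
                cols.append((codes == k).astype(float))
                colnames.append(f"{name}={data.levels[name][k - 1]}")
                scales.append(1.0)
                centers.append(0.0)
        else:
            col = data.column(name)
            if standardize:
                mu = col.mean()
                sd = col.std()  # ddof=0
                cols.append((col - mu) / sd)
                scales.append(sd)
                centers.append(mu)
            else:
                cols.append(col.astype(float))
                scales.append(1.0)
                centers.append(0.0)
            colnames.append(name)
        groups[name] = list(range(start, len(cols)))
    X = np.column_stack(cols) if cols else np.empty((data.n, 0))
    return X, colnames, groups, np.asarray(scales), np.asarray(centers)


def drop_collinear(X: np.ndarray, tol: float = 1e-9) -> list[int]:
    """Indices of a maximal linearly independent subset of columns.

    Uses column-pivoted QR; an implicit intercept is assumed, so columns are
    centered first (a constant column is collinear with the intercept).
    """
    if X.shape[1] == 0:
        return []
    Xc = X - X.mean(axis=0)
    norms = np.linalg.norm(Xc, axis=0)
    nonconst = np.flatnonzero(norms > tol * max(1.0, norms.max()))
    if nonconst.size == 0:
        return []
    _, R, piv = scipy.linalg.qr(Xc[:, nonconst], mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    keep = piv[diag > tol * diag[0]] if diag.size else []
    return sorted(nonconst[k] for k in keep)


# ---------------------------------------------------------------------------
# gaussian pieces
# ---------------------------------------------------------------------------

def gaussian_loglik(rss: float, n: int) -> float:
    """Profile log-likelihood of a linear model at the MLE sigma^2 = RSS/n."""
    sigma2 = max(rss / n, 1e-12)
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)


def lstsq_fit(X: np.ndarray, y: np.ndarray):
    """OLS with intercept and collinearity drop.

    Returns (coef over original columns with dropped ones set to 0,
    intercept, fitted values, kept column indices).
    """
    n = len(y)
    keep = drop_collinear(X)
    X1 = np.column_stack([np.ones(n), X[:, keep]])
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    fitted = X1 @ beta
    coef = np.zeros(X.shape[1])
    coef[keep] = beta[1:]
    return coef, float(beta[0]), fitted, keep


# ---------------------------------------------------------------------------
# multinomial logit (reference coding)
# ---------------------------------------------------------------------------

def one_hot(codes: np.ndarray, L: int) -> np.ndarray:
    Y = np.zeros((len(codes), L))
    Y[np.arange(len(codes)), codes - 1] = 1.0
    return Y


def softmax_probs(X1: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Class probabilities; level-1 logits are fixed at zero."""
    eta = np.column_stack([np.zeros(X1.shape[0]), X1 @ W])
    eta -= eta.max(axis=1, keepdims=True)
    P = np.exp(eta)
    P /= P.sum(axis=1, keepdims=True)
    return P


def multinomial_loglik(X1: np.ndarray, Y: np.ndarray, W: np.ndarray) -> float:
    eta = np.column_stack([np.zeros(X1.shape[0]), X1 @ W])
    return float(np.sum(eta * Y) - np.sum(logsumexp(eta, axis=1)))


def _neg_ll_grad(W_flat, X1, Y, shape, ridge):
    W = W_flat.reshape(shape)
    ll = multinomial_loglik(X1, Y, W)
    P = softmax_probs(X1, W)
    G = X1.T @ (P[:, 1:] - Y[:, 1:])
    obj = -ll
    if ridge > 0:
        obj += 0.5 * ridge * np.sum(W[1:] ** 2)
        G = G.copy()
        G[1:] += ridge * W[1:]
    return obj, G.ravel()


def fit_multinomial(
    X: np.ndarray,
    codes: np.ndarray,
    L: int,
    l1: float = 0.0,
    ridge: float = 0.0,
    W0: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 5000,
):
    """Fit a reference-coded multinomial logit, optionally L1-penalized.

    Minimizes ``-loglik + l1 * sum(|W[1:]|) + ridge/2 * sum(W[1:]**2)`` over
    the (m+1) x (L-1) weight matrix W (intercept row unpenalized).

    Returns (W, loglik) where loglik is the unpenalized log-likelihood at W.
    """
    n, m = X.shape
    X1 = np.column_stack([np.ones(n), X])
    Y = one_hot(codes, L)
    shape = (m + 1, L - 1)
    W = np.zeros(shape) if W0 is None else np.array(W0, dtype=float)

    if l1 == 0.0:
        res = scipy.optimize.minimize(
            _neg_ll_grad,
            W.ravel(),
            args=(X1, Y, shape, ridge),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
        )
        W = res.x.reshape(shape)
        return W, multinomial_loglik(X1, Y, W)

    # FISTA. Hessian of the softmax NLL is bounded by 0.5 * X1'X1 (in the
    # Loewner order per class block), so 0.5 * smax(X1)^2 is a valid Lipschitz
    # constant for the gradient.
    smax = np.linalg.norm(X1, 2)
    step = 1.0 / (0.5 * smax * smax + ridge + 1e-12)

    def smooth_grad(Wc):
        P = softmax_probs(X1, Wc)
        G = X1.T @ (P[:, 1:] - Y[:, 1:])
        if ridge > 0:
            G = G.copy()
            G[1:] += ridge * Wc[1:]
        return G

    def objective(Wc):
        obj = -multinomial_loglik(X1, Y, Wc) + l1 * np.sum(np.abs(Wc[1:]))
        if ridge > 0:
            obj += 0.5 * ridge * np.sum(Wc[1:] ** 2)
        return obj

    Z = W.copy()
    t = 1.0
    prev_obj = objective(W)
    for it in range(max_iter):
        G = smooth_grad(Z)
        W_new = Z - step * G
        # soft-threshold the non-intercept rows
        W_new[1:] = np.sign(W_new[1:]) * np.maximum(
            np.abs(W_new[1:]) - step * l1, 0.0
        )
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        Z = W_new + ((t - 1.0) / t_new) * (W_new - W)
        delta = np.max(np.abs(W_new - W)) if W_new.size else 0.0
        W, t = W_new, t_new
        if it % 10 == 9 or delta < tol:
            obj = objective(W)
            if obj > prev_obj + 1e-10:  # FISTA ripple: restart momentum
                Z = W.copy()
                t = 1.0
            prev_obj = min(prev_obj, obj)
            if delta < tol:
                break
    else:
        raise ConvergenceError(
            f"multinomial L1 solver did not converge in {max_iter} iterations"
        )
    W[1:][np.abs(W[1:]) < ZERO_TOL] = 0.0
    return W, multinomial_loglik(X1, Y, W)


def multinomial_intercept_mle(codes: np.ndarray, L: int):
    """Closed-form intercept-only fit: probabilities are level frequencies."""
    n = len(codes)
    freq = np.array([(codes == k).mean() for k in range(1, L + 1)])
    obs = freq > 0
    loglik = float(n * np.sum(freq[obs] * np.log(freq[obs])))
    return freq, loglik


def separation_suspected(W: np.ndarray, bound: float = 30.0) -> bool:
    """Heuristic flag for (quasi-)complete separation: diverging weights."""
    return bool(W.size) and float(np.max(np.abs(W))) > bound
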
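"""Lasso solution path and the covariance significance test for lasso.

The per-gene regression models are selected along the LARS-lasso path
under the objective

    (1 / (2n)) * ||y - X beta||^2 + lambda * ||beta||_1,

so the first knot is lambda_1 = max_j |<x_j, y>| / n for standardized
columns. At the knot where predictor j first enters the path with active
set A, the covariance statistic

    T_j = ( <y, X beta_hat(lambda_next)> - <y, X_A beta_tilde_A(lambda_next)> ) / sigma2_hat

compares the fitted covariance of the full path solution at the next knot
with that of the lasso restricted to the previously active set; under the
null that all signal variables are already in A, T_j is asymptotically
standard exponential, giving p_j = exp(-T_j).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import lars_path


@dataclass
class LassoPathResult:
    """LARS-lasso path knots, coefficients and covariance-test p-values.

    ``alphas`` are the knots in decreasing order (including the terminal
    one); ``coef_path`` has shape (p, len(alphas)). ``entry_step[j]`` is the
    column index of the first knot at which predictor j is nonzero.
    ``pvalues[j] = exp(-T_j)`` from the covariance test at j's first entry;
    predictors that never enter the path carry no p-value.
    """

    alphas: np.ndarray
    coef_path: np.ndarray
    entry_step: dict[int, int]
    pvalues: dict[int, float] = field(default_factory=dict)
    tstats: dict[int, float] = field(default_factory=dict)
    sigma2_hat: float = float("nan")
    sigma2_flagged: bool = False


def fit_lasso_path(y: np.ndarray, X: np.ndarray, max_steps: int | None = None) -> LassoPathResult:
    """Compute the LARS-lasso path of y on standardized X.

    ``max_steps`` caps the number of path steps (default
    ``min(n - 1, 100)``); the path then stops early and late-entering
    predictors simply receive no p-value downstream.
    """
    n, p = X.shape
    if p == 0:
        raise ValueError("empty design matrix")
    if max_steps is None:
        max_steps = min(n - 1, 100)
    alphas, _, coefs = lars_path(X, y, method="lasso", max_iter=max_steps)
    entry: dict[int, int] = {}
    nz = coefs != 0.0
    for j in range(p):
        hits = np.flatnonzero(nz[j])
        if hits.size:
            entry[j] = int(hits[0])
    return LassoPathResult(alphas=alphas, coef_path=coefs, entry_step=entry)


def lasso_coef_at(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Lasso solution at an arbitrary penalty, by interpolating the path.

    The lasso path is piecewise linear in lambda, so the solution at any
    lambda between knots is the linear interpolation of the bracketing
    knot solutions. For lambda above the first knot the solution is zero;
    below the terminal knot the terminal solution is returned.
    """
    alphas, _, coefs = lars_path(X, y, method="lasso")
    if lam >= alphas[0]:
        return np.zeros(X.shape[1])
    xs = alphas[::-1]
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        out[j] = np.interp(lam, xs, coefs[j, ::-1])
    return out


def _largest_support(path: LassoPathResult) -> np.ndarray:
    sizes = (path.coef_path != 0.0).sum(axis=0)
    k = int(np.argmax(sizes))
    return np.flatnonzero(path.coef_path[:, k] != 0.0)


def estimate_noise_variance(
    y: np.ndarray, X: np.ndarray, path: LassoPathResult, refit_df_min: int = 10
) -> tuple[float, bool]:
    """Residual-variance estimate for the covariance test.

    Ordinary least-squares refit on the largest support reached along the
    path when enough residual degrees of freedom remain
    (``n - |S| - 1 >= refit_df_min``; the extra 1 accounts for the centered
    response). Otherwise a plug-in from the terminal path solution's
    residual sum of squares is used and flagged.
    """
    n = y.size
    support = _largest_support(path)
    s = support.size
    if s == 0:
        return float(np.dot(y, y) / max(n - 1, 1)), False
    if n - s - 1 >= refit_df_min:
        beta, *_ = np.linalg.lstsq(X[:, support], y, rcond=None)
        rss = float(np.sum((y - X[:, support] @ beta) ** 2))
        return rss / (n - s - 1), False
    resid = y - X @ path.coef_path[:, -1]
    rss = float(np.sum(resid**2))
    return rss / max(n - s - 1, 1), True


def covariance_test(
    y: np.ndarray,
    X: np.ndarray,
    path: LassoPathResult | None = None,
    max_steps: int | None = None,
    refit_df_min: int = 10,
) -> LassoPathResult:
    """Attach covariance-test p-values to each predictor's first entry.

    For each knot k at which a new predictor enters (active set A taken
    from the knot-k solution, next knot lambda_{k+1}), computes
    ``T = (<y, X b_full(l_{k+1})> - <y, X_A b_A(l_{k+1})>) / sigma2_hat``
    and ``p = exp(-T)``. A predictor keeps the p-value of its first entry.
    """
    if path is None:
        path = fit_lasso_path(y, X, max_steps=max_steps)
    path.sigma2_hat, path.sigma2_flagged = estimate_noise_variance(
        y, X, path, refit_df_min=refit_df_min
    )
    n_knots = path.alphas.size
    # group entering predictors by entry knot; evaluate both fits at the next knot
    restricted_cache: dict[int, float] = {}
    for j, step in path.entry_step.items():
        if step >= n_knots:  # defensive; cannot happen
            continue
        lam_next = path.alphas[step]
        # active set just before entry = support of the solution at knot step-1
        if step not in restricted_cache:
            prev_support = np.flatnonzero(path.coef_path[:, step - 1] != 0.0) if step > 0 else np.array([], dtype=int)
            full_cov = float(y @ (X @ path.coef_path[:, step]))
            if prev_support.size == 0:
                restricted_cov = 0.0
            else:
                b_res = lasso_coef_at(X[:, prev_support], y, lam_next)
                restricted_cov = float(y @ (X[:, prev_support] @ b_res))
            restricted_cache[step] = full_cov - restricted_cov
        T = restricted_cache[step] / path.sigma2_hat
        T = max(T, 0.0)
        path.tstats[j] = T
        path.pvalues[j] = float(min(1.0, np.exp(-T)))
    return path
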
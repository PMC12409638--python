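"""Whittaker smoother and asPLS baseline estimation.

The baseline estimator is the adaptive smoothness penalized least squares
(asPLS) scheme: an iteratively reweighted Whittaker smoother in which points
above the running baseline are down-weighted through a logistic function of
the residual, and the roughness penalty is additionally scaled per point by
an adaptive factor ``alpha = |residual| / max|residual|`` so the baseline can
bend where the signal sits far above it.

The normal equations are banded (bandwidth = difference order), so both the
plain smoother and the asPLS iteration solve banded systems — no dense n x n
matrix is ever formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.linalg import solve_banded, solveh_banded

__all__ = ["BaselineResult", "whittaker_solve", "aspls_baseline"]


@dataclass
class BaselineResult:
    baseline: np.ndarray
    weights: np.ndarray
    iterations: int
    converged: bool


def _difference_penalty(n: int, diff_order: int) -> sparse.csr_matrix:
    """D^T D for the order-``diff_order`` forward difference matrix (n columns)."""
    if n < diff_order + 1:
        raise ValueError(f"need at least {diff_order + 1} points, got {n}")
    diff = sparse.eye(n, format="csc")
    for _ in range(diff_order):
        diff = diff[1:] - diff[:-1]
    return (diff.T @ diff).tocsr()


def whittaker_solve(y: np.ndarray, weights: np.ndarray, lam: float,
                    diff_order: int = 2,
                    penalty_scale: np.ndarray | None = None) -> np.ndarray:
    """Solve the penalized least squares problem of the Whittaker smoother.

    Minimizes ``sum_i w_i (y_i - z_i)^2 + lam * sum (D^d z)^2``.  When
    ``penalty_scale`` (the asPLS per-point ``alpha``) is given, the penalty
    matrix becomes ``lam * diag(alpha) @ D^T D`` and the (mildly asymmetric)
    system is solved with a general banded factorization; otherwise the
    symmetric positive-definite banded solver is used.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if y.ndim != 1 or y.shape != w.shape:
        raise ValueError("y and weights must be 1-D arrays of equal length")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if not np.any(w > 0):
        raise ValueError("all weights are zero: system is singular")
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    n = y.size
    dtd = _difference_penalty(n, diff_order)
    rhs = w * y
    d = diff_order
    if penalty_scale is None:
        # upper banded form for solveh_banded: ab[d - k] holds diagonal k >= 0
        ab = np.zeros((d + 1, n))
        for k in range(d + 1):
            ab[d - k, k:] = lam * dtd.diagonal(k)
        ab[d] += w
        return solveh_banded(ab, rhs, lower=False)
    alpha = np.asarray(penalty_scale, dtype=float)
    if alpha.shape != y.shape:
        raise ValueError("penalty_scale must match y")
    mat = sparse.diags(alpha) @ dtd * lam
    ab = np.zeros((2 * d + 1, n))
    for k in range(-d, d + 1):
        diag = mat.diagonal(k)
        if k >= 0:
            ab[d - k, k:] = diag
        else:
            ab[d - k, :n + k] = diag
    ab[d] += w
    return solve_banded((d, d), ab, rhs)


def aspls_baseline(y: np.ndarray, lam: float, diff_order: int = 2,
                   tol: float = 1e-3, max_iter: int = 100) -> BaselineResult:
    """Estimate a baseline by adaptive smoothness penalized least squares.

    Weights start at 1 and are updated from the residual ``r = y - z`` via
    ``w = 1 / (1 + exp(2 (r - s) / s))`` where ``s`` is the standard
    deviation of the negative residuals; the adaptive penalty factor is
    ``alpha = |r| / max |r|``.  Iteration stops when the relative change of
    the weight vector drops below ``tol``.  Non-convergence within
    ``max_iter`` is reported via ``converged=False``, not raised.
    """
    y = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("y contains NaN or infinite values")
    if lam <= 0 or tol <= 0:
        raise ValueError("lam and tol must be positive")
    n = y.size
    if n < diff_order + 1:
        raise ValueError("input shorter than diff_order + 1")
    weights = np.ones(n)
    alpha = np.ones(n)
    z = y.copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        z = whittaker_solve(y, weights, lam, diff_order, penalty_scale=alpha)
        resid = y - z
        neg = resid[resid < 0]
        sd = float(np.std(neg)) if neg.size else 0.0
        if sd <= np.finfo(float).eps * max(1.0, float(np.max(np.abs(y), initial=0.0))):
            converged = True  # residuals vanish: baseline reproduces the input
            break
        # logistic down-weighting of points above the baseline
        arg = np.clip(2.0 * (resid - sd) / sd, -500, 500)
        new_weights = 1.0 / (1.0 + np.exp(arg))
        max_abs = float(np.max(np.abs(resid)))
        alpha = np.abs(resid) / max_abs if max_abs > 0 else np.ones(n)
        denom = float(np.linalg.norm(weights))
        change = float(np.linalg.norm(new_weights - weights)) / denom if denom else 0.0
        weights = new_weights
        if change < tol:
            converged = True
            break
    return BaselineResult(baseline=z, weights=weights, iterations=iterations,
                          converged=converged)
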
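"""Core numerics for (weighted, quadratically penalized) logistic likelihoods.

Every classifier in this package maximizes an objective of the form

    J(w) = sum_i v_i * log p(y_i | x_i; w)  -  1/2 (w - m)^T P (w - m)

where ``p(y=1 | x; w) = sigmoid(w^T x)`` on augmented inputs, ``v`` are
nonnegative per-case weights, and the optional quadratic term is a Gaussian
prior with mean ``m`` and precision matrix ``P`` (positive semidefinite):
the unpenalized baseline fit has no prior, the uniform-prior adaptive fit
uses ``P = C I`` centered at the baseline discriminant, the full-Hessian
variant uses ``P = -H`` with ``H`` the baseline log-likelihood Hessian at
its optimum, and the per-training-case pretraining uses an isotropic prior
centered at an interpolated mean.  The objective is concave (strictly so
whenever ``P`` is positive definite), so damped Newton iterations from any
start converge to the global maximum.

All log-probabilities use the overflow-safe identity
``log sigmoid(t) = -log1p(exp(-t))`` evaluated branch-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "sigmoid",
    "log_sigmoid",
    "penalized_objective",
    "penalized_gradient",
    "penalized_hessian",
    "newton_maximize",
    "FitDiagnostics",
]

_RIDGE = 1e-8  # diagonal jitter for Hessian invertibility


def sigmoid(t: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.empty_like(t)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out[0] if scalar else out


def log_sigmoid(t: np.ndarray) -> np.ndarray:
    """log(sigmoid(t)) without overflow for large |t|."""
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.empty_like(t)
    pos = t >= 0
    out[pos] = -np.log1p(np.exp(-t[pos]))
    out[~pos] = t[~pos] - np.log1p(np.exp(t[~pos]))
    return out[0] if scalar else out


def _check_dims(w, X, y, weights):
    w = np.asarray(w, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[1] != w.shape[0]:
        raise ValueError(f"dimension mismatch: w has {w.shape[0]}, X has {X.shape[1]}")
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y length mismatch")
    if weights is None:
        weights = np.ones(X.shape[0])
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape[0] != X.shape[0]:
            raise ValueError("weights length must match case count")
    return w, X, y, weights


def weighted_log_likelihood(w, X, y, weights=None) -> float:
    """Weighted Bernoulli log-likelihood sum_i v_i log p(y_i | x_i; w)."""
    w, X, y, v = _check_dims(w, X, y, weights)
    t = X @ w
    # log p(y) = y*log(sig(t)) + (1-y)*log(sig(-t)) = log_sigmoid((2y-1)*t)
    return float(np.sum(v * log_sigmoid((2.0 * y - 1.0) * t)))


def penalized_objective(w, X, y, weights=None, prior_mean=None, precision=None) -> float:
    """J(w) as documented in the module docstring.

    ``precision`` may be a scalar (isotropic, ``P = c I``) or a full
    symmetric PSD matrix.  ``prior_mean`` defaults to zero when a precision
    is given.
    """
    val = weighted_log_likelihood(w, X, y, weights)
    if precision is not None:
        w = np.asarray(w, dtype=float)
        m = np.zeros_like(w) if prior_mean is None else np.asarray(prior_mean, dtype=float)
        dw = w - m
        P = np.asarray(precision, dtype=float)
        if P.ndim == 0:
            val -= 0.5 * float(P) * float(dw @ dw)
        else:
            val -= 0.5 * float(dw @ P @ dw)
    return val


def penalized_gradient(w, X, y, weights=None, prior_mean=None, precision=None) -> np.ndarray:
    w, X, y, v = _check_dims(w, X, y, weights)
    p = sigmoid(X @ w)
    g = X.T @ (v * (y - p))
    if precision is not None:
        m = np.zeros_like(w) if prior_mean is None else np.asarray(prior_mean, dtype=float)
        P = np.asarray(precision, dtype=float)
        g = g - (P * (w - m) if P.ndim == 0 else P @ (w - m))
    return g


def penalized_hessian(w, X, y, weights=None, precision=None) -> np.ndarray:
    w, X, y, v = _check_dims(w, X, y, weights)
    p = sigmoid(X @ w)
    s = v * p * (1.0 - p)
    H = -(X.T * s) @ X
    if precision is not None:
        P = np.asarray(precision, dtype=float)
        H = H - (P * np.eye(w.shape[0]) if P.ndim == 0 else P)
    return H


@dataclass
class FitDiagnostics:
    """Convergence record for a single Newton solve."""

    iterations: int = 0
    final_gradient_norm: float = np.inf
    converged: bool = False
    objective_trace: list = field(default_factory=list)
    message: str = ""


def newton_maximize(
    w0: np.ndarray,
    value,
    grad,
    hess,
    tol: float = 1e-8,
    max_iter: int = 100,
    norm_cap: float | None = None,
) -> tuple[np.ndarray, FitDiagnostics]:
    """Damped Newton ascent of a concave objective.

    Accepts a step only if the objective does not decrease (step-halving
    line search, up to 30 halvings), adds a ``1e-8`` ridge to the Hessian
    diagonal for invertibility, and stops when the gradient max-norm drops
    below ``tol``.  ``norm_cap`` guards unbounded likelihoods (perfect
    separation): if ``||w||_2`` exceeds it the solve stops with
    ``converged=False``.
    """
    w = np.asarray(w0, dtype=float).copy()
    diag = FitDiagnostics()
    f = value(w)
    diag.objective_trace.append(f)
    for it in range(1, max_iter + 1):
        g = grad(w)
        gnorm = float(np.max(np.abs(g)))
        diag.final_gradient_norm = gnorm
        diag.iterations = it - 1
        if gnorm <= tol:
            diag.converged = True
            return w, diag
        H = hess(w)
        H = H - _RIDGE * np.eye(w.shape[0])
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            step = g  # fall back to gradient ascent direction
        # step-halving: accept only non-decreasing objective
        alpha = 1.0
        for _ in range(30):
            w_new = w + alpha * step
            f_new = value(w_new)
            if np.isfinite(f_new) and f_new >= f:
                break
            alpha *= 0.5
        else:
            diag.message = "line search failed to find an ascent step"
            return w, diag
        w, f = w_new, f_new
        diag.objective_trace.append(f)
        if norm_cap is not None and np.linalg.norm(w) > norm_cap:
            diag.message = (
                "discriminant norm cap reached; likelihood is likely unbounded "
                "(separable cases)"
            )
            diag.iterations = it
            return w, diag
    g = grad(w)
    diag.final_gradient_norm = float(np.max(np.abs(g)))
    diag.iterations = max_iter
    diag.converged = diag.final_gradient_norm <= tol
    if not diag.converged:
        diag.message = f"no convergence in {max_iter} iterations"
    return w, diag
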
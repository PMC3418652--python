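"""Query-varying regularization: per-training-case discriminants and an
interpolated prior mean.

Instead of centering the adaptive prior at the single baseline vector, one
adaptive discriminant w_i is pretrained for every training case by
maximizing the coupled objective

    L~(w_1, ..., w_N) = sum_i log p(y_i | x_i; w_i)
                        - C'/2 sum_i || w_i - wbar_i ||^2,

where wbar_i = sum_{k != i} c_ik w_k is the kernel-weighted average of the
*other* cases' vectors (leave-one-out), with weights c_ik from the same
Gaussian similarity kernel used for retrieval.  Cases with similar
features are thereby pushed toward similar discriminants.  At query time
the prior mean is interpolated over all N training vectors,
wbar_Var = sum_i c_i w_i, and the per-query refit proceeds exactly as in
the uniform-prior scheme with wbar_Var in place of wbar.

The penalty is a positive-semidefinite quadratic form in the stacked
vector (w_1, ..., w_N), so the coupled objective is concave and is
maximized here by block-coordinate ascent with exact block derivatives:
the gradient of the penalty with respect to w_i includes both its own
residual w_i - wbar_i and the cross terms through the residuals of every
other case (w_i enters each wbar_k).  Each block subproblem is then a
strictly concave logistic-plus-quadratic maximization solved by damped
Newton, so the joint objective is non-decreasing at every block update
and the sweeps converge to the global maximum.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .adaptive import AdaptiveFit, _AdaptiveClassifierBase, fit_adaptive
from .baseline import BaselineLogistic
from .data import CaseLibrary, Standardizer, augment
from .logistic import (
    log_sigmoid,
    newton_maximize,
    penalized_gradient,
    penalized_hessian,
    sigmoid,
)
from .retrieval import interpolation_weights, retrieve

__all__ = [
    "VaryingPriorModel",
    "train_varying_prior",
    "prior_mean_for_query",
    "fit_adaptive_varying",
    "joint_objective",
    "joint_gradient",
    "AdaptiveVaryingClassifier",
]


def _interp_matrix(X_std: np.ndarray, sigma: float) -> np.ndarray:
    """Row-normalized leave-one-out kernel weights c_ik (diagonal zero)."""
    D2 = squareform(pdist(X_std, metric="sqeuclidean"))
    A = np.exp(-D2 / sigma**2)
    np.fill_diagonal(A, 0.0)
    rows = A.sum(axis=1, keepdims=True)
    if np.any(rows == 0):
        warnings.warn("kernel underflow in interpolation matrix; using uniform rows")
        n = A.shape[0]
        A[rows[:, 0] == 0] = 1.0
        np.fill_diagonal(A, 0.0)
        rows = A.sum(axis=1, keepdims=True)
    return A / rows


def joint_objective(W: np.ndarray, Xa: np.ndarray, y: np.ndarray,
                    Cmat: np.ndarray, C_prime: float) -> float:
    """Coupled pretraining objective for stacked vectors W of shape (N, d+1)."""
    t = np.einsum("ij,ij->i", Xa, W)
    ll = float(np.sum(log_sigmoid((2.0 * y - 1.0) * t)))
    R = W - Cmat @ W
    return ll - 0.5 * C_prime * float(np.sum(R * R))


def joint_gradient(W: np.ndarray, Xa: np.ndarray, y: np.ndarray,
                   Cmat: np.ndarray, C_prime: float) -> np.ndarray:
    """Exact gradient of the coupled objective, one row per block."""
    t = np.einsum("ij,ij->i", Xa, W)
    G_ll = Xa * (y - sigmoid(t))[:, None]
    R = W - Cmat @ W
    return G_ll - C_prime * (R - Cmat.T @ R)


@dataclass
class VaryingPriorModel:
    """Pretrained per-training-case adaptive vectors and interpolation state."""

    train_vectors: np.ndarray        # (N, d+1)
    train_features: np.ndarray       # (N, d) raw features
    standardizer: Standardizer
    C_prime: float
    sigma: float
    sweeps: int = 0
    converged: bool = False
    objective_trace: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "train_vectors": self.train_vectors.tolist(),
            "train_features": self.train_features.tolist(),
            "standardizer": self.standardizer.to_dict(),
            "C_prime": self.C_prime,
            "sigma": self.sigma,
            "sweeps": self.sweeps,
            "converged": self.converged,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "VaryingPriorModel":
        return cls(
            train_vectors=np.asarray(d["train_vectors"], dtype=float),
            train_features=np.asarray(d["train_features"], dtype=float),
            standardizer=Standardizer.from_dict(d["standardizer"]),
            C_prime=float(d["C_prime"]),
            sigma=float(d["sigma"]),
            sweeps=int(d.get("sweeps", 0)),
            converged=bool(d.get("converged", False)),
        )

    @classmethod
    def load(cls, path) -> "VaryingPriorModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _train_stacked_newton(W, Xa, y, Cmat, C_prime, tol, max_iter):
    """Damped Newton on the stacked (N*(d+1))-dimensional concave problem.

    The penalty Hessian C' (I-C)^T (I-C) (x) I is constant and the
    likelihood Hessian is block diagonal, so each iteration is one dense
    solve; quadratic convergence near the optimum.
    """
    N, p = W.shape
    M = (np.eye(N) - Cmat).T @ (np.eye(N) - Cmat)
    pen_H = C_prime * np.kron(M, np.eye(p))

    def value(wflat):
        return joint_objective(wflat.reshape(N, p), Xa, y, Cmat, C_prime)

    def grad(wflat):
        return joint_gradient(wflat.reshape(N, p), Xa, y, Cmat, C_prime).ravel()

    def hess(wflat):
        Wc = wflat.reshape(N, p)
        pr = sigmoid(np.einsum("ij,ij->i", Xa, Wc))
        s = pr * (1.0 - pr)
        H = -pen_H.copy()
        for i in range(N):
            blk = slice(i * p, (i + 1) * p)
            H[blk, blk] -= s[i] * np.outer(Xa[i], Xa[i])
        return H

    wflat, diag = newton_maximize(W.ravel(), value, grad, hess, tol=tol,
                                  max_iter=max_iter)
    return wflat.reshape(N, p), diag


def train_varying_prior(
    lib: CaseLibrary,
    C_prime: float,
    sigma: float,
    baseline: BaselineLogistic | None = None,
    tol: float = 1e-6,
    max_sweeps: int = 50,
    solver: str = "newton",
) -> VaryingPriorModel:
    """Pretrain one adaptive vector per training case (coupled objective).

    All blocks start at the baseline discriminant.  ``solver="newton"``
    (default) runs damped Newton on the stacked concave problem;
    ``solver="block"`` runs Gauss-Seidel block-coordinate ascent with
    exact block derivatives (monotone in the joint objective at every
    block update, but first-order, hence slower near the optimum).
    Stops when the joint-gradient max-norm falls below ``tol`` or after
    ``max_sweeps`` sweeps/iterations.
    """
    if C_prime <= 0:
        raise ValueError(
            "C_prime must be positive: with C_prime = 0 each single-case "
            "likelihood is unbounded"
        )
    if len(lib) < 2:
        raise ValueError("need at least 2 cases")
    if baseline is None:
        baseline = BaselineLogistic().fit(lib.features, lib.labels)
    std = baseline.standardizer_
    X_std = std.transform(lib.features)
    Xa = augment(lib.features, std)
    y = lib.labels.astype(float)
    N, p = Xa.shape
    Cmat = _interp_matrix(X_std, sigma)
    W = np.tile(baseline.coef_aug_, (N, 1))

    if solver == "newton":
        W, diag = _train_stacked_newton(W, Xa, y, Cmat, C_prime, tol, max_sweeps)
        if not diag.converged:
            warnings.warn(
                f"varying-prior pretraining: no convergence in {max_sweeps} "
                f"Newton iterations (gradient {diag.final_gradient_norm:.3g})"
            )
        return VaryingPriorModel(
            train_vectors=W,
            train_features=lib.features,
            standardizer=std,
            C_prime=C_prime,
            sigma=sigma,
            sweeps=diag.iterations,
            converged=diag.converged,
            objective_trace=diag.objective_trace,
        )
    if solver != "block":
        raise ValueError(f"unknown solver {solver!r}")

    trace = [joint_objective(W, Xa, y, Cmat, C_prime)]
    converged = False
    sweeps = 0
    max_block_grad = np.inf
    for sweep in range(1, max_sweeps + 1):
        sweeps = sweep
        for i in range(N):
            # residuals of the other blocks as linear functions of w_i:
            # r_k = b_k - c_ki * w_i for k != i
            R = W - Cmat @ W
            c_in = Cmat[:, i].copy()          # c_ki, k's weight on case i
            c_in[i] = 0.0
            b = R + np.outer(c_in, W[i])      # rows k != i give b_k
            s2 = float(c_in @ c_in)
            bc = c_in @ b                     # sum_k c_ki * b_k
            wbar_i = Cmat[i] @ W
            xi, yi = Xa[i], y[i]

            def value(u):
                t = float(xi @ u)
                ll = float(log_sigmoid(np.array((2 * yi - 1) * t)))
                du = u - wbar_i
                pen = float(du @ du) + s2 * float(u @ u) - 2.0 * float(bc @ u)
                # constant sum ||b_k||^2 omitted: irrelevant to the argmax,
                # line-search compares values at fixed block state only
                return ll - 0.5 * C_prime * pen

            def grad(u):
                pi = float(sigmoid(np.array(xi @ u)))
                g = xi * (yi - pi)
                return g - C_prime * ((u - wbar_i) + s2 * u - bc)

            def hess(u):
                pi = float(sigmoid(np.array(xi @ u)))
                Hll = -np.outer(xi, xi) * pi * (1 - pi)
                return Hll - C_prime * (1.0 + s2) * np.eye(p)

            u, diag = newton_maximize(W[i], value, grad, hess, tol=tol,
                                      max_iter=50)
            W[i] = u
        trace.append(joint_objective(W, Xa, y, Cmat, C_prime))
        # convergence is judged on the exact joint gradient at the end of
        # the sweep, not on per-block gradients that later updates stale
        max_block_grad = float(np.max(np.abs(
            joint_gradient(W, Xa, y, Cmat, C_prime)
        )))
        if max_block_grad < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"varying-prior pretraining: no convergence in {max_sweeps} sweeps "
            f"(max block gradient {max_block_grad:.3g})"
        )
    return VaryingPriorModel(
        train_vectors=W,
        train_features=lib.features,
        standardizer=std,
        C_prime=C_prime,
        sigma=sigma,
        sweeps=sweeps,
        converged=converged,
        objective_trace=trace,
    )


def prior_mean_for_query(query, model: VaryingPriorModel) -> np.ndarray:
    """Interpolated prior mean wbar_Var = sum_i c_i w_i over all N cases."""
    c = interpolation_weights(
        query, model.train_features, model.sigma, std=model.standardizer
    )
    return c @ model.train_vectors


def fit_adaptive_varying(
    query,
    retrieved,
    model: VaryingPriorModel,
    baseline: BaselineLogistic,
    C: float,
    **kwargs,
) -> AdaptiveFit:
    """Per-query refit with the query-specific prior mean."""
    mean = prior_mean_for_query(query, model)
    fit = fit_adaptive(
        query, retrieved, baseline, C=C, method="uniform", prior_mean=mean,
        **kwargs,
    )
    fit.method = "varying"
    return fit


class AdaptiveVaryingClassifier(_AdaptiveClassifierBase):
    """Case-adaptive classifier whose prior mean varies with the query.

    Parameters
    ----------
    n_r : int, default 50
        Retrieved cases per query.
    C : float, default 0.2
        Regularization strength of the per-query refit.
    C_prime : float, default 0.2
        Coupling strength of the per-training-case pretraining.
    sigma : float or None
        Bandwidth override (shared by retrieval and interpolation).
    standardize : bool, default True
    """

    def __init__(self, n_r=50, C=0.2, C_prime=0.2, sigma=None, standardize=True):
        self.n_r = n_r
        self.C = C
        self.C_prime = C_prime
        self.sigma = sigma
        self.standardize = standardize

    def fit(self, X, y, library=None, baseline=None):
        self._fit_common(X, y, library=library, baseline=baseline)
        train_lib = CaseLibrary.from_arrays(
            np.asarray(X, dtype=float), np.asarray(y, dtype=int), role="train"
        )
        self.prior_model_ = train_varying_prior(
            train_lib, C_prime=self.C_prime, sigma=self.baseline_.sigma_,
            baseline=self.baseline_,
        )
        return self

    def _query_discriminant(self, x):
        retrieved = retrieve(
            x, self.library_, self.n_r,
            std=self.baseline_.standardizer_, sigma=self.baseline_.sigma_,
        )
        return fit_adaptive_varying(
            x, retrieved, self.prior_model_, self.baseline_, C=self.C
        ).w
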
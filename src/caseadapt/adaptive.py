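"""Per-query adaptive classification with a fixed Gaussian prior.

For a query x, the N_r most similar library cases are retrieved and a
query-specific discriminant w is fitted by maximizing

    L_Uni(w) = sum_j beta_j log p(y_j | x_j; w)  -  C/2 ||w - w_bar||^2

(the default, isotropic form), or the full-Hessian variant

    L_Ada(w) ~= sum_j beta_j log p(y_j | x_j; w)
                + 1/2 (w - w_bar)^T H (w - w_bar),    H = grad^2 L(w_bar),

which keeps the exact Gaussian prior N(w_bar, (-H)^{-1}) implied by a
second-order expansion of the baseline likelihood about its optimum.  The
regularization constant C balances the retrieved evidence against fidelity
to the baseline: C = 0 retrains on the retrieved cases alone (the
non-regularized ablation), C -> infinity returns the baseline unchanged.
The query itself is then scored with sigmoid(w^T x).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .baseline import BaselineLogistic
from .data import CaseLibrary, augment
from .logistic import (
    FitDiagnostics,
    newton_maximize,
    penalized_gradient,
    penalized_hessian,
    penalized_objective,
    sigmoid,
)
from .retrieval import RetrievalResult, retrieve

__all__ = [
    "AdaptiveFit",
    "objective_uniform",
    "objective_full_hessian",
    "fit_adaptive",
    "classify_query",
    "AdaptiveUniformClassifier",
]

_NORM_CAP = 1e6  # guard for unbounded likelihoods with C = 0


@dataclass
class AdaptiveFit:
    """A per-query discriminant with provenance."""

    w: np.ndarray
    method: str
    C: float | None
    n_r: int
    diagnostics: FitDiagnostics = field(default_factory=FitDiagnostics)


def _retrieved_design(retrieved: RetrievalResult, baseline: BaselineLogistic):
    """Augmented standardized features, labels, beta weights of retrieved cases."""
    Xa = augment(retrieved.features, baseline.standardizer_)
    return Xa, retrieved.labels.astype(float), retrieved.beta


def objective_uniform(w, retrieved: RetrievalResult, baseline: BaselineLogistic,
                      C: float) -> float:
    """Similarity-weighted retrieved log-likelihood minus (C/2)||w - w_bar||^2."""
    if C < 0:
        raise ValueError("C must be nonnegative")
    Xa, y, beta = _retrieved_design(retrieved, baseline)
    return penalized_objective(
        w, Xa, y, weights=beta, prior_mean=baseline.coef_aug_, precision=C,
    )


def objective_full_hessian(w, retrieved: RetrievalResult,
                           baseline: BaselineLogistic) -> float:
    """Retrieved log-likelihood plus the baseline's quadratic expansion term.

    The quadratic uses the (negative semidefinite) Hessian of the baseline
    log-likelihood at its optimum, i.e. the prior precision is -H.
    """
    H = baseline.hessian_
    if not np.allclose(H, H.T, atol=1e-8):
        raise ValueError("baseline Hessian is not symmetric; model integrity error")
    Xa, y, beta = _retrieved_design(retrieved, baseline)
    return penalized_objective(
        w, Xa, y, weights=beta, prior_mean=baseline.coef_aug_, precision=-H,
    )


def fit_adaptive(
    query,
    retrieved: RetrievalResult,
    baseline: BaselineLogistic,
    C: float = 0.2,
    method: str = "uniform",
    prior_mean=None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> AdaptiveFit:
    """Maximize the selected adaptive objective by damped Newton from w_bar.

    ``method`` is ``"uniform"`` (isotropic prior, strength C),
    ``"full_hessian"`` (prior precision -grad^2 L(w_bar)), or ``"none"``
    (C = 0: weighted refit on the retrieved cases alone, guarded by a
    norm cap against separable-retrieved-set divergence).  ``prior_mean``
    overrides the prior center (used by the varying-prior classifier);
    default is the baseline discriminant.
    """
    if len(retrieved) == 0:
        raise ValueError("retrieved set must be nonempty")
    Xa, y, beta = _retrieved_design(retrieved, baseline)
    mean = baseline.coef_aug_ if prior_mean is None else np.asarray(prior_mean, float)
    if method == "none":
        C = 0.0
        precision = None
    elif method == "uniform":
        if C < 0:
            raise ValueError("C must be nonnegative for method='uniform'")
        precision = C if C > 0 else None
    elif method == "full_hessian":
        precision = -baseline.hessian_
        C = None
    else:
        raise ValueError(f"unknown method {method!r}")

    def value(w):
        return penalized_objective(w, Xa, y, beta, mean, precision)

    def grad(w):
        return penalized_gradient(w, Xa, y, beta, mean, precision)

    def hess(w):
        return penalized_hessian(w, Xa, y, beta, precision)

    w0 = mean.copy()
    w, diag = newton_maximize(
        w0, value, grad, hess, tol=tol, max_iter=max_iter,
        norm_cap=_NORM_CAP if precision is None else None,
    )
    return AdaptiveFit(w=w, method=method, C=C, n_r=len(retrieved), diagnostics=diag)


def classify_query(
    query,
    lib: CaseLibrary,
    baseline: BaselineLogistic,
    n_r: int = 50,
    C: float = 0.2,
    method: str = "uniform",
    exclude_id: str | None = None,
) -> float:
    """Full per-query pipeline: retrieve, weight, refit, score.

    Returns the estimated probability of malignancy for the query.  A pure
    function of its inputs; the baseline model is never mutated.
    """
    retrieved = retrieve(
        query, lib, n_r, std=baseline.standardizer_, sigma=baseline.sigma_,
        exclude_id=exclude_id,
    )
    fit = fit_adaptive(query, retrieved, baseline, C=C, method=method)
    xq = augment(np.asarray(query, dtype=float), baseline.standardizer_)
    return float(sigmoid(xq @ fit.w))


class _AdaptiveClassifierBase(BaseEstimator, ClassifierMixin):
    """Shared fit/predict plumbing for the per-query adaptive classifiers.

    ``fit(X, y, library=(X_lib, y_lib))`` trains the baseline on (X, y)
    and stores the retrieval library; if no library is given the training
    cases double as the library.  ``predict_proba`` runs the per-query
    pipeline for every row.
    """

    def _fit_common(self, X, y, library=None, baseline=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.array([0, 1])
        if baseline is not None:
            self.baseline_ = baseline
        else:
            self.baseline_ = BaselineLogistic(
                standardize=self.standardize, sigma=self.sigma
            ).fit(X, y)
        if library is None:
            X_lib, y_lib = X, y
        else:
            X_lib, y_lib = library
        self.library_ = CaseLibrary.from_arrays(
            np.asarray(X_lib, dtype=float), np.asarray(y_lib, dtype=int),
            role="retrieval",
        )
        return self

    def _query_discriminant(self, x) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def predict_proba(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        p1 = np.empty(X.shape[0])
        for i, x in enumerate(X):
            w = self._query_discriminant(x)
            xa = augment(x, self.baseline_.standardizer_)
            p1[i] = sigmoid(xa @ w)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class AdaptiveUniformClassifier(_AdaptiveClassifierBase):
    """Case-adaptive classifier with a fixed (query-independent) prior.

    Parameters
    ----------
    n_r : int, default 50
        Number of retrieved similar cases per query.
    C : float, default 0.2
        Regularization strength (ignored for ``method="full_hessian"`` and
        forced to 0 for ``method="none"``).
    method : {"uniform", "full_hessian", "none"}, default "uniform"
    sigma : float or None
        Similarity bandwidth override; None uses the baseline's
        percentile rule.
    standardize : bool, default True
    """

    def __init__(self, n_r=50, C=0.2, method="uniform", sigma=None,
                 standardize=True):
        self.n_r = n_r
        self.C = C
        self.method = method
        self.sigma = sigma
        self.standardize = standardize

    def fit(self, X, y, library=None, baseline=None):
        return self._fit_common(X, y, library=library, baseline=baseline)

    def _query_discriminant(self, x):
        retrieved = retrieve(
            x, self.library_, self.n_r,
            std=self.baseline_.standardizer_, sigma=self.baseline_.sigma_,
        )
        return fit_adaptive(
            x, retrieved, self.baseline_, C=self.C, method=self.method
        ).w
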
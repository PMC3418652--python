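"""Non-regularized case-adaptive classifier by full retraining (Ada-LR).

The earlier adaptive scheme this package's regularized classifiers are
compared against: for each query, the classifier is retrained on *all* N
baseline training cases plus the N_r retrieved cases, with the retrieved
cases emphasized by similarity-dependent weights greater than 1,

    L_Ada(w) = sum_i log p(y_i | x_i; w)
               + sum_j beta_j log p(y_j | x_j; w),    beta_j > 1.

The emphasis rule used here is beta_j = 1 + kappa * exp(-d_j^2 / sigma^2)
(kappa > 0, so beta in (1, 1 + kappa]); it realizes the required
properties — larger than 1, decreasing with distance to the query — with a
declared parametric form.  Zero emphasis (beta_j = 0 for all j) reduces
the objective to the plain baseline likelihood.
"""

from __future__ import annotations

import numpy as np

from .adaptive import AdaptiveFit, _AdaptiveClassifierBase
from .data import CaseLibrary, augment
from .logistic import (
    newton_maximize,
    penalized_gradient,
    penalized_hessian,
    penalized_objective,
)
from .retrieval import RetrievalResult, retrieve

__all__ = ["fit_ada_lr", "emphasis_weights", "AdaLRClassifier"]


def emphasis_weights(distances, sigma: float, kappa: float = 1.0) -> np.ndarray:
    """Similarity-decreasing emphasis weights in (1, 1 + kappa]."""
    d = np.asarray(distances, dtype=float)
    return 1.0 + kappa * np.exp(-(d**2) / sigma**2)


def fit_ada_lr(
    query,
    retrieved: RetrievalResult,
    train_lib: CaseLibrary,
    baseline,
    emphasis=None,
    kappa: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> AdaptiveFit:
    """Retrain on training set + emphasized retrieved cases by damped Newton.

    ``emphasis`` may be an explicit weight vector for the retrieved cases
    (e.g. all zeros to reduce to the baseline); by default it is
    :func:`emphasis_weights` of the retrieval distances.
    """
    std = baseline.standardizer_
    X_tr = augment(train_lib.features, std)
    y_tr = train_lib.labels.astype(float)
    if len(retrieved):
        if emphasis is None:
            emphasis = emphasis_weights(retrieved.distances, baseline.sigma_, kappa)
        else:
            emphasis = np.asarray(emphasis, dtype=float)
        X_r = augment(retrieved.features, std)
        y_r = retrieved.labels.astype(float)
        X = np.vstack([X_tr, X_r])
        y = np.concatenate([y_tr, y_r])
        v = np.concatenate([np.ones(len(y_tr)), emphasis])
    else:
        X, y, v = X_tr, y_tr, np.ones(len(y_tr))

    def value(w):
        return penalized_objective(w, X, y, v)

    def grad(w):
        return penalized_gradient(w, X, y, v)

    def hess(w):
        return penalized_hessian(w, X, y, v)

    w, diag = newton_maximize(
        baseline.coef_aug_, value, grad, hess, tol=tol, max_iter=max_iter,
        norm_cap=1e6,
    )
    return AdaptiveFit(w=w, method="full_retrain", C=None, n_r=len(retrieved),
                       diagnostics=diag)


class AdaLRClassifier(_AdaptiveClassifierBase):
    """Per-query full-retrain adaptive classifier (comparison arm).

    Parameters
    ----------
    n_r : int, default 50
        Retrieved cases per query.
    kappa : float, default 1.0
        Emphasis magnitude; retrieved-case weights lie in (1, 1 + kappa].
    sigma : float or None
        Bandwidth override.
    standardize : bool, default True
    """

    def __init__(self, n_r=50, kappa=1.0, sigma=None, standardize=True):
        self.n_r = n_r
        self.kappa = kappa
        self.sigma = sigma
        self.standardize = standardize

    def fit(self, X, y, library=None, baseline=None):
        self._fit_common(X, y, library=library, baseline=baseline)
        self.train_lib_ = CaseLibrary.from_arrays(
            np.asarray(X, dtype=float), np.asarray(y, dtype=int), role="train"
        )
        return self

    def _query_discriminant(self, x):
        retrieved = retrieve(
            x, self.library_, self.n_r,
            std=self.baseline_.standardizer_, sigma=self.baseline_.sigma_,
        )
        return fit_ada_lr(
            x, retrieved, self.train_lib_, self.baseline_, kappa=self.kappa
        ).w
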
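"""Baseline logistic-regression classifier fitted by damped Newton-Raphson.

The baseline discriminant w̄ maximizes the unpenalized log-likelihood

    L(w) = sum_i log p(y_i | x_i; w),      p(y=1 | x; w) = sigmoid(w^T x),

over augmented, standardized inputs.  Besides w̄ the fitted model keeps the
log-likelihood Hessian at the optimum — the curvature that defines the
Gaussian prior N(w̄, [-∇²L(w̄)]⁻¹) used by the adaptive classifiers — the
feature standardizer, and the similarity bandwidth σ (10th percentile of
pairwise training distances unless overridden).
"""

from __future__ import annotations

import json
import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .data import CaseLibrary, Standardizer, augment, fit_standardizer
from .logistic import (
    FitDiagnostics,
    newton_maximize,
    penalized_gradient,
    penalized_hessian,
    sigmoid,
    weighted_log_likelihood,
)
from .retrieval import select_sigma

__all__ = [
    "BaselineLogistic",
    "BaselineModel",
    "fit_baseline",
    "log_likelihood",
    "predict_probability",
]


def log_likelihood(w, cases: CaseLibrary, std: Standardizer | None = None, weights=None) -> float:
    """Log-likelihood of a case library under discriminant ``w``.

    ``w`` has length d+1 (bias first); features are standardized with
    ``std`` (if given) and augmented before scoring.
    """
    X = augment(cases.features, std)
    return weighted_log_likelihood(w, X, cases.labels, weights)


def predict_probability(w, x_aug) -> float | np.ndarray:
    """Probability of malignancy sigmoid(w^T x) for augmented input(s)."""
    w = np.asarray(w, dtype=float)
    x_aug = np.asarray(x_aug, dtype=float)
    if x_aug.shape[-1] != w.shape[0]:
        raise ValueError(
            f"dimension mismatch: w has {w.shape[0]}, x has {x_aug.shape[-1]}"
        )
    out = sigmoid(x_aug @ w)
    return float(out) if out.ndim == 0 else out


class BaselineLogistic(BaseEstimator, ClassifierMixin):
    """Unpenalized logistic regression via damped Newton, sklearn-style.

    Parameters
    ----------
    standardize : bool, default True
        Z-score features with training-split statistics (sample sd) before
        augmentation; retrieval distances use the same space.
    tol : float, default 1e-8
        Convergence threshold on the gradient max-norm.
    max_iter : int, default 100
        Newton iteration cap.
    sigma : float or None, default None
        Similarity bandwidth; None applies the percentile rule below.
    sigma_percentile : float, default 10
        Percentile of pairwise training distances used when ``sigma`` is
        None.

    Attributes
    ----------
    coef_aug_ : ndarray of shape (d+1,)
        Fitted discriminant w̄; ``coef_aug_[0]`` is the bias.
    hessian_ : ndarray of shape (d+1, d+1)
        ∇²L(w̄), symmetric negative semidefinite.
    standardizer_ : Standardizer
    sigma_ : float
    diagnostics_ : FitDiagnostics
    """

    def __init__(self, standardize=True, tol=1e-8, max_iter=100,
                 sigma=None, sigma_percentile=10.0):
        self.standardize = standardize
        self.tol = tol
        self.max_iter = max_iter
        self.sigma = sigma
        self.sigma_percentile = sigma_percentile

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError(
                f"both classes must be present with labels {{0,1}}; got {classes.tolist()}"
            )
        self.classes_ = np.array([0, 1])
        d = X.shape[1]
        if X.shape[0] < d + 2:
            warnings.warn(
                f"only {X.shape[0]} cases for {d + 1} parameters; fit may be unstable"
            )
        lib = CaseLibrary.from_arrays(X, y, role="train")
        if self.standardize:
            self.standardizer_ = fit_standardizer(lib)
        else:
            self.standardizer_ = Standardizer.identity(d)
        Xa = augment(X, self.standardizer_)

        def value(w):
            return weighted_log_likelihood(w, Xa, y, sample_weight)

        def grad(w):
            return penalized_gradient(w, Xa, y, sample_weight)

        def hess(w):
            return penalized_hessian(w, Xa, y, sample_weight)

        w0 = np.zeros(d + 1)
        w, diag = newton_maximize(
            w0, value, grad, hess, tol=self.tol, max_iter=self.max_iter,
            norm_cap=1e6,
        )
        # on separable data the gradient vanishes as ||w|| -> inf, so a
        # gradient test alone reports success with an absurdly large w;
        # treat an exploding norm as non-convergence
        # threshold in z-scored space: |w| ~ 50 means odds ratios ~ e^50
        # per sd, i.e. deterministic classification
        if diag.converged and np.linalg.norm(w) > 50.0:
            diag.converged = False
            diag.message = "coefficient norm exploded; data likely separable"
        if not diag.converged:
            warnings.warn(
                "baseline fit did not converge "
                f"(grad max-norm {diag.final_gradient_norm:.3g}); "
                "perfect separation drives ||w|| to infinity"
            )
        self.coef_aug_ = w
        self.hessian_ = penalized_hessian(w, Xa, y, sample_weight)
        self.diagnostics_ = diag
        self.n_iter_ = diag.iterations
        self.converged_ = diag.converged
        self.train_size_ = X.shape[0]
        if self.sigma is not None:
            self.sigma_ = float(self.sigma)
        else:
            self.sigma_ = select_sigma(
                lib, percentile=self.sigma_percentile, std=self.standardizer_
            )
        return self

    @property
    def coef_raw_(self) -> np.ndarray:
        """Fitted discriminant expressed in raw (unstandardized) feature space.

        Undoes the z-scoring so the returned vector is directly comparable
        with a generative-model discriminant on raw features:
        slope_k = w_k / scale_k, bias = w_0 - sum_k w_k mean_k / scale_k.
        """
        w = self.coef_aug_
        m, s = self.standardizer_.mean, self.standardizer_.scale
        slopes = w[1:] / s
        bias = w[0] - float(np.sum(w[1:] * m / s))
        return np.concatenate(([bias], slopes))

    def decision_function(self, X):
        Xa = augment(np.asarray(X, dtype=float), self.standardizer_)
        return Xa @ self.coef_aug_

    def predict_proba(self, X):
        p1 = sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.decision_function(X) >= 0).astype(int)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "coef_aug": self.coef_aug_.tolist(),
            "hessian": self.hessian_.tolist(),
            "standardizer": self.standardizer_.to_dict(),
            "sigma": self.sigma_,
            "train_size": self.train_size_,
            "params": self.get_params(),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "BaselineLogistic":
        model = cls(**d.get("params", {}))
        model.coef_aug_ = np.asarray(d["coef_aug"], dtype=float)
        model.hessian_ = np.asarray(d["hessian"], dtype=float)
        model.standardizer_ = Standardizer.from_dict(d["standardizer"])
        model.sigma_ = float(d["sigma"])
        model.train_size_ = int(d["train_size"])
        model.classes_ = np.array([0, 1])
        model.diagnostics_ = FitDiagnostics(converged=True)
        model.converged_ = True
        return model

    @classmethod
    def load(cls, path) -> "BaselineLogistic":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# Alias matching the domain vocabulary: a fitted BaselineLogistic *is* the
# baseline model (w̄, Hessian, standardizer, σ).
BaselineModel = BaselineLogistic


def fit_baseline(lib: CaseLibrary, **opts) -> tuple[BaselineLogistic, FitDiagnostics]:
    """Fit the baseline classifier on a case library.

    Thin functional wrapper over :class:`BaselineLogistic`.
    """
    model = BaselineLogistic(**opts).fit(lib.features, lib.labels)
    return model, model.diagnostics_
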
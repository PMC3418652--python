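"""Nearest-case retrieval and Gaussian similarity weighting.

Similar cases are the N_r library cases nearest the query by Euclidean
distance in standardized feature space.  Each retrieved case j gets a
normalized similarity weight

    beta_j = gamma_j / sum_k gamma_k,   gamma_j = exp(-d_j^2 / sigma^2),

so closer cases carry more weight in the adaptive refit; the same kernel
(over *all* training cases) provides the interpolation weights c_i used to
form a query-specific prior mean.  The bandwidth sigma defaults to the
10th percentile of the pairwise distances among training cases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .data import CaseLibrary, CaseRecord, Standardizer

__all__ = [
    "RetrievalResult",
    "select_sigma",
    "retrieve",
    "similarity_weights",
    "interpolation_weights",
]


@dataclass
class RetrievalResult:
    """Ordered retrieved cases with distances and normalized weights."""

    cases: list
    distances: np.ndarray
    beta: np.ndarray

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if not (len(self.cases) == len(self.distances) == len(self.beta)):
            raise ValueError("cases, distances and beta must have equal length")

    def __len__(self) -> int:
        return len(self.cases)

    @property
    def features(self) -> np.ndarray:
        return np.array([c.features for c in self.cases], dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return np.array([c.label for c in self.cases], dtype=int)


def select_sigma(
    lib: CaseLibrary,
    percentile: float = 10.0,
    std: Standardizer | None = None,
) -> float:
    """Bandwidth rule: a percentile of all pairwise training distances.

    Computes the given percentile (linear interpolation between order
    statistics) of the N(N-1)/2 Euclidean inter-distances among the
    library's standardized features.
    """
    if len(lib) < 2:
        raise ValueError("need at least 2 cases to compute pairwise distances")
    X = lib.features
    if std is not None:
        X = std.transform(X)
    dists = pdist(X, metric="euclidean")
    return float(np.percentile(dists, percentile))


def similarity_weights(distances, sigma: float) -> np.ndarray:
    """Normalized Gaussian similarity weights beta over retrieved cases.

    Falls back to uniform weights with a warning if every kernel value
    underflows to zero (all distances vastly larger than sigma).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one distance")
    gamma = np.exp(-(d**2) / sigma**2)
    total = gamma.sum()
    if total == 0.0:
        warnings.warn(
            "all similarity kernel values underflowed; using uniform weights"
        )
        return np.full(d.shape, 1.0 / d.size)
    return gamma / total


def retrieve(
    query,
    lib: CaseLibrary,
    n_r: int,
    std: Standardizer | None = None,
    sigma: float | None = None,
    exclude_id: str | None = None,
) -> RetrievalResult:
    """Retrieve the ``n_r`` nearest library cases to a query feature vector.

    Distances are Euclidean in the standardizer's space; ties at the
    boundary break by library order.  A case whose id equals
    ``exclude_id`` is never returned (a test case must not retrieve
    itself).  If ``sigma`` is given, similarity weights are attached;
    otherwise ``beta`` is uniform placeholder weights recomputed by the
    caller.
    """
    if len(lib) == 0:
        raise ValueError("cannot retrieve from an empty library")
    if n_r < 1:
        raise ValueError("n_r must be >= 1")
    query = np.asarray(query, dtype=float)
    records = lib.records
    X = lib.features
    if exclude_id is not None:
        keep = [i for i, r in enumerate(records) if r.id != exclude_id]
        records = [records[i] for i in keep]
        X = X[keep]
        if not records:
            raise ValueError("library is empty after excluding the query id")
    if std is not None:
        X = std.transform(X)
        query = std.transform(query)
    dists = cdist(query[None, :], X, metric="euclidean")[0]
    if n_r > len(records):
        warnings.warn(
            f"n_r={n_r} exceeds library size {len(records)}; returning all cases"
        )
        n_r = len(records)
    # stable sort => ties broken by library index
    order = np.argsort(dists, kind="stable")[:n_r]
    sel_d = dists[order]
    sel_cases = [records[i] for i in order]
    if sigma is not None:
        beta = similarity_weights(sel_d, sigma)
    else:
        beta = np.full(n_r, 1.0 / n_r)
    return RetrievalResult(cases=sel_cases, distances=sel_d, beta=beta)


def interpolation_weights(
    query,
    lib_features: np.ndarray,
    sigma: float,
    std: Standardizer | None = None,
) -> np.ndarray:
    """Kernel interpolation weights c over all given cases.

    c_i = alpha_i / sum_k alpha_k with alpha_i = exp(-||x - x_i||^2 / sigma^2);
    identical in form to :func:`similarity_weights` but evaluated over the
    whole training set rather than a retrieved subset.
    """
    X = np.asarray(lib_features, dtype=float)
    query = np.asarray(query, dtype=float)
    if std is not None:
        X = std.transform(X)
        query = std.transform(query)
    d = cdist(query[None, :], X, metric="euclidean")[0]
    return similarity_weights(d, sigma)
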
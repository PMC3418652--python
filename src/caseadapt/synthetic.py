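"""Synthetic case-library generator emulating the CADx study regime.

Real CADx case libraries (lesion feature vectors with biopsy-proven
labels) are not publicly available, so this module generates feature
tables with the same shape: nine real-valued features per case, two
classes with unequal prevalence, and a three-way split into training set
(100 benign / 75 malignant), test set (100 / 75) and retrieval library
(446 / 210).

Features are drawn from a standard multivariate Gaussian.  Two label
mechanisms are supported:

* ``global_linear`` — one logistic model ``P(y=1|x) = sigmoid(w_true^T x~)``
  (``x~`` augmented with the constant 1) holds everywhere; a single linear
  classifier is Bayes-optimal up to estimation noise.
* ``locally_varying`` — feature space is partitioned into K regions (the
  Voronoi cells of K random anchor directions) and each region has its own
  local discriminant ``w_k``; labels are Bernoulli with the local logit.
  The class boundary therefore bends from region to region: a single
  global linear classifier is systematically biased, while a classifier
  refitted in the neighborhood of a query can recover the local boundary.
  This is exactly the regime case-adaptive classification is built for.

``global_linear`` is implemented as the degenerate case in which all K
local discriminants coincide, so the two mechanisms are byte-identical
when the local vectors are equal — a useful collapse property for tests.
The generative model is recorded as metadata, giving an analytic Bayes
scorer (``oracle_scores``) whose AUC upper-bounds every classifier.

Labels divided by ``noise_scale`` sharpen (→0) or flatten (→∞) the
logits; the default 1.0 with slope norm 2.5 yields a Bayes AUC around
0.9 and a realistic amount of label noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .data import CaseLibrary, CaseRecord, augment
from .logistic import sigmoid

__all__ = [
    "SyntheticSpec",
    "SyntheticMetadata",
    "generate",
    "oracle_scores",
    "oracle_bayes_auc",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters; defaults mirror the study's split sizes."""

    train_counts: tuple = (100, 75)     # (benign, malignant)
    test_counts: tuple = (100, 75)
    library_counts: tuple = (446, 210)
    d: int = 9
    boundary: str = "locally_varying"   # or "global_linear"
    n_clusters: int = 4
    signal: float = 2.5                 # slope norm of each local discriminant
    noise_scale: float = 1.0            # logits are divided by this
    seed: int = 0

    def __post_init__(self):
        for counts in (self.train_counts, self.test_counts, self.library_counts):
            if len(counts) != 2 or min(counts) < 1:
                raise ValueError("each split needs positive benign and malignant counts")
        if self.boundary not in ("global_linear", "locally_varying"):
            raise ValueError(f"unknown boundary {self.boundary!r}")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")

    @property
    def n_train(self) -> int:
        return sum(self.train_counts)

    @property
    def n_test(self) -> int:
        return sum(self.test_counts)

    @property
    def n_library(self) -> int:
        return sum(self.library_counts)


@dataclass
class SyntheticMetadata:
    """The true generative model, for oracle scoring and recovery tests."""

    anchors: np.ndarray        # (K, d) region anchor points
    local_w: np.ndarray        # (K, d+1) augmented local discriminants
    boundary: str
    noise_scale: float
    spec: SyntheticSpec | None = None

    @property
    def w_true(self) -> np.ndarray:
        """The single global discriminant (meaningful for global_linear)."""
        return self.local_w[0]


def _assign_regions(X: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    return np.argmin(cdist(X, anchors), axis=1)


def _true_logits(X: np.ndarray, meta: SyntheticMetadata) -> np.ndarray:
    k = _assign_regions(X, meta.anchors)
    Xa = augment(X)
    return np.einsum("ij,ij->i", Xa, meta.local_w[k]) / meta.noise_scale


def oracle_scores(X, meta: SyntheticMetadata) -> np.ndarray:
    """True-model P(y=1 | x) — the Bayes scorer of the generator."""
    return sigmoid(_true_logits(np.asarray(X, dtype=float), meta))


def generate(spec: SyntheticSpec):
    """Generate (train, test, library) case libraries plus metadata.

    Candidates are drawn from the generative model and assigned, in draw
    order, to the first split whose per-class quota is still open
    (train, then test, then library), so every split hits its class
    counts exactly.  Fully deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    K, d = spec.n_clusters, spec.d

    anchors = rng.standard_normal((K, d))
    anchors /= np.linalg.norm(anchors, axis=1, keepdims=True)
    slopes = rng.standard_normal((K, d))
    slopes *= spec.signal / np.linalg.norm(slopes, axis=1, keepdims=True)
    local_w = np.hstack([np.zeros((K, 1)), slopes])  # zero local intercepts
    if spec.boundary == "global_linear":
        local_w = np.tile(local_w[0], (K, 1))
    meta = SyntheticMetadata(
        anchors=anchors, local_w=local_w, boundary=spec.boundary,
        noise_scale=spec.noise_scale, spec=spec,
    )

    quotas = {
        "train": list(spec.train_counts),
        "test": list(spec.test_counts),
        "retrieval": list(spec.library_counts),
    }
    buckets = {name: [] for name in quotas}
    order = ["train", "test", "retrieval"]
    counter = 0
    while any(q[0] or q[1] for q in quotas.values()):
        X = rng.standard_normal((512, d))
        p = sigmoid(_true_logits(X, meta))
        y = (rng.random(512) < p).astype(int)
        for x, lab in zip(X, y):
            for name in order:
                if quotas[name][lab] > 0:
                    quotas[name][lab] -= 1
                    buckets[name].append(CaseRecord(f"syn-{counter}", x, int(lab)))
                    counter += 1
                    break

    libs = {
        name: CaseLibrary(buckets[name], role=name) for name in order
    }
    return libs["train"], libs["test"], libs["retrieval"], meta


def oracle_bayes_auc(test: CaseLibrary, meta: SyntheticMetadata) -> float:
    """AUC of the true-model probabilities on a generated split.

    Upper reference for every classifier (up to sampling noise of the
    finite split).
    """
    from .evaluation import ScoredTestSet, compute_auc

    scores = oracle_scores(test.features, meta)
    return compute_auc(ScoredTestSet(scores, test.labels, tag="oracle"))
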
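"""Empirical ROC/AUC evaluation with bootstrap resampling.

AUC is the empirical (Mann-Whitney) statistic
P(score_pos > score_neg) + 1/2 P(tie), computed from ranks; confidence
intervals come from case-level bootstrap resampling (percentile method,
default 2000 resamples), and classifier comparisons use a paired bootstrap
on the shared test cases.  Hyperparameters (the regularization strengths)
are chosen by stratified k-fold cross-validation on the training split,
maximizing mean validation AUC over a candidate grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ScoredTestSet",
    "EvaluationReport",
    "compute_auc",
    "roc_curve",
    "bootstrap_auc",
    "paired_bootstrap_compare",
    "select_by_cv",
    "stratified_folds",
]

#: Candidate grid for the regularization strengths C and C'.
DEFAULT_PARAM_GRID = (0.001, 0.01, 0.05, 0.1, 0.2, 0.5, 1.0, 5.0, 10.0, 100.0)


@dataclass
class ScoredTestSet:
    """Per-case malignancy scores with true labels for one classifier."""

    scores: np.ndarray
    labels: np.ndarray
    tag: str = ""

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape[0] != self.labels.shape[0]:
            raise ValueError("scores and labels length mismatch")

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class EvaluationReport:
    auc: float
    bootstrap_ci: tuple
    n_boot: int
    seed: int
    tag: str = ""
    paired_p: float | None = None
    n_redrawn: int = 0


def _auc_from_arrays(scores: np.ndarray, labels: np.ndarray) -> float:
    n_pos = int(labels.sum())
    n_neg = labels.shape[0] - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: only one class present")
    ranks = rankdata(scores)  # average ranks handle ties
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def compute_auc(scored: ScoredTestSet) -> float:
    """Empirical AUC via the rank (Mann-Whitney) statistic."""
    return _auc_from_arrays(scored.scores, scored.labels)


def roc_curve(scored: ScoredTestSet) -> np.ndarray:
    """Stepwise empirical ROC as ordered (FPR, TPR) points from (0,0) to (1,1).

    The trapezoidal area under the returned polyline equals the rank AUC
    (ties produce diagonal segments).
    """
    scores, labels = scored.scores, scored.labels
    n_pos = int(labels.sum())
    n_neg = labels.shape[0] - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: only one class present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # group ties: one ROC vertex per distinct threshold
    distinct = np.flatnonzero(np.diff(s)) if len(s) > 1 else np.array([], dtype=int)
    ends = np.append(distinct, len(s) - 1)
    tp = np.cumsum(y)[ends]
    fp = (ends + 1) - tp
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    return np.column_stack([fpr, tpr])


def bootstrap_auc(
    scored: ScoredTestSet,
    n_boot: int = 2000,
    seed: int = 0,
) -> EvaluationReport:
    """Percentile bootstrap CI for the AUC (case resampling).

    Resamples with a single class are redrawn (and counted); if more than
    half of the attempted resamples are single-class the test set is too
    small or imbalanced and an error is raised.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(scored)
    aucs = np.empty(n_boot)
    redrawn = 0
    attempts = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            labs = scored.labels[idx]
            attempts += 1
            if 0 < labs.sum() < n:
                break
            redrawn += 1
            if attempts >= 20 and redrawn > 0.5 * attempts:
                raise ValueError(
                    "more than half of bootstrap resamples were single-class; "
                    "use a larger test set"
                )
        aucs[b] = _auc_from_arrays(scored.scores[idx], labs)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return EvaluationReport(
        auc=compute_auc(scored),
        bootstrap_ci=(float(lo), float(hi)),
        n_boot=n_boot,
        seed=seed,
        tag=scored.tag,
        n_redrawn=redrawn,
    )


def paired_bootstrap_compare(
    scored_a: ScoredTestSet,
    scored_b: ScoredTestSet,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Two-sided paired bootstrap p-value for the AUC difference (a - b).

    Both score sets must cover the same cases in the same order; resampling
    is joint, so per-case correlation between the classifiers is retained.
    p = 2 * min(frac(dAUC <= 0), frac(dAUC >= 0)) with an (n_boot + 1)
    denominator correction, capped at 1.
    """
    if len(scored_a) != len(scored_b) or not np.array_equal(
        scored_a.labels, scored_b.labels
    ):
        raise ValueError("paired comparison requires identical cases and labels")
    rng = np.random.default_rng(seed)
    n = len(scored_a)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(1000):
            idx = rng.integers(0, n, size=n)
            labs = scored_a.labels[idx]
            if 0 < labs.sum() < n:
                break
        else:
            raise ValueError("could not draw a two-class bootstrap resample")
        deltas[b] = _auc_from_arrays(scored_a.scores[idx], labs) - _auc_from_arrays(
            scored_b.scores[idx], labs
        )
    frac_le = (np.sum(deltas <= 0) + 1) / (n_boot + 1)
    frac_ge = (np.sum(deltas >= 0) + 1) / (n_boot + 1)
    p = min(1.0, 2.0 * min(frac_le, frac_ge))
    return {
        "delta_auc": compute_auc(scored_a) - compute_auc(scored_b),
        "p_value": float(p),
        "n_boot": n_boot,
        "seed": seed,
    }


def stratified_folds(y: np.ndarray, k: int, seed: int, max_retries: int = 5):
    """Label-stratified k-fold index pairs; refolds if a fold is single-class."""
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(y, dtype=int)
    for attempt in range(max_retries):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + attempt)
        folds = list(skf.split(np.zeros_like(y), y))
        ok = all(
            len(np.unique(y[tr])) == 2 and len(np.unique(y[va])) == 2
            for tr, va in folds
        )
        if ok:
            if attempt:
                warnings.warn(f"refolded {attempt} time(s) to get two-class folds")
            return folds
    raise ValueError("could not produce two-class stratified folds")


def select_by_cv(
    X,
    y,
    make_classifier,
    grid=DEFAULT_PARAM_GRID,
    k: int = 10,
    seed: int = 0,
) -> tuple[float, dict]:
    """Choose a regularization strength by stratified k-fold CV on (X, y).

    ``make_classifier(value)`` must return an unfitted estimator; for each
    candidate and each fold the estimator is fitted on the k-1 training
    folds (which also serve as the retrieval library) and its validation
    AUC recorded.  Returns the argmax of mean validation AUC, ties broken
    toward the larger (more strongly regularized) value, together with the
    per-candidate mean-AUC table.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be nonempty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    folds = stratified_folds(y, k, seed)
    table = {}
    for c in grid:
        fold_aucs = []
        for tr, va in folds:
            clf = make_classifier(c)
            clf.fit(X[tr], y[tr])
            scores = clf.predict_proba(X[va])[:, 1]
            fold_aucs.append(_auc_from_arrays(scores, y[va]))
        table[c] = float(np.mean(fold_aucs))
    best = max(table.items(), key=lambda kv: (kv[1], kv[0]))[0]
    return best, table
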
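import numpy as np
import pytest
from hypothesis import given, strategies as st

import caseadapt as ca
from caseadapt.evaluation import (
    ScoredTestSet,
    bootstrap_auc,
    compute_auc,
    paired_bootstrap_compare,
    roc_curve,
    select_by_cv,
    stratified_folds,
)


def _pair_count_auc(scores, labels):
    """O(n^2) oracle: P(s_pos > s_neg) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def _random_scored(gen, n=30):
    labels = gen.integers(0, 2, n)
    labels[0], labels[1] = 0, 1
    # coarse grid scores force ties
    scores = gen.integers(0, 10, n) / 10.0
    return ScoredTestSet(scores, labels)


class TestComputeAUC:
    def test_perfect_separation_gives_one(self):
        s = ScoredTestSet([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert compute_auc(s) == 1.0

    def test_constant_scores_give_half(self):
        s = ScoredTestSet(np.full(10, 0.5), [0, 1] * 5)
        assert compute_auc(s) == 0.5

    def test_matches_pair_count_oracle(self, rng):
        for _ in range(20):
            s = _random_scored(rng)
            assert compute_auc(s) == pytest.approx(
                _pair_count_auc(s.scores, s.labels), abs=1e-12
            )

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        s = _random_scored(rng, n=100)
        assert compute_auc(s) == pytest.approx(
            roc_auc_score(s.labels, s.scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="one class"):
            compute_auc(ScoredTestSet([0.1, 0.9], [1, 1]))

    @given(st.integers(0, 10_000))
    def test_invariant_under_increasing_transform(self, seed):
        gen = np.random.default_rng(seed)
        s = _random_scored(gen)
        transformed = ScoredTestSet(np.exp(3 * s.scores) - 0.5, s.labels)
        assert compute_auc(transformed) == pytest.approx(compute_auc(s), abs=1e-12)


class TestROCCurve:
    def test_endpoints_and_monotonicity(self, rng):
        pts = roc_curve(_random_scored(rng))
        np.testing.assert_array_equal(pts[0], [0.0, 0.0])
        np.testing.assert_array_equal(pts[-1], [1.0, 1.0])
        assert np.all(np.diff(pts[:, 0]) >= 0)
        assert np.all(np.diff(pts[:, 1]) >= 0)

    def test_trapezoidal_area_equals_rank_auc(self, rng):
        for _ in range(10):
            s = _random_scored(rng)
            pts = roc_curve(s)
            area = np.trapezoid(pts[:, 1], pts[:, 0])
            assert area == pytest.approx(compute_auc(s), abs=1e-12)


class TestBootstrap:
    def test_seed_determinism(self, rng):
        s = _random_scored(rng, n=60)
        a = bootstrap_auc(s, n_boot=50, seed=9)
        b = bootstrap_auc(s, n_boot=50, seed=9)
        assert a.bootstrap_ci == b.bootstrap_ci and a.auc == b.auc

    def test_single_resample_reproducible(self, rng):
        s = _random_scored(rng, n=40)
        a = bootstrap_auc(s, n_boot=1, seed=5)
        b = bootstrap_auc(s, n_boot=1, seed=5)
        assert a.bootstrap_ci == b.bootstrap_ci

    def test_perfect_scores_degenerate_interval(self):
        labels = np.array([0, 1] * 20)
        s = ScoredTestSet(labels.astype(float), labels)
        rep = bootstrap_auc(s, n_boot=200, seed=0)
        assert rep.bootstrap_ci == (1.0, 1.0)
        assert rep.auc == 1.0

    def test_ci_shrinks_with_test_set_size(self):
        gen = np.random.default_rng(17)

        def width(n):
            labels = np.array([0, 1] * (n // 2))
            scores = labels + gen.standard_normal(n)
            rep = bootstrap_auc(ScoredTestSet(scores, labels), n_boot=400, seed=2)
            return rep.bootstrap_ci[1] - rep.bootstrap_ci[0]

        assert width(400) < width(100)

    def test_pathological_single_class_input_rejected(self):
        s = ScoredTestSet(np.linspace(0, 1, 40), [1] * 40)
        with pytest.raises(ValueError, match="single-class"):
            bootstrap_auc(s, n_boot=2000, seed=0)


class TestPairedCompare:
    def test_identical_scorers_give_p_one(self, rng):
        s = _random_scored(rng, n=50)
        out = paired_bootstrap_compare(s, s, n_boot=100, seed=1)
        assert out["p_value"] == 1.0
        assert out["delta_auc"] == 0.0

    def test_perfect_vs_random_is_significant(self):
        gen = np.random.default_rng(8)
        labels = np.array([0, 1] * 100)
        perfect = ScoredTestSet(labels.astype(float), labels)
        random_s = ScoredTestSet(gen.random(200), labels)
        out = paired_bootstrap_compare(perfect, random_s, n_boot=2000, seed=3)
        assert out["p_value"] < 0.01

    def test_symmetric_in_argument_order(self, rng):
        a = _random_scored(rng, n=50)
        b = ScoredTestSet(rng.random(50), a.labels)
        p_ab = paired_bootstrap_compare(a, b, n_boot=500, seed=4)["p_value"]
        p_ba = paired_bootstrap_compare(b, a, n_boot=500, seed=4)["p_value"]
        assert p_ab == p_ba

    def test_mismatched_cases_rejected(self, rng):
        a = _random_scored(rng, n=20)
        b = ScoredTestSet(a.scores, 1 - a.labels)
        with pytest.raises(ValueError, match="identical cases"):
            paired_bootstrap_compare(a, b)


class _ConstantCClassifier:
    """Deterministic stub: score = C * x_0 (higher C = better on fold AUC
    only through its sign); used to pin down argmax/tie behavior."""

    def __init__(self, c):
        self.c = c

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        s = self.c * X[:, 0]
        return np.column_stack([-s, s])


class TestSelectByCV:
    def test_single_candidate_returned(self, toy_library):
        best, table = select_by_cv(
            toy_library.features, toy_library.labels,
            lambda c: ca.AdaptiveUniformClassifier(n_r=5, C=c),
            grid=[0.2], k=4, seed=0,
        )
        assert best == 0.2 and set(table) == {0.2}

    def test_returned_value_is_argmax_of_reported_table(self, toy_library):
        best, table = select_by_cv(
            toy_library.features, toy_library.labels,
            lambda c: ca.AdaptiveUniformClassifier(n_r=8, C=c),
            grid=[0.01, 0.5, 100.0], k=4, seed=0,
        )
        assert table[best] == max(table.values())

    def test_ties_break_toward_stronger_regularization(self, toy_library):
        # scores are invariant to positive scaling => all candidates tie
        best, table = select_by_cv(
            toy_library.features, toy_library.labels,
            lambda c: _ConstantCClassifier(c),
            grid=[0.1, 1.0, 10.0], k=4, seed=0,
        )
        assert len(set(table.values())) == 1
        assert best == 10.0

    def test_folds_match_manual_pipeline_composition(self, toy_library):
        X, y = toy_library.features, toy_library.labels
        folds = stratified_folds(y, k=2, seed=0)
        manual = []
        for tr, va in folds:
            clf = ca.AdaptiveUniformClassifier(n_r=5, C=0.3).fit(X[tr], y[tr])
            s = clf.predict_proba(X[va])[:, 1]
            manual.append(compute_auc(ScoredTestSet(s, y[va])))
        best, table = select_by_cv(
            X, y, lambda c: ca.AdaptiveUniformClassifier(n_r=5, C=c),
            grid=[0.3], k=2, seed=0,
        )
        assert table[0.3] == pytest.approx(np.mean(manual), abs=1e-12)

    def test_folds_are_stratified_two_class(self, toy_library):
        y = toy_library.labels
        for tr, va in stratified_folds(y, k=4, seed=0):
            assert len(np.unique(y[tr])) == 2
            assert len(np.unique(y[va])) == 2
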
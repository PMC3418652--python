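import numpy as np
import pytest
from scipy.optimize import minimize

import caseadapt as ca
from caseadapt.adaptive import (
    AdaptiveUniformClassifier,
    classify_query,
    fit_adaptive,
    objective_full_hessian,
    objective_uniform,
)
from caseadapt.data import CaseLibrary, augment
from caseadapt.logistic import newton_maximize, penalized_objective
from caseadapt.retrieval import retrieve


@pytest.fixture(scope="module")
def setup(toy_library, toy_baseline):
    gen = np.random.default_rng(21)
    query = gen.standard_normal(2)
    retrieved = retrieve(
        query, toy_library, n_r=10,
        std=toy_baseline.standardizer_, sigma=toy_baseline.sigma_,
    )
    return query, retrieved, toy_baseline


class TestObjectives:
    def test_penalty_vanishes_at_baseline_discriminant(self, setup):
        q, r, bl = setup
        at_wbar = objective_uniform(bl.coef_aug_, r, bl, C=3.0)
        no_penalty = objective_uniform(bl.coef_aug_, r, bl, C=0.0)
        assert at_wbar == pytest.approx(no_penalty, abs=1e-14)

    def test_zero_C_reduces_to_weighted_likelihood(self, setup, rng):
        q, r, bl = setup
        w = rng.standard_normal(3)
        Xa = augment(r.features, bl.standardizer_)
        expected = penalized_objective(w, Xa, r.labels.astype(float), r.beta)
        assert objective_uniform(w, r, bl, C=0.0) == pytest.approx(expected, abs=1e-12)

    def test_uniform_matches_naive_evaluation(self, setup, rng):
        q, r, bl = setup
        w = rng.standard_normal(3)
        C = 0.7
        Xa = augment(r.features, bl.standardizer_)
        naive = 0.0
        for j in range(len(r)):
            t = Xa[j] @ w
            p = 1 / (1 + np.exp(-t))
            naive += r.beta[j] * np.log(p if r.labels[j] == 1 else 1 - p)
        naive -= C / 2 * np.sum((w - bl.coef_aug_) ** 2)
        assert objective_uniform(w, r, bl, C=C) == pytest.approx(naive, abs=1e-12)

    def test_full_hessian_quadratic_vanishes_at_baseline(self, setup):
        q, r, bl = setup
        assert objective_full_hessian(bl.coef_aug_, r, bl) == pytest.approx(
            objective_uniform(bl.coef_aug_, r, bl, C=0.0), abs=1e-14
        )

    def test_full_hessian_with_isotropic_hessian_equals_uniform(self, setup, rng):
        q, r, bl = setup
        C = 1.4
        w = rng.standard_normal(3)
        saved = bl.hessian_
        try:
            bl.hessian_ = -C * np.eye(3)
            full = objective_full_hessian(w, r, bl)
        finally:
            bl.hessian_ = saved
        assert full == pytest.approx(objective_uniform(w, r, bl, C=C), abs=1e-12)

    def test_full_hessian_matches_naive_quadratic_form(self, setup, rng):
        q, r, bl = setup
        w = rng.standard_normal(3)
        dw = w - bl.coef_aug_
        naive = objective_uniform(w, r, bl, C=0.0) + 0.5 * dw @ bl.hessian_ @ dw
        assert objective_full_hessian(w, r, bl) == pytest.approx(naive, abs=1e-12)

    def test_asymmetric_hessian_rejected(self, setup):
        q, r, bl = setup
        saved = bl.hessian_
        try:
            bl.hessian_ = saved + np.triu(np.ones((3, 3)), 1)
            with pytest.raises(ValueError, match="symmetric"):
                objective_full_hessian(bl.coef_aug_, r, bl)
        finally:
            bl.hessian_ = saved


class TestFitAdaptive:
    def test_huge_C_returns_baseline(self, setup):
        q, r, bl = setup
        fit = fit_adaptive(q, r, bl, C=1e12, method="uniform")
        np.testing.assert_allclose(fit.w, bl.coef_aug_, atol=1e-5)

    def test_zero_C_equals_weighted_retrieved_fit(self, setup):
        q, r, bl = setup
        fit = fit_adaptive(q, r, bl, method="none")
        Xa = augment(r.features, bl.standardizer_)
        y = r.labels.astype(float)

        def neg(w):
            return -penalized_objective(w, Xa, y, r.beta)

        res = minimize(neg, bl.coef_aug_, method="BFGS", options={"gtol": 1e-10})
        mine = penalized_objective(fit.w, Xa, y, r.beta)
        assert mine == pytest.approx(-res.fun, abs=1e-8)

    @pytest.mark.parametrize("method,C", [("uniform", 0.5), ("full_hessian", None)])
    def test_objective_matches_generic_maximizer(self, setup, method, C):
        q, r, bl = setup
        fit = fit_adaptive(q, r, bl, C=C if C is not None else 0.0, method=method)
        if method == "uniform":
            obj = lambda w: objective_uniform(w, r, bl, C)
        else:
            obj = lambda w: objective_full_hessian(w, r, bl)
        res = minimize(lambda w: -obj(w), np.zeros(3), method="BFGS",
                       options={"gtol": 1e-10})
        assert obj(fit.w) == pytest.approx(-res.fun, abs=1e-6)

    def test_unique_optimum_from_different_starts(self, setup):
        q, r, bl = setup
        Xa = augment(r.features, bl.standardizer_)
        y = r.labels.astype(float)
        C = 0.5
        args = dict(weights=r.beta, prior_mean=bl.coef_aug_, precision=C)
        from caseadapt.logistic import (
            penalized_gradient,
            penalized_hessian,
        )

        sols = []
        for start in (np.zeros(3), bl.coef_aug_, np.full(3, 5.0)):
            w, diag = newton_maximize(
                start,
                lambda w: penalized_objective(w, Xa, y, **args),
                lambda w: penalized_gradient(w, Xa, y, **args),
                lambda w: penalized_hessian(w, Xa, y, r.beta, C),
                tol=1e-8,
            )
            assert diag.converged
            sols.append(w)
        for w in sols[1:]:
            np.testing.assert_allclose(w, sols[0], atol=1e-6)

    def test_distance_to_baseline_non_increasing_in_C(self, setup):
        q, r, bl = setup
        dists = []
        for C in (0.01, 0.1, 1.0, 10.0, 100.0):
            fit = fit_adaptive(q, r, bl, C=C, method="uniform")
            dists.append(np.linalg.norm(fit.w - bl.coef_aug_))
        assert all(b <= a + 1e-10 for a, b in zip(dists, dists[1:]))

    def test_monotone_objective_trace(self, setup):
        q, r, bl = setup
        fit = fit_adaptive(q, r, bl, C=0.3, method="uniform")
        tr = fit.diagnostics.objective_trace
        assert all(b >= a for a, b in zip(tr, tr[1:]))

    def test_separable_unregularized_fit_is_guarded(self, toy_baseline):
        # one-class retrieved set, no prior: likelihood unbounded, must not crash
        X = np.array([[2.0, 2.0], [2.1, 1.9], [1.9, 2.1]])
        lib = CaseLibrary.from_arrays(X, np.ones(3, dtype=int), role="retrieval")
        r = retrieve(np.array([2.0, 2.0]), lib, n_r=3,
                     std=toy_baseline.standardizer_, sigma=toy_baseline.sigma_)
        fit = fit_adaptive(None, r, toy_baseline, method="none", max_iter=500)
        assert np.all(np.isfinite(fit.w))

    def test_negative_C_rejected(self, setup):
        q, r, bl = setup
        with pytest.raises(ValueError):
            fit_adaptive(q, r, bl, C=-1.0, method="uniform")


class TestClassifyQuery:
    def test_huge_C_reproduces_baseline_probability(self, setup, toy_library):
        q, _, bl = setup
        p_adapt = classify_query(q, toy_library, bl, n_r=10, C=1e12)
        p_base = bl.predict_proba(q[None, :])[0, 1]
        assert p_adapt == pytest.approx(p_base, abs=1e-5)

    def test_single_malignant_neighbor_pushes_probability_up(self, toy_baseline):
        q = np.array([0.3, -0.2])
        lib = CaseLibrary.from_arrays(
            np.vstack([q, [[5.0, 5.0]]]), np.array([1, 0]), role="retrieval"
        )
        p = classify_query(q, lib, toy_baseline, n_r=1, C=0.0, method="none")
        assert p > 0.5

    def test_baseline_not_mutated(self, setup, toy_library):
        q, _, bl = setup
        w_before = bl.coef_aug_.copy()
        classify_query(q, toy_library, bl, n_r=5, C=0.2)
        np.testing.assert_array_equal(bl.coef_aug_, w_before)


class TestEstimator:
    def test_predict_proba_shape_and_range(self, toy_library):
        clf = AdaptiveUniformClassifier(n_r=8, C=0.5).fit(
            toy_library.features, toy_library.labels
        )
        P = clf.predict_proba(toy_library.features[:5])
        assert P.shape == (5, 2)
        np.testing.assert_allclose(P.sum(axis=1), 1.0)
        assert np.all((P >= 0) & (P <= 1))

    def test_get_set_params_round_trip(self):
        clf = AdaptiveUniformClassifier(n_r=25, C=0.1, method="none")
        params = clf.get_params()
        clone = AdaptiveUniformClassifier(**params)
        assert clone.get_params() == params
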
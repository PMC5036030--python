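"""Likelihood values, the brute-force latent-state oracle, and gradients."""

import itertools

import numpy as np
import pytest
from scipy.optimize import approx_fprime
from scipy.special import logit as slogit

import occufp as o
from occufp.likelihood import (
    LikelihoodProblem,
    ParameterVector,
    brute_force_site_loglik,
    negative_loglik,
    negative_loglik_grad,
    site_loglik,
    site_logliks,
)

from conftest import random_problem


def scalar_problem(y, psi, p, p10=None, misclassification=None):
    """Intercept-only problem with site probabilities fixed by hand."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    M = y.shape[0]
    mis = (p10 is not None) if misclassification is None else misclassification
    Xpsi = o.DesignMatrix(np.ones((M, 1)), ("(Intercept)",))
    Xp = o.DesignMatrix(np.ones((M, 1)), ("(Intercept)",))
    prob = LikelihoodProblem(y, Xpsi, Xp, mis)
    params = ParameterVector(
        [slogit(psi)], [slogit(p)], None if not mis else float(slogit(p10))
    )
    return prob, params


class TestHandValues:
    def test_conventional_single_replicate(self):
        prob, params = scalar_problem([[1.0]], psi=0.5, p=0.5)
        assert site_loglik(prob, params, 0) == pytest.approx(np.log(0.25), abs=1e-12)

    def test_misclassification_two_term_mixture(self):
        # psi=0.6, p=0.7, p10=0.1, y=(1,0): 0.6*0.7*0.3 + 0.4*0.1*0.9 = 0.162
        prob, params = scalar_problem([[1.0, 0.0]], psi=0.6, p=0.7, p10=0.1)
        assert site_loglik(prob, params, 0) == pytest.approx(
            np.log(0.162), abs=1e-10
        )

    def test_conventional_all_zero_history(self):
        psi, p = 0.37, 0.22
        prob, params = scalar_problem([[0.0, 0.0, 0.0]], psi=psi, p=p)
        expected = np.log(psi * (1 - p) ** 3 + (1 - psi))
        assert site_loglik(prob, params, 0) == pytest.approx(expected, abs=1e-12)

    def test_missing_replicates_skipped(self):
        prob_full, params = scalar_problem([[1.0, 0.0]], psi=0.6, p=0.7, p10=0.1)
        prob_miss, _ = scalar_problem([[1.0, np.nan, 0.0]], psi=0.6, p=0.7, p10=0.1)
        assert site_loglik(prob_miss, params, 0) == pytest.approx(
            site_loglik(prob_full, params, 0), abs=1e-12
        )


class TestReduction:
    def test_p10_zero_equals_conventional(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, size=(1, 4)).astype(float)
            psi, p = rng.uniform(0.05, 0.95, size=2)
            prob_m, params_m = scalar_problem(y, psi=psi, p=p, p10=1e-13)
            prob_c, params_c = scalar_problem(y, psi=psi, p=p)
            a = site_loglik(prob_m, params_m, 0)
            b = site_loglik(prob_c, params_c, 0)
            if np.isfinite(b):
                assert a == pytest.approx(b, abs=1e-8)
            else:  # detections at an unoccupied-only-possible history
                assert a < -20


class TestAdditivity:
    def test_sum_of_site_terms(self, rng):
        prob, params = random_problem(rng, M=12, J=5, misclassification=True)
        total = sum(site_loglik(prob, params, i) for i in range(12))
        assert negative_loglik(prob, params) == pytest.approx(-total, abs=1e-10)

    def test_duplicating_sites_doubles(self, rng):
        prob, params = random_problem(rng, M=7, J=4)
        doubled = LikelihoodProblem(
            np.vstack([prob.detections] * 2),
            o.DesignMatrix(
                np.vstack([prob.psi_design.values] * 2), prob.psi_design.column_labels
            ),
            o.DesignMatrix(
                np.vstack([prob.p_design.values] * 2), prob.p_design.column_labels
            ),
            False,
        )
        assert negative_loglik(doubled, params) == pytest.approx(
            2.0 * negative_loglik(prob, params), abs=1e-9
        )


class TestOracle:
    @pytest.mark.parametrize("misclassification", [False, True])
    @pytest.mark.parametrize("replicate_p", [False, True])
    def test_agrees_with_enumeration(self, rng, misclassification, replicate_p):
        for _ in range(50):
            prob, params = random_problem(
                rng, M=5, J=4, misclassification=misclassification,
                with_missing=True, replicate_p=replicate_p,
            )
            for i in range(5):
                assert site_loglik(prob, params, i) == pytest.approx(
                    brute_force_site_loglik(prob, params, i), abs=1e-10
                )

    @pytest.mark.parametrize("misclassification", [False, True])
    @pytest.mark.parametrize("J", [1, 3, 6])
    def test_history_probabilities_sum_to_one(self, rng, misclassification, J):
        # exhaustively enumerate all 2^J histories at one site
        Xpsi = o.DesignMatrix(np.ones((1, 1)), ("(Intercept)",))
        Xp = o.DesignMatrix(
            np.column_stack([np.ones(1), rng.normal(size=1)]), ("(Intercept)", "c")
        )
        theta = rng.normal(size=3 + (1 if misclassification else 0))
        params = ParameterVector.unflatten(theta, 1, 2, misclassification)
        total = 0.0
        for hist in itertools.product([0.0, 1.0], repeat=J):
            prob = LikelihoodProblem(
                np.array([hist]), Xpsi, Xp, misclassification
            )
            total += np.exp(site_loglik(prob, params, 0))
        assert total == pytest.approx(1.0, abs=1e-10)


class TestMonotonicity:
    def test_all_detections_increasing_in_p(self):
        # occupied-dominant point, all-ones history: loglik rises with p
        vals = []
        for p in (0.3, 0.5, 0.7, 0.9):
            prob, params = scalar_problem([[1.0] * 4], psi=0.9, p=p, p10=0.05)
            vals.append(site_loglik(prob, params, 0))
        assert np.all(np.diff(vals) > 0)


class TestGradient:
    @pytest.mark.parametrize("misclassification", [False, True])
    @pytest.mark.parametrize("replicate_p", [False, True])
    def test_matches_finite_differences(self, rng, misclassification, replicate_p):
        for _ in range(5):
            prob, params = random_problem(
                rng, M=9, J=4, misclassification=misclassification,
                with_missing=True, replicate_p=replicate_p,
            )
            theta = params.flatten()
            g = negative_loglik_grad(prob, params)
            gn = approx_fprime(
                theta,
                lambda t: negative_loglik(
                    prob, ParameterVector.unflatten(t, 3, 2, misclassification)
                ),
                1e-7,
            )
            np.testing.assert_allclose(g, gn, atol=1e-4)


class TestValidation:
    def test_all_missing_site_rejected(self):
        y = np.array([[np.nan, np.nan]])
        Xpsi = o.DesignMatrix(np.ones((1, 1)), ("(Intercept)",))
        with pytest.raises(ValueError, match="non-missing"):
            LikelihoodProblem(y, Xpsi, Xpsi, False)

    def test_non_binary_rejected(self):
        Xpsi = o.DesignMatrix(np.ones((1, 1)), ("(Intercept)",))
        with pytest.raises(ValueError, match="0, 1 or missing"):
            LikelihoodProblem(np.array([[2.0]]), Xpsi, Xpsi, False)

    def test_parameter_length_checked(self, rng):
        prob, params = random_problem(rng)
        bad = ParameterVector(params.beta[:-1], params.alpha)
        with pytest.raises(ValueError):
            site_logliks(prob, bad)
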
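"""Closed-form equilibrium, trait moments, stability, and the decision boundary."""

from fractions import Fraction

import numpy as np
import pytest

from plastidyn import (
    ModelParams,
    StabilityVerdict,
    coexistence_equilibrium,
    decision_boundary,
    distribution_moments,
    equilibrate,
    jacobian,
    rhs,
    stability_report,
)
from plastidyn.equilibrium_analysis import trait_scores


class TestCoexistenceEquilibrium:
    @pytest.mark.parametrize(
        "lam, expected",
        [
            (0.0, [1 / 3, 1 / 3, 1 / 3]),
            (1.0, [0.0, 0.0, 1.0]),
            (-1.0, [1.0, 0.0, 0.0]),
            (0.5, [1 / 13, 3 / 13, 9 / 13]),  # geometric, ratio (1+l)/(1-l) = 3
        ],
    )
    def test_reference_distributions(self, lam, expected):
        xs = coexistence_equilibrium(ModelParams(transition_bias=lam))
        np.testing.assert_allclose(xs, expected, atol=1e-15)

    @pytest.mark.parametrize("n", [1, 2, 3, 5, 8])
    @pytest.mark.parametrize("lam", np.linspace(-1, 1, 9))
    def test_normalization_to_carrying_capacity(self, n, lam):
        p = ModelParams(n_phenotypes=n, transition_bias=float(lam), carrying_capacity=2.5)
        assert coexistence_equilibrium(p).sum() == pytest.approx(2.5, abs=1e-12)

    @pytest.mark.parametrize("rN", [0.1, 0.5, 0.9])
    def test_independent_of_growth_ladder(self, rN):
        base = coexistence_equilibrium(ModelParams(transition_bias=0.3))
        alt = coexistence_equilibrium(ModelParams(transition_bias=0.3, rN=rN))
        np.testing.assert_array_equal(base, alt)

    def test_mirror_symmetry(self):
        for lam in (0.2, 0.55, 0.9):
            a = coexistence_equilibrium(ModelParams(n_phenotypes=4, transition_bias=lam))
            b = coexistence_equilibrium(ModelParams(n_phenotypes=4, transition_bias=-lam))
            np.testing.assert_allclose(a, b[::-1], rtol=1e-13)

    def test_no_transitions_rejected(self):
        with pytest.raises(ValueError, match="c > 0"):
            coexistence_equilibrium(ModelParams(transition_speed=0.0))

    @pytest.mark.parametrize("lam", [-0.8, -0.3, 0.0, 0.4, 0.9])
    @pytest.mark.parametrize("c", [0.5, 2.0])
    def test_matches_long_integration_fixed_point(self, lam, c):
        """Independent oracle: the dynamics settle onto the closed form."""
        p = ModelParams(
            n_phenotypes=4, transition_bias=lam, transition_speed=c
        )
        x0 = np.full(4, p.carrying_capacity / 8)
        x_num, _, converged = equilibrate(p, x0, max_horizon=2000.0)
        assert converged
        np.testing.assert_allclose(
            x_num, coexistence_equilibrium(p), atol=1e-8
        )


class TestDistributionMoments:
    def test_uniform_case(self):
        s = distribution_moments(np.array([1 / 3, 1 / 3, 1 / 3]))
        assert s.mean_trait == pytest.approx(0.5)
        assert s.variance == pytest.approx(1 / 6)
        assert s.third_central_moment == pytest.approx(0.0, abs=1e-15)
        assert s.frequencies.sum() == pytest.approx(1.0, abs=1e-12)

    def test_point_mass(self):
        s = distribution_moments(np.array([0.0, 0.0, 1.0]))
        assert s.mean_trait == pytest.approx(1.0)
        assert s.variance == pytest.approx(0.0, abs=1e-15)
        assert s.third_central_moment == pytest.approx(0.0, abs=1e-15)

    def test_biased_equilibrium_against_exact_arithmetic(self):
        """Brute-force oracle in exact rational arithmetic."""
        weights = [Fraction(1, 13), Fraction(3, 13), Fraction(9, 13)]
        scores = [Fraction(0), Fraction(1, 2), Fraction(1)]
        mean = sum(w * s for w, s in zip(weights, scores))
        var = sum(w * (s - mean) ** 2 for w, s in zip(weights, scores))
        m3 = sum(w * (s - mean) ** 3 for w, s in zip(weights, scores))

        s = distribution_moments(np.array([1 / 13, 3 / 13, 9 / 13]))
        assert s.mean_trait == pytest.approx(float(mean), rel=1e-12)
        assert s.variance == pytest.approx(float(var), rel=1e-12)
        assert s.third_central_moment == pytest.approx(float(m3), rel=1e-10)

    def test_zero_total_is_degenerate(self):
        with pytest.raises(ValueError):
            distribution_moments(np.zeros(3))

    def test_trait_scores_span_unit_interval(self):
        np.testing.assert_allclose(trait_scores(5), [0, 0.25, 0.5, 0.75, 1.0])

    def test_variance_maximal_at_zero_bias_and_skewness_odd(self):
        lam_grid = np.linspace(-1, 1, 21)
        p = ModelParams()
        var = []
        m3 = []
        for lam in lam_grid:
            s = distribution_moments(
                coexistence_equilibrium(p.replace(transition_bias=float(lam)))
            )
            var.append(s.variance)
            m3.append(s.third_central_moment)
        var = np.array(var)
        m3 = np.array(m3)
        assert var.argmax() == 10  # lambda = 0
        np.testing.assert_allclose(m3, -m3[::-1], atol=1e-14)
        assert abs(m3[10]) < 1e-14
        # heterogeneity vanishes in the unidirectional limits
        assert var[0] == pytest.approx(0.0, abs=1e-14)
        assert var[-1] == pytest.approx(0.0, abs=1e-14)


class TestStability:
    def test_coexistence_is_stable_origin_is_not(self, default_params):
        xs = coexistence_equilibrium(default_params)
        rep = stability_report(default_params, xs)
        assert rep.verdict is StabilityVerdict.STABLE
        rep0 = stability_report(default_params, np.zeros(3))
        assert rep0.verdict is StabilityVerdict.UNSTABLE
        # the untreated origin grows at the ladder rates minus transition losses
        assert rep0.max_real_part > 0

    def test_equilibrium_unchanged_and_stable_under_perturbed_ladder(self):
        p = ModelParams(rN=0.5)
        xs = coexistence_equilibrium(p)
        np.testing.assert_array_equal(xs, coexistence_equilibrium(ModelParams()))
        assert stability_report(p, xs).verdict is StabilityVerdict.STABLE

    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    @pytest.mark.parametrize("lam", np.linspace(-0.9, 0.9, 7))
    def test_verdicts_across_transition_parameter_grid(self, c, lam):
        p = ModelParams(transition_speed=c, transition_bias=float(lam))
        assert (
            stability_report(p, coexistence_equilibrium(p)).verdict
            is StabilityVerdict.STABLE
        )
        assert (
            stability_report(p, np.zeros(3)).verdict is StabilityVerdict.UNSTABLE
        )

    def test_analytic_jacobian_matches_finite_differences(self, rng):
        p = ModelParams(
            n_phenotypes=4, transition_bias=0.3, transition_speed=2.0, rN=0.4
        )
        h = 1e-6
        for _ in range(5):
            x = rng.uniform(0.05, 1.0, size=4)
            J = jacobian(p, x)
            J_fd = np.empty_like(J)
            for j in range(4):
                e = np.zeros(4)
                e[j] = h
                J_fd[:, j] = (rhs(x + e, p) - rhs(x - e, p)) / (2 * h)
            np.testing.assert_allclose(J, J_fd, atol=1e-7)


class TestDecisionBoundary:
    def test_two_phenotype_closed_form_root(self):
        # f(l) = mean growth rate minus mI is linear: 0.6 - 0.4 l - 0.6 -> root 0
        p = ModelParams(n_phenotypes=2, rN=0.2, mD=1.0, mI=0.6)
        assert decision_boundary(p) == pytest.approx(0.0, abs=1e-10)

    def test_none_when_one_treatment_dominates(self):
        # mI above mD * r1: the growth-weighted mean never reaches it
        p = ModelParams(mI=1.5)
        assert decision_boundary(p) is None

    def test_requires_calibrated_intensity(self, default_params):
        with pytest.raises(ValueError, match="mI"):
            decision_boundary(default_params)

    def test_boundary_splits_treatment_dominance(self, calibrated_params):
        lam_t = decision_boundary(calibrated_params)
        assert lam_t is not None and -1 < lam_t < 1
        from plastidyn import TreatmentKind, adaptive_choice

        below = coexistence_equilibrium(
            calibrated_params.replace(transition_bias=lam_t - 0.05)
        )
        above = coexistence_equilibrium(
            calibrated_params.replace(transition_bias=lam_t + 0.05)
        )
        assert adaptive_choice(below, calibrated_params.replace(transition_bias=lam_t - 0.05)) is TreatmentKind.GROWTH_DEPENDENT
        assert adaptive_choice(above, calibrated_params.replace(transition_bias=lam_t + 0.05)) is TreatmentKind.GROWTH_INDEPENDENT
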
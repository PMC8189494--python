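"""Unit and property tests for the core probability kernels."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from agejs import (
    CaptureData,
    ConstantSurvival,
    ParameterState,
    QuadraticSurvival,
    StudyDesign,
    ValidationError,
    beta_from_eta,
    compose_initial_age_dist,
    eta_from_beta,
    feasible_histories,
    survival_at_age,
    trajectory_log_prob,
)
from conftest import brute_force_marginal

simplexes = st.integers(2, 8).flatmap(
    lambda k: st.lists(st.floats(0.01, 1.0), min_size=k, max_size=k)
).map(lambda v: np.array(v) / np.sum(v))


class TestEntryTransform:
    @pytest.mark.parametrize(
        "beta, expected",
        [
            (
                [0.4, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1],
                [0.4, 1 / 6, 0.2, 0.25, 1 / 3, 0.5, 1.0],
            ),
            ([1.0, 0.0, 0.0], [1.0, 0.0, 0.0]),  # zero-remaining-mass convention
            ([0.25, 0.25, 0.25, 0.25], [1 / 4, 1 / 3, 1 / 2, 1.0]),
        ],
    )
    def test_conditional_entry_probabilities(self, beta, expected):
        np.testing.assert_allclose(eta_from_beta(beta), expected, atol=1e-12)

    def test_uniform_closed_form(self):
        K = 6
        eta = eta_from_beta(np.full(K, 1 / K))
        np.testing.assert_allclose(eta, [1 / (K - k) for k in range(K)], atol=1e-12)

    @pytest.mark.parametrize("bad", [[0.5, 0.4], [-0.1, 1.1], [0.5, 0.5, 0.5]])
    def test_non_simplex_rejected(self, bad):
        with pytest.raises(ValidationError):
            eta_from_beta(bad)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(simplexes)
    def test_round_trip(self, beta):
        np.testing.assert_allclose(beta_from_eta(eta_from_beta(beta)), beta, atol=1e-12)


class TestInitialAgeMixture:
    def test_stated_mixture(self):
        pi_prime = [0.27, 0.17, 0.14, 0.12, 0.11, 0.09, 0.06, 0.03, 0.01]
        pi = compose_initial_age_dist(0.4, pi_prime)
        np.testing.assert_allclose(
            pi,
            [0.6, 0.108, 0.068, 0.056, 0.048, 0.044, 0.036, 0.024, 0.012, 0.004],
            atol=1e-12,
        )

    def test_certain_entry_recovers_pi_prime(self):
        pi = compose_initial_age_dist(1.0, [0.3, 0.7])
        np.testing.assert_allclose(pi, [0.0, 0.3, 0.7], atol=1e-15)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.floats(0.0, 1.0), simplexes)
    def test_normalisation(self, eta1, pi_prime):
        assert math.isclose(compose_initial_age_dist(eta1, pi_prime).sum(), 1.0,
                            abs_tol=1e-12)


class TestSurvivalLink:
    quad = QuadraticSurvival(alpha0=float(np.log(0.85 / 0.15)), alpha1=-0.5,
                             alpha2=-0.20, center=5.0)

    @pytest.mark.parametrize("age, expected", [(1, 0.63), (4, 0.88), (9, 0.03)])
    def test_senescent_curve_values(self, age, expected):
        assert round(float(survival_at_age(age, self.quad)), 2) == expected

    def test_zero_slopes_reduce_to_constant(self):
        flat = QuadraticSurvival(alpha0=0.3, alpha1=0.0, alpha2=0.0, center=5.0)
        vals = survival_at_age(np.arange(1, 15), flat)
        np.testing.assert_allclose(vals, 1 / (1 + np.exp(-0.3)), atol=1e-12)

    def test_constant_model(self):
        assert float(survival_at_age(7, ConstantSurvival(0.85))) == 0.85

    def test_monotone_decreasing_past_vertex(self):
        vertex = self.quad.center - self.quad.alpha1 / (2 * self.quad.alpha2)
        ages = np.arange(math.ceil(vertex), 25)
        vals = survival_at_age(ages, self.quad)
        assert (np.diff(vals) < 0).all()


class TestFeasibleHistories:
    def test_single_leading_detection_count(self):
        design = StudyDesign(K=3, J=4, M=5)
        hists = feasible_histories([1, 0, 0], design)
        assert len(hists) == 3 * design.J
        assert all(h.entry == 1 and h.x1 >= 1 for h in hists)

    def test_all_zero_row_count(self):
        design = StudyDesign(K=3, J=2, M=5)
        hists = feasible_histories([0, 0, 0], design)
        # never-entered + occasion-1 entries (J ages x 3 exits) + later entries
        assert len(hists) == 1 + 3 * design.J + (2 + 1)
        assert any(h.entry == 0 for h in hists)

    def test_exhaustive_against_brute_force(self, tiny_params):
        """Histories sum to the brute-force marginal P(y) over raw configs."""
        design = StudyDesign(K=3, J=3, M=1)
        params = ParameterState(psi=0.7, p=0.3, beta=np.array([0.5, 0.3, 0.2]),
                                survival=ConstantSurvival(0.8),
                                pi_prime=np.array([0.5, 0.3, 0.2]))
        for y in ([0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 0, 1], [1, 1, 1]):
            hists = feasible_histories(y, design)
            total = sum(
                math.exp(trajectory_log_prob(h, y, params, design, w=w))
                for h in hists
                for w in (0, 1)
                if trajectory_log_prob(h, y, params, design, w=w) > -math.inf
            )
            assert math.isclose(total, brute_force_marginal(y, params, design),
                                rel_tol=1e-12)

    def test_detection_at_first_occasion_forces_positive_initial_age(self):
        design = StudyDesign(K=3, J=2, M=5)
        hists = feasible_histories([1, 1, 0], design)
        assert all(h.x1 >= 1 for h in hists)

    def test_known_age_constraint(self):
        design = StudyDesign(K=3, J=5, M=5)
        hists = feasible_histories([0, 1, 0], design, age_occasion=2, age_value=4)
        assert all(h.age_at(2, design) == 4 for h in hists)
        assert all(h.entry == 1 and h.x1 == 3 for h in hists)


class TestTrajectoryLogProb:
    def test_hand_arithmetic(self):
        """Detected twice over two occasions: psi * eta1 pi'_1 * phi * p^2."""
        design = StudyDesign(K=2, J=1, M=2)
        params = ParameterState(psi=0.5, p=0.25, beta=np.array([0.4, 0.6]),
                                survival=ConstantSurvival(0.85),
                                pi_prime=np.array([1.0]))
        from agejs import LatentHistory

        lp = trajectory_log_prob(LatentHistory(x1=1, entry=1, last=2), [1, 1],
                                 params, design, w=1)
        assert math.isclose(math.exp(lp), 0.5 * 0.4 * 1.0 * 0.85 * 0.25**2,
                            rel_tol=1e-12)

    def test_detection_while_excluded_is_impossible(self, tiny_params, tiny_design):
        from agejs import LatentHistory

        lp = trajectory_log_prob(LatentHistory(x1=1, entry=1, last=2), [1, 0],
                                 tiny_params, tiny_design, w=0)
        assert lp == -math.inf

    def test_never_entered_mass(self, tiny_params, tiny_design):
        """w=1 never-entered mass equals psi times the full (1 - eta) chain."""
        from agejs.model import NEVER_ENTERED as never

        lp = trajectory_log_prob(never, [0, 0], tiny_params, tiny_design, w=1)
        expected = tiny_params.psi * np.prod(1 - tiny_params.eta)
        if expected == 0:
            assert lp == -math.inf
        else:
            assert math.isclose(math.exp(lp), expected, rel_tol=1e-12)

    def test_ages_increment_after_entry(self):
        from agejs import LatentHistory

        design = StudyDesign(K=5, J=3, M=2)
        h = LatentHistory(x1=0, entry=2, last=3)
        ages = [h.age_at(k, design) for k in range(1, 6)]
        assert ages == [0, 1, 2, 3, 4]  # keeps incrementing after death at k=3


class TestCaptureDataValidation:
    def test_rejects_non_binary(self):
        with pytest.raises(ValidationError, match="row 1"):
            CaptureData(ids=["a"], y=np.array([[2, 0]]),
                        age_occasion=np.array([-1]), age_value=np.array([-1]))

    def test_rejects_empty_history(self):
        with pytest.raises(ValidationError, match="no detections"):
            CaptureData(ids=["a"], y=np.array([[0, 0]]),
                        age_occasion=np.array([-1]), age_value=np.array([-1]))

    def test_age_design_consistency(self):
        data = CaptureData(ids=["a"], y=np.array([[1, 0, 0]]),
                           age_occasion=np.array([1]), age_value=np.array([9]))
        with pytest.raises(ValidationError, match="'a'"):
            data.validate_against(StudyDesign(K=3, J=5, M=3))
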
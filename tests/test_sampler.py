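"""Sampler correctness: enumeration oracle, Gibbs machinery, diagnostics."""

import math
import warnings

import numpy as np
import pytest

import arviz as az

from agejs import (
    CaptureData,
    ConstantSurvival,
    MCMCConfig,
    ParameterState,
    StudyDesign,
    ValidationError,
    default_configs,
    enumerate_reference,
    fit,
    gelman_rubin,
    marginal_of,
    sample_latent_fixed_params,
    simulate_dataset,
    trajectory_log_prob,
)
from agejs.sampler import Priors, _Engine
from conftest import brute_force_joint, total_variation


class TestEnumerateReference:
    def test_single_unobserved_closed_form(self):
        """One augmented, never-detected individual: closed-form P(N_1 = 1).

        The unnormalised mass of 'present at occasion 1' is psi * eta_1 times
        the probability of surviving the study undetected; competing mass
        comes from exclusion (1 - psi) and from entry at occasion 2.
        """
        psi, p, phi, eta1 = 0.6, 0.3, 0.8, 0.7
        design = StudyDesign(K=2, J=1, M=1)
        params = ParameterState(psi=psi, p=p, beta=np.array([eta1, 1 - eta1]),
                                survival=ConstantSurvival(phi),
                                pi_prime=np.array([1.0]))
        data = CaptureData(ids=[], y=np.zeros((0, 2)), age_occasion=np.zeros(0),
                           age_value=np.zeros(0))
        dist = enumerate_reference(data, params, design)
        m1 = marginal_of(dist, 0)
        q = 1 - p
        in1 = psi * eta1 * ((1 - phi) * q + phi * q * q)   # alive at occasion 1
        out1 = (1 - psi) + psi * (1 - eta1) * q            # excluded, or enters at 2
        assert m1[1] == pytest.approx(in1 / (in1 + out1), rel=1e-12)
        assert m1[0] == pytest.approx(out1 / (in1 + out1), rel=1e-12)

    def test_matches_raw_enumeration(self, tiny_data, tiny_params, tiny_design):
        """Joint (N_1..K, N*) equals an independent raw-configuration sum."""
        dist = enumerate_reference(tiny_data, tiny_params, tiny_design)
        ref = brute_force_joint(tiny_data, tiny_params, tiny_design)
        assert total_variation(dist, ref) < 1e-12

    def test_probabilities_sum_to_one(self, tiny_data, tiny_params, tiny_design):
        dist = enumerate_reference(tiny_data, tiny_params, tiny_design)
        assert math.isclose(sum(dist.values()), 1.0, abs_tol=1e-12)

    def test_guard_refuses_large_spaces(self, tiny_params):
        design = StudyDesign(K=7, J=9, M=500)
        data = CaptureData(ids=[], y=np.zeros((0, 7)), age_occasion=np.zeros(0),
                           age_value=np.zeros(0))
        params = ParameterState(psi=0.5, p=0.25, beta=np.full(7, 1 / 7),
                                survival=ConstantSurvival(0.85),
                                pi_prime=np.full(9, 1 / 9))
        with pytest.raises(ValidationError, match="exceeds guard"):
            enumerate_reference(data, params, design)


class TestLatentGibbs:
    def test_fixed_parameter_marginals_match_oracle(self, tiny_data, tiny_params,
                                                    tiny_design):
        dist = enumerate_reference(tiny_data, tiny_params, tiny_design)
        draws = sample_latent_fixed_params(tiny_data, tiny_params, tiny_design,
                                           n_sweeps=15_000, seed=4, burnin=200)
        for idx, name in [(0, "N"), (tiny_design.K, "Nstar")]:
            exact = marginal_of(dist, idx)
            col = draws["N"][:, 0] if name == "N" else draws["Nstar"]
            emp = {int(v): float((col == v).mean()) for v in np.unique(col)}
            assert total_variation(exact, emp) < 0.05

    def test_table_weights_agree_with_trajectory_log_prob(self, tiny_params,
                                                          tiny_design):
        """Two routes to the same history weight: tabulated vs. kernel-by-kernel."""
        dummy = CaptureData(ids=["a"], y=np.array([[1, 0]]),
                            age_occasion=np.array([-1]), age_value=np.array([-1]))
        eng = _Engine(dummy, "agejs_constant", tiny_design, Priors())
        params = {"psi": tiny_params.psi, "p": tiny_params.p,
                  "beta": tiny_params.beta, "pi_prime": tiny_params.pi_prime,
                  "phi": tiny_params.survival.phi}
        base = eng.table.base_log_weights(params)
        zeros = np.zeros(tiny_design.K, dtype=int)
        for h, lw in zip(eng.table.histories, base):
            ref = trajectory_log_prob(h, zeros, tiny_params, tiny_design, w=1)
            ref -= math.log(tiny_params.psi)
            if ref == -math.inf:
                assert lw < -600  # clipped rather than -inf, effectively zero
            else:
                assert lw == pytest.approx(ref, abs=1e-9)


class TestFit:
    def test_zero_detection_dataset_degrades_gracefully(self):
        data = CaptureData(ids=[], y=np.zeros((0, 3)), age_occasion=np.zeros(0),
                           age_value=np.zeros(0))
        design = StudyDesign(K=3, J=2, M=20)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = fit(data, "agejs_constant", design,
                       mcmc=MCMCConfig(n_chains=2, n_iter=600, n_burnin=100,
                                       thin=1, seed=0))
        assert np.median(post.stacked("psi")) < 0.5

    def test_retained_draw_count_and_abundance_bounds(self):
        const, _ = default_configs()
        data, _ = simulate_dataset(const, seed=9)
        mc = MCMCConfig(n_chains=2, n_iter=800, n_burnin=200, thin=3, seed=1)
        post = fit(data, "agejs_constant", const.design, mcmc=mc)
        assert post.n_draws == (800 - 200 + 2) // 3
        N, Nstar = post.stacked("N"), post.stacked("Nstar")
        assert (N.max(axis=1) <= Nstar).all()
        assert (Nstar <= post.design.M).all()
        # alive-by-age decomposition is exact for every draw
        np.testing.assert_array_equal(post.stacked("Nkj").sum(axis=2), N)

    def test_inconsistent_age_names_individual(self):
        data = CaptureData(ids=["bad"], y=np.array([[1, 0]]),
                           age_occasion=np.array([1]), age_value=np.array([7]))
        with pytest.raises(ValidationError, match="'bad'"):
            fit(data, "agejs_constant", StudyDesign(K=2, J=3, M=3),
                mcmc=MCMCConfig(n_chains=1, n_iter=10, n_burnin=0, thin=1))

    def test_augmentation_ceiling_warning(self):
        const, _ = default_configs()
        data, _ = simulate_dataset(const, seed=12)
        design = StudyDesign(K=7, J=9, M=data.n + 2)
        with pytest.warns(UserWarning, match="augmentation ceiling"):
            fit(data, "agejs_constant", design,
                mcmc=MCMCConfig(n_chains=1, n_iter=400, n_burnin=100, thin=1,
                                seed=3))

    def test_seed_determinism(self):
        const, _ = default_configs()
        data, _ = simulate_dataset(const, seed=13)
        mc = MCMCConfig(n_chains=2, n_iter=400, n_burnin=100, thin=2, seed=11)
        p1 = fit(data, "agejs_constant", const.design, mcmc=mc)
        p2 = fit(data, "agejs_constant", const.design, mcmc=mc)
        for k in p1.draws:
            np.testing.assert_array_equal(p1.draws[k], p2.draws[k])


class TestGelmanRubin:
    def test_identical_constant_chains(self):
        assert gelman_rubin(np.array([[2.0] * 10, [2.0] * 10])) == 1.0

    def test_hand_computed_split_chain_value(self):
        """Classic split-chain arithmetic on two short, far-apart chains."""
        chains = np.array([[1.0, 2, 3, 4], [101.0, 102, 103, 104]])
        halves = np.array([[1.0, 2], [101, 102], [3, 4], [103, 104]])
        W = halves.var(axis=1, ddof=1).mean()
        B = 2 * halves.mean(axis=1).var(ddof=1)
        expected = math.sqrt(((2 - 1) / 2 * W + B / 2) / W)
        assert gelman_rubin(chains) == pytest.approx(expected, rel=1e-12)

    def test_agrees_with_arviz_split_variant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 400))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = float(az.rhat(x, method="split"))
        assert gelman_rubin(x) == pytest.approx(ref, abs=1e-6)

    def test_well_mixed_chains_near_one(self):
        rng = np.random.default_rng(1)
        assert gelman_rubin(rng.normal(size=(4, 2000))) < 1.01

    def test_single_chain_rejected(self):
        with pytest.raises(ValidationError, match="chains"):
            gelman_rubin(np.ones((1, 100)))
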
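import math

import numpy as np
import pytest

from nichesync.agent import (AgentState, EpochTrace, action_step,
                             confidence_interval, gaussian_perception_flow,
                             learning_step, make_agent, perception_step)
from nichesync.free_energy import GaussianBeliefs, LinearGaussianModel
from nichesync.generalized_coords import GeneralizedState, to_time_units
from nichesync.generative_model import (BirdsongEnergy, Expectations,
                                        generalized_from_flow,
                                        predict_sensory, song_observation)


class TestPerception:
    def test_zero_errors_give_pure_shift_flow(self, model, tick_model):
        """At a self-consistent state observing its own output, the
        free-energy gradient vanishes, so the flow is the pure shift."""
        exp = generalized_from_flow(tick_model, np.array([2.0, 3.0, 25.0]),
                                    np.array([1.0, 2.0, 20.0]), 24.0, 1.0)
        sens = predict_sensory(tick_model, exp)
        energy = BirdsongEnergy(model)
        _, g_mu, _, _ = energy.grads(exp.to_flat(), sens.values, 24.0)
        # prediction errors vanish: only the weak cause-shrinkage prior
        # leaves a residual gradient, confined to the cause block
        hidden = np.concatenate([g_mu[:15], g_mu[18:]])
        assert np.max(np.abs(hidden)) < 1e-6
        assert np.max(np.abs(g_mu[15:18])) < 1e-2

    def test_perception_step_returns_finite_agent(self, model):
        agent = make_agent(model, x_top0=np.array([2.0, 3.0, 25.0]),
                           x_bottom0=np.array([1.0, 2.0, 20.0]))
        exp = generalized_from_flow(model.in_tick_units(agent.dt),
                                    np.array([2.0, 3.0, 25.0]),
                                    np.array([1.0, 2.0, 20.0]), 24.0, 1.0)
        agent = AgentState(mu=exp.to_flat(), theta_mean=24.0,
                           theta_log_precision=8.0, prior_theta_mean=24.0,
                           prior_theta_log_precision=8.0, dt=agent.dt)
        sens = to_time_units(GeneralizedState(
            predict_sensory(model.in_tick_units(agent.dt), exp).values,
            agent.dt))
        updated = perception_step(agent, model, sens, agent.dt)
        assert np.all(np.isfinite(updated.mu))
        assert not np.array_equal(updated.mu, agent.mu)

    def test_gaussian_fixture_recovers_posterior_mean(self):
        """Gradient flow on the conjugate fixture converges to the
        analytic posterior mean within 1e-4 (Lemma-style fixed point)."""
        model = LinearGaussianModel(eta=0.8, prior_var=1.3, lik_var=0.6)
        s = np.array([-0.9])
        post = model.exact_posterior(s)
        q0 = GaussianBeliefs(np.array([3.0]), post.log_precisions)
        means, Fs = gaussian_perception_flow(model, s, q0)
        assert abs(means[-1, 0] - post.mean[0]) < 1e-4

    def test_descent_on_fixed_input(self):
        """With static sensory input, F is non-increasing along the flow."""
        model = LinearGaussianModel(eta=0.0, prior_var=1.0, lik_var=1.0)
        q0 = GaussianBeliefs(np.array([4.0]), np.array([0.2]))
        _, Fs = gaussian_perception_flow(model, np.array([1.0]), q0,
                                         n_steps=100)
        assert np.all(np.diff(Fs) <= 1e-8)


class TestAction:
    def test_silent_agent_emits_zero_amplitude(self, model):
        agent = make_agent(model, role="silent")
        amp, freq = action_step(agent, model)
        assert amp == 0.0 and freq == model.song.f_mid

    def test_singing_agent_voices_its_expectations(self, model):
        rng = np.random.default_rng(0)
        agent = make_agent(model, x_bottom0=rng.normal(size=3),
                           x_top0=rng.normal(size=3), role="singing")
        out = action_step(agent, model)
        x1 = agent.expectations.x_bottom.values[:, 0]
        assert out == song_observation(x1, model.song)

    def test_identical_expectations_identical_emissions(self, model):
        a = make_agent(model, x_bottom0=np.array([1.0, 2.0, 3.0]),
                       role="singing")
        b = make_agent(model, x_bottom0=np.array([1.0, 2.0, 3.0]),
                       role="singing")
        assert action_step(a, model) == action_step(b, model)

    def test_listening_agent_cannot_act(self, model):
        agent = make_agent(model, role="listening")
        with pytest.raises(ValueError, match="listening"):
            action_step(agent, model)


def _quadratic_trace(theta, theta_star, pi_data, agent):
    """One-tick trace of F(theta) = pi_d/2 (theta-theta*)^2 plus the
    agent's own prior term (as the recorded partials contain it)."""
    pi0 = math.exp(agent.prior_theta_log_precision)
    grad = pi_data * (theta - theta_star) + pi0 * (theta - agent.prior_theta_mean)
    curv = pi_data + pi0
    return EpochTrace(F=np.array([0.0]), dF_dtheta=np.array([grad]),
                      curvature=np.array([curv]), epoch_seconds=2.0,
                      n_ticks=1, sensory_gain=1.0)


class TestLearning:
    def test_infinitely_precise_prior_cannot_move(self, model):
        agent = make_agent(model, theta_prior_mean=24.0,
                           theta_prior_log_precision=32.0)
        trace = EpochTrace(F=np.ones(4), dF_dtheta=np.full(4, 5.0),
                           curvature=np.full(4, 1.0), epoch_seconds=2.0)
        updated = learning_step(agent, trace)
        assert abs(updated.theta_mean - agent.theta_mean) < 1e-6

    def test_quadratic_converges_to_precision_weighted_compromise(self, model):
        """Repeated updates settle on the Bayesian compromise between the
        data optimum and the prior mean."""
        theta_star, pi_data = 30.0, 4.0
        agent = make_agent(model, theta_prior_mean=24.0,
                           theta_prior_log_precision=0.0)
        for _ in range(60):
            agent = learning_step(agent,
                                  _quadratic_trace(agent.theta_mean, theta_star,
                                                   pi_data, agent))
        pi0 = 1.0
        expected = (pi_data * theta_star + pi0 * 24.0) / (pi_data + pi0)
        assert abs(agent.theta_mean - expected) < 1e-6

    def test_precision_never_decreases(self, model):
        rng = np.random.default_rng(3)
        agent = make_agent(model, theta_prior_log_precision=0.0)
        for _ in range(20):
            trace = EpochTrace(F=rng.normal(size=8),
                               dF_dtheta=rng.normal(size=8),
                               curvature=rng.normal(size=8),  # may be negative
                               epoch_seconds=2.0)
            updated = learning_step(agent, trace)
            assert updated.theta_log_precision >= agent.theta_log_precision - 1e-12
            agent = updated

    def test_zero_learning_scale_freezes_agent(self, model):
        agent = make_agent(model, theta_prior_log_precision=0.0)
        trace = EpochTrace(F=np.ones(4), dF_dtheta=np.full(4, 5.0),
                           curvature=np.full(4, 2.0), epoch_seconds=2.0)
        frozen = learning_step(agent, trace, learning_scale=0.0)
        assert frozen.theta_mean == agent.theta_mean
        assert frozen.theta_log_precision == agent.theta_log_precision

    def test_trust_region_bounds_step(self, model):
        agent = make_agent(model, theta_prior_log_precision=0.0)
        trace = EpochTrace(F=np.array([0.0]), dF_dtheta=np.array([1e6]),
                           curvature=np.array([0.0]), epoch_seconds=2.0,
                           n_ticks=512)
        updated = learning_step(agent, trace, trust_region=2.0)
        assert abs(updated.theta_mean - agent.theta_mean) <= 2.0 + 1e-12

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            EpochTrace(F=np.array([]), dF_dtheta=np.array([]),
                       curvature=np.array([]), epoch_seconds=2.0)


class TestConfidenceInterval:
    def test_unit_standard_deviation(self, model):
        agent = make_agent(model, theta_prior_mean=5.0,
                           theta_prior_log_precision=0.0)
        low, high = confidence_interval(agent, 0.90)
        assert low == pytest.approx(5.0 - 1.6449, abs=1e-3)
        assert high == pytest.approx(5.0 + 1.6449, abs=1e-3)

    def test_width_vanishes_with_precision(self, model):
        agent = make_agent(model, theta_prior_log_precision=40.0)
        low, high = confidence_interval(agent, 0.90)
        assert high - low < 1e-8

    def test_level_ratio_matches_gaussian_quantiles(self, model):
        agent = make_agent(model, theta_prior_log_precision=0.0)
        w90 = np.diff(confidence_interval(agent, 0.90))[0]
        w50 = np.diff(confidence_interval(agent, 0.50))[0]
        assert w90 / w50 == pytest.approx(1.6449 / 0.6745, abs=1e-3)

    def test_invalid_level_rejected(self, model):
        with pytest.raises(ValueError):
            confidence_interval(make_agent(model), 1.5)


def test_agent_state_invariants(model):
    with pytest.raises(ValueError, match="finite"):
        AgentState(mu=np.full(33, np.nan), theta_mean=24.0,
                   theta_log_precision=8.0, prior_theta_mean=24.0,
                   prior_theta_log_precision=8.0)
    with pytest.raises(ValueError, match="log-precision"):
        AgentState(mu=np.zeros(33), theta_mean=24.0,
                   theta_log_precision=1.0, prior_theta_mean=24.0,
                   prior_theta_log_precision=8.0)
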
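"""The active-inference agent.

Fast perception is a gradient flow on free energy in generalized
coordinates, mu_dot = D mu - kappa dF/dmu, integrated by local
linearization; action voices the current predictions as song; slow
learning updates the order parameter theta once per epoch from the
time-averaged free-energy gradient, with posterior precision accrued
from the epoch's curvature (so confidence intervals only ever shrink).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.stats import norm

from .generalized_coords import (GeneralizedState, phi1_matrix, shift_matrix,
                                 to_tick_units)
from .generative_model import (DIM_MU, N_ORD_V, N_ORD_X, N_STATES,
                               BirdsongEnergy, Expectations, HierarchicalModel,
                               silent_sample, song_observation)

Role = Literal["singing", "listening", "silent"]

_PREC_SLACK = 1e-9


@dataclass(frozen=True)
class AgentState:
    """Posterior expectations and order-parameter beliefs of one agent."""

    mu: np.ndarray                    # flattened generalized expectations
    theta_mean: float
    theta_log_precision: float
    prior_theta_mean: float
    prior_theta_log_precision: float
    role: Role = "silent"
    dt: float = 1.0 / 256.0

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        if not np.all(np.isfinite(mu)):
            raise ValueError("agent expectations must be finite")
        if self.theta_log_precision < self.prior_theta_log_precision - _PREC_SLACK:
            raise ValueError("posterior log-precision cannot fall below the prior's")
        if self.role not in ("singing", "listening", "silent"):
            raise ValueError(f"unknown role {self.role!r}")
        object.__setattr__(self, "mu", mu)

    @property
    def expectations(self) -> Expectations:
        return Expectations.from_flat(self.mu, self.dt)

    def with_role(self, role: Role) -> "AgentState":
        return replace(self, role=role)


def make_agent(model: HierarchicalModel, *, theta_prior_mean: float | None = None,
               theta_prior_log_precision: float | None = None,
               x_top0: np.ndarray | None = None, x_bottom0: np.ndarray | None = None,
               dt: float = 1.0 / 256.0, role: Role = "silent") -> AgentState:
    """Agent with expectations seeded at the given order-0 values (higher
    orders zero, cause consistent with the top level)."""
    prior = model.order_parameters["rho_base"]
    pm = prior.mean if theta_prior_mean is None else float(theta_prior_mean)
    plp = (prior.log_precision if theta_prior_log_precision is None
           else float(theta_prior_log_precision))
    mu = np.zeros(DIM_MU)
    if x_bottom0 is not None:
        mu[0:15].reshape(N_STATES, N_ORD_X)[:, 0] = x_bottom0
    if x_top0 is not None:
        mu[18:33].reshape(N_STATES, N_ORD_X)[:, 0] = x_top0
        mu[15] = float(model.top.output_map @ np.asarray(x_top0, dtype=float))
    return AgentState(mu=mu, theta_mean=pm, theta_log_precision=plp,
                      prior_theta_mean=pm, prior_theta_log_precision=plp,
                      role=role, dt=dt)


# ---------------------------------------------------------------------------
# Perception
# ---------------------------------------------------------------------------

def _full_shift_matrix() -> np.ndarray:
    blocks = [shift_matrix(N_ORD_X)] * N_STATES + [shift_matrix(N_ORD_V)] \
        + [shift_matrix(N_ORD_X)] * N_STATES
    D = np.zeros((DIM_MU, DIM_MU))
    pos = 0
    for b in blocks:
        n = b.shape[0]
        D[pos:pos + n, pos:pos + n] = b
        pos += n
    return D


_D_FULL = _full_shift_matrix()


class PerceptionIntegrator:
    """Local-linearization stepper for the perception gradient flow.

    The propagator uses the finite-difference curvature of F (refreshed
    every ``refresh_every`` ticks, and whenever the sensory gain changes);
    gradients are central finite differences at every tick.  Each step is
    guarded by a free-energy backtracking rule: if the full step would
    blow F up (local linearization overshooting the Lorenz nonlinearity),
    the corrective part is geometrically damped toward the pure
    prediction step mu + phi1(D) D mu, which is always bounded.
    """

    #: accept a step when F_new <= F0 + this margin (nats); absolute, so
    #: the rule is invariant to the arbitrary log-determinant constant
    _MERIT_MARGIN = 25.0

    def __init__(self, energy: BirdsongEnergy, dt: float = 1.0, kappa: float = 0.5,
                 refresh_every: int = 8, max_backtracks: int = 6):
        self.energy = energy
        self.dt = float(dt)  # in sample units: one tick = 1.0
        self.kappa = float(kappa)
        self.refresh_every = int(refresh_every)
        self.max_backtracks = int(max_backtracks)
        self._M: np.ndarray | None = None
        self._M_pred = phi1_matrix(_D_FULL, self.dt) @ _D_FULL
        self._ticks_since_refresh = 0
        self._gain: float | None = None
        self.n_backtracks = 0  # diagnostic counter

    def refresh(self, mu: np.ndarray, s: np.ndarray, theta: float, gain: float) -> None:
        H = self.energy.fd_hessian(mu, s, theta, gain)
        J = _D_FULL - self.kappa * H
        M = phi1_matrix(J, self.dt)
        if not np.all(np.isfinite(M)):
            M = self.dt * np.eye(DIM_MU)  # Euler fallback
        self._M = M
        self._ticks_since_refresh = 0
        self._gain = gain

    def step(self, mu: np.ndarray, s: np.ndarray, theta: float, gain: float
             ) -> tuple[np.ndarray, float, float, float]:
        """One dt of gradient flow; returns (mu_new, F, dF/dtheta, d2F/dtheta2)."""
        if (self._M is None or self._gain != gain
                or self._ticks_since_refresh >= self.refresh_every):
            self.refresh(mu, s, theta, gain)
        F0, g_mu, g_th, c_th = self.energy.grads(mu, s, theta, gain)
        step_pred = self._M_pred @ mu
        step_corr = self._M @ (_D_FULL @ mu - self.kappa * g_mu) - step_pred
        merit = F0 + self._MERIT_MARGIN
        alpha = 1.0
        mu_new = mu + step_pred + step_corr
        for _ in range(self.max_backtracks):
            if (np.all(np.isfinite(mu_new))
                    and self.energy.F_batch(mu_new[None], s, theta, gain)[0] <= merit):
                break
            alpha *= 0.25
            self.n_backtracks += 1
            mu_new = mu + step_pred + alpha * step_corr
            self._ticks_since_refresh = self.refresh_every  # force refresh next tick
        else:
            mu_new = mu + step_pred  # pure prediction; always bounded
        if not np.all(np.isfinite(mu_new)):
            bad = int(np.argmax(~np.isfinite(mu_new)))
            raise FloatingPointError(
                f"perception update diverged at flat coordinate {bad}")
        self._ticks_since_refresh += 1
        return mu_new, F0, g_th, c_th


def perception_step(agent: AgentState, model: HierarchicalModel,
                    sensory: GeneralizedState, dt: float, *, kappa: float = 0.5,
                    gain: float = 1.0, energy: BirdsongEnergy | None = None
                    ) -> AgentState:
    """One perception update of the agent's expectations.

    mu <- integrate (D mu - kappa dF/dmu) over one sample step dt, with F
    evaluated at the supplied generalized sensory signal (derivatives per
    second; converted to per-sample units internally, which is also the
    convention of ``agent.mu``).
    """
    if sensory.values.shape != (model.sensory_dim, N_ORD_X):
        raise ValueError("sensory signal must be in matching generalized coordinates")
    s_ticks = to_tick_units(GeneralizedState(sensory.values, dt)).values
    energy = energy or BirdsongEnergy(model, agent.prior_theta_mean,
                                      agent.prior_theta_log_precision, dt=dt)
    stepper = PerceptionIntegrator(energy, kappa=kappa, refresh_every=1)
    mu_new, _, _, _ = stepper.step(agent.mu, s_ticks, agent.theta_mean, gain)
    return replace(agent, mu=mu_new)


def gaussian_perception_flow(model, s, q0, *, kappa: float = 0.5,
                             dt: float = 0.05, n_steps: int = 600):
    """Perception as gradient flow on the static linear-Gaussian fixture.

    Runs mu_dot = -kappa dF/dmu (no shift: the model is static) with the
    package integrator until the expectations settle; the fixed point is
    the analytic posterior mean.  Returns (mean trajectory, F trajectory).
    """
    from .free_energy import free_energy_gaussian, GaussianBeliefs
    from .generalized_coords import GeneralizedState, integrate_flow

    logp = q0.log_precisions

    def F_of(mean: np.ndarray) -> float:
        return free_energy_gaussian(model, s, GaussianBeliefs(mean, logp)).F

    def flow(state: GeneralizedState) -> np.ndarray:
        mean = state.values[:, 0]
        g = np.empty_like(mean)
        for i in range(mean.size):
            h = 1e-5 * max(1.0, abs(mean[i]))
            up, dn = mean.copy(), mean.copy()
            up[i] += h
            dn[i] -= h
            g[i] = (F_of(up) - F_of(dn)) / (2 * h)
        return (-kappa * g)[:, None]

    state = GeneralizedState(q0.mean[:, None], dt)
    means = [state.values[:, 0].copy()]
    Fs = [F_of(means[0])]
    for _ in range(n_steps):
        state = integrate_flow(flow, state, dt)
        means.append(state.values[:, 0].copy())
        Fs.append(F_of(means[-1]))
    return np.array(means), np.array(Fs)


# ---------------------------------------------------------------------------
# Action
# ---------------------------------------------------------------------------

def action_step(agent: AgentState, model: HierarchicalModel) -> tuple[float, float]:
    """Emit one song sample: the sonogram the agent's expectations predict.

    Action is the voicing of proprioceptive predictions — singing emits
    song_observation at the current bottom-level expectations; a silent
    agent emits the zero-amplitude sample.  A listening agent does not act.
    """
    if agent.role == "listening":
        raise ValueError("a listening agent does not emit samples")
    if agent.role == "silent":
        return silent_sample(model.song)
    x1 = agent.mu[0:15].reshape(N_STATES, N_ORD_X)[:, 0]
    return song_observation(x1, model.song)


# ---------------------------------------------------------------------------
# Learning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EpochTrace:
    """F, dF/dtheta and d2F/dtheta2 recorded over one epoch.

    The arrays are either per-tick records or single epoch-level
    estimates; ``n_ticks`` gives the number of samples the epoch actually
    contained (the evidence multiplicity), and ``sensory_gain`` the mean
    sensory precision gain — attention gates how much the epoch can teach.
    """

    F: np.ndarray
    dF_dtheta: np.ndarray
    curvature: np.ndarray
    epoch_seconds: float
    n_ticks: int | None = None
    sensory_gain: float = 1.0

    def __post_init__(self) -> None:
        F = np.atleast_1d(np.asarray(self.F, dtype=float))
        g = np.atleast_1d(np.asarray(self.dF_dtheta, dtype=float))
        c = np.atleast_1d(np.asarray(self.curvature, dtype=float))
        if F.size == 0:
            raise ValueError("epoch trace must be non-empty")
        if not (F.shape == g.shape == c.shape):
            raise ValueError("trace components must share one time axis")
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "dF_dtheta", g)
        object.__setattr__(self, "curvature", c)
        object.__setattr__(self, "n_ticks",
                           int(self.n_ticks) if self.n_ticks is not None else F.size)


def learning_step(agent: AgentState, trace: EpochTrace, *, eta: float = 1.0,
                  learning_scale: float = 1.0,
                  trust_region: float | None = None) -> AgentState:
    """Slow (epoch-wise) Bayesian update of the order parameter.

    Every tick's F carries the full theta-prior term, so the epoch-mean
    gradient is first split into the prior pull (counted once) and the
    data gradient (counted once per tick, gated by the sensory gain):

        g_data = n_ticks * gain * (mean dF/dtheta - pi0 (theta - thbar))

    Posterior precision accrues the matching data curvature (floored at
    zero, so precision — and the credible interval — never loosens), and
    theta takes a natural-gradient step on prior + data, clipped to the
    ``trust_region`` within which the epoch-level derivative estimates
    are valid.  ``learning_scale`` scales the whole update (0 freezes the
    agent — the frozen-niche control).
    """
    if not 0.0 <= learning_scale:
        raise ValueError("learning_scale must be non-negative")
    if learning_scale == 0.0:
        return agent
    pi0 = math.exp(agent.prior_theta_log_precision)
    prior_grad = pi0 * (agent.theta_mean - agent.prior_theta_mean)
    mean_grad = float(np.mean(trace.dF_dtheta))
    mean_curv = float(np.mean(trace.curvature))
    weight = trace.n_ticks * trace.sensory_gain
    g_data = weight * (mean_grad - prior_grad)
    c_data = max(0.0, weight * (mean_curv - pi0))
    pi_new = math.exp(agent.theta_log_precision) + c_data * learning_scale
    step = -eta * learning_scale * (g_data + prior_grad) / pi_new
    if trust_region is not None:
        step = max(-trust_region, min(trust_region, step))
    return replace(agent, theta_mean=agent.theta_mean + step,
                   theta_log_precision=math.log(pi_new))


def confidence_interval(agent: AgentState, level: float = 0.90) -> tuple[float, float]:
    """Central Bayesian credible interval for theta at the given level."""
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    z = float(norm.ppf(0.5 + level / 2.0))
    half = z * math.exp(-agent.theta_log_precision / 2.0)
    return agent.theta_mean - half, agent.theta_mean + half
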
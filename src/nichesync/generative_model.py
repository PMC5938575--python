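"""Hierarchical dynamic generative model of birdsong.

Two Lorenz systems stacked in time: a slow "area X" level whose output
cause modulates the Rayleigh number (rho) of a fast "HVC" level, whose
states are voiced as a sonogram (amplitude, frequency).  The learnable
order parameter is the song level's baseline Rayleigh number rho_base
(rho1 = rho_base + v) — the trait that determines the chaotic structure
of the songs and that the duet experiments exchange.

Dynamics, observations and prediction errors are all expressed in
generalized coordinates (value + temporal derivatives): hidden states and
sensory channels carry 4 derivatives, causes carry 2.  Nonlinear maps are
closed at first order (higher derivative orders propagate through the
base-point Jacobian), the standard local-linearization treatment.

Precisions are diagonal, log-parametrized, and specified per characteristic
channel scale; across derivative orders they follow the smoothness-based
profile for noise with Gaussian autocorrelation of width ``smoothness``:
precision of order k scales as s^(2k) / (2k-1)!!.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.special import expit

from .free_energy import LN2PI, FreeEnergyReport
from .generalized_coords import GeneralizedState

# Embedding orders: n = 4 for hidden states and sensory channels, n = 2 for causes.
N_ORD_X = 5
N_ORD_V = 3
N_STATES = 3  # hidden states per Lorenz level
DIM_MU = 2 * N_STATES * N_ORD_X + N_ORD_V  # 33

_SL_BOTTOM = slice(0, 15)
_SL_CAUSE = slice(15, 18)
_SL_TOP = slice(18, 33)

_DOUBLE_FACT = np.array([1.0, 1.0, 3.0, 15.0, 105.0])  # (2k-1)!! for k = 0..4


def order_weights(n_orders: int, smoothness: float) -> np.ndarray:
    """Relative precision of derivative order k: s^(2k) / (2k-1)!!."""
    k = np.arange(n_orders)
    return smoothness ** (2 * k) / _DOUBLE_FACT[:n_orders]


@dataclass(frozen=True)
class SongMap:
    """States -> sonogram coordinates.

    amplitude = softplus(a0 + a1 * x2) (arbitrary units, >= 0);
    frequency = f_mid + f_band * tanh(f_gain * (x3 - x3_ref) / f_band),
    a smooth saturation that keeps the channel strictly inside the
    songbird band (f_mid +/- f_band) while preserving gradients.
    """

    a0: float = 0.0
    a1: float = 0.3
    f_mid: float = 3500.0
    f_gain: float = 60.0
    f_band: float = 1500.0
    x3_ref: float = 24.0

    @property
    def f_lo(self) -> float:
        return self.f_mid - self.f_band

    @property
    def f_hi(self) -> float:
        return self.f_mid + self.f_band


@dataclass(frozen=True)
class LevelSpec:
    """One level of the hierarchy: Lorenz flow parameters, the linear map
    from hidden states to the outgoing cause, and noise log-precisions."""

    flow_params: Mapping[str, float]
    output_map: np.ndarray
    log_precision_states: float  # gamma_w
    log_precision_output: float  # gamma_z (sensory) or gamma_v (cause)

    def __post_init__(self) -> None:
        for name in ("sigma", "beta", "tau"):
            if name not in self.flow_params:
                raise ValueError(f"flow_params missing {name!r}")
        if not self.flow_params["tau"] > 0:
            raise ValueError("tau must be positive")
        for v in self.flow_params.values():
            if not np.isfinite(v):
                raise ValueError("flow parameters must be finite")
        if not (np.isfinite(self.log_precision_states) and np.isfinite(self.log_precision_output)):
            raise ValueError("log-precisions must be finite")
        object.__setattr__(self, "output_map",
                           np.asarray(self.output_map, dtype=float).reshape(-1))


@dataclass(frozen=True)
class OrderParameterPrior:
    mean: float
    log_precision: float


@dataclass(frozen=True)
class Scales:
    """Characteristic scales dividing each channel before precision
    weighting (Pi_eff = exp(gamma) / scale^2)."""

    amplitude: float = 0.5   # a.u.
    frequency: float = 150.0  # Hz
    state: float = 10.0      # Lorenz state units
    cause: float = 2.0       # cause units


@dataclass(frozen=True)
class HierarchicalModel:
    """Ordered levels (top = slowest first) plus the learnable order
    parameters; houses the generative density p(s, psi)."""

    levels: tuple[LevelSpec, ...]
    order_parameters: Mapping[str, OrderParameterPrior]
    sensory_dim: int = 2
    song: SongMap = field(default_factory=SongMap)
    scales: Scales = field(default_factory=Scales)
    smoothness: float = 1.0 / 128.0  # noise autocorrelation width, seconds
    cause_prior_log_precision: float = 0.0  # zero-mean shrinkage prior on v

    def __post_init__(self) -> None:
        if len(self.levels) < 1:
            raise ValueError("model needs at least one level")
        if self.top.output_map.shape != (N_STATES,):
            raise ValueError("top-level output map must send 3 hidden states to 1 cause")
        if not self.smoothness > 0:
            raise ValueError("smoothness must be positive")

    @property
    def top(self) -> LevelSpec:
        return self.levels[0]

    @property
    def bottom(self) -> LevelSpec:
        return self.levels[-1]

    def in_tick_units(self, dt: float) -> "HierarchicalModel":
        """The same model with time measured in integration steps.

        Generalized filtering is numerically well-conditioned when one
        sample is one time unit (derivative magnitudes then decay with
        order instead of exploding as ||J||^k); only the time constants
        and the noise smoothness carry units, so only they rescale.
        """
        if not dt > 0:
            raise ValueError("dt must be positive")
        levels = tuple(replace(lv, flow_params=dict(lv.flow_params,
                                                    tau=lv.flow_params["tau"] / dt))
                       for lv in self.levels)
        return replace(self, levels=levels, smoothness=self.smoothness / dt)


def birdsong_model(*, rho_base_prior_mean: float = 24.0,
                   rho_base_prior_log_precision: float = 8.0,
                   rho_top: float = 28.0,
                   tau_top: float = 2.0, tau_bottom: float = 0.25,
                   gamma_w: float = 8.0, gamma_z: float = 4.0, gamma_v: float = 6.0,
                   gamma_v_prior: float = -6.0, output_gain: float = 0.32,
                   song: SongMap | None = None, scales: Scales | None = None,
                   smoothness: float = 1.0 / 128.0) -> HierarchicalModel:
    """The default two-level chaotic birdsong model.

    The top (area X) Lorenz runs at ``tau_top`` seconds with fixed
    ``rho_top``; its second state, scaled by ``output_gain``, is the cause
    v that modulates the bottom (HVC) level's rho around the learnable
    baseline: rho1 = rho_base + v.
    """
    top = LevelSpec(flow_params={"sigma": 10.0, "beta": 8.0 / 3.0, "tau": tau_top,
                                 "rho": rho_top},
                    output_map=np.array([0.0, output_gain, 0.0]),
                    log_precision_states=gamma_w, log_precision_output=gamma_v)
    bottom = LevelSpec(flow_params={"sigma": 10.0, "beta": 8.0 / 3.0, "tau": tau_bottom},
                       output_map=np.zeros(N_STATES),
                       log_precision_states=gamma_w, log_precision_output=gamma_z)
    return HierarchicalModel(
        levels=(top, bottom),
        order_parameters={"rho_base": OrderParameterPrior(rho_base_prior_mean,
                                                          rho_base_prior_log_precision)},
        song=song or SongMap(), scales=scales or Scales(), smoothness=smoothness,
        cause_prior_log_precision=gamma_v_prior)


# ---------------------------------------------------------------------------
# Flows and observations
# ---------------------------------------------------------------------------

def lorenz_flow(x: np.ndarray, params: Mapping[str, float]) -> np.ndarray:
    """Classic Lorenz vector field scaled by the time constant tau."""
    for v in params.values():
        if not np.isfinite(v):
            raise ValueError("flow parameters must be finite")
    if not params["tau"] > 0:
        raise ValueError("tau must be positive")
    x = np.asarray(x, dtype=float)
    sigma, rho, beta, tau = params["sigma"], params["rho"], params["beta"], params["tau"]
    return np.array([sigma * (x[1] - x[0]),
                     x[0] * (rho - x[2]) - x[1],
                     x[0] * x[1] - beta * x[2]]) / tau


def lorenz_jacobian(x: np.ndarray, params: Mapping[str, float]) -> np.ndarray:
    sigma, rho, beta, tau = params["sigma"], params["rho"], params["beta"], params["tau"]
    return np.array([[-sigma, sigma, 0.0],
                     [rho - x[2], -1.0, -x[0]],
                     [x[1], x[0], -beta]]) / tau


def song_observation(x1: np.ndarray, song: SongMap = SongMap()) -> tuple[float, float]:
    """Map bottom-level hidden states to (amplitude a.u., frequency Hz)."""
    x1 = np.asarray(x1, dtype=float)
    if not np.all(np.isfinite(x1)):
        raise ValueError("hidden state must be finite")
    amp = float(np.logaddexp(0.0, song.a0 + song.a1 * x1[1]))
    u = song.f_gain * (x1[2] - song.x3_ref) / song.f_band
    freq = float(song.f_mid + song.f_band * math.tanh(u))
    return amp, freq


def silent_sample(song: SongMap = SongMap()) -> tuple[float, float]:
    """The zero-amplitude sample delivered when nothing is audible."""
    return 0.0, song.f_mid


@dataclass(frozen=True)
class Expectations:
    """Per-level expectations in generalized coordinates, plus the cause."""

    x_top: GeneralizedState      # (3, 5)
    cause: GeneralizedState      # (1, 3)
    x_bottom: GeneralizedState   # (3, 5)

    def __post_init__(self) -> None:
        if self.x_top.values.shape != (N_STATES, N_ORD_X):
            raise ValueError("x_top must be (3, 5)")
        if self.cause.values.shape != (1, N_ORD_V):
            raise ValueError("cause must be (1, 3)")
        if self.x_bottom.values.shape != (N_STATES, N_ORD_X):
            raise ValueError("x_bottom must be (3, 5)")

    def to_flat(self) -> np.ndarray:
        return np.concatenate([self.x_bottom.values.ravel(),
                               self.cause.values.ravel(),
                               self.x_top.values.ravel()])

    @classmethod
    def from_flat(cls, mu: np.ndarray, dt: float) -> "Expectations":
        mu = np.asarray(mu, dtype=float)
        if mu.shape != (DIM_MU,):
            raise ValueError(f"flat expectations must have length {DIM_MU}")
        return cls(x_top=GeneralizedState(mu[_SL_TOP].reshape(N_STATES, N_ORD_X), dt),
                   cause=GeneralizedState(mu[_SL_CAUSE].reshape(1, N_ORD_V), dt),
                   x_bottom=GeneralizedState(mu[_SL_BOTTOM].reshape(N_STATES, N_ORD_X), dt))


def _generalized_level_flow(x: np.ndarray, params: dict,
                            v: np.ndarray | None = None) -> np.ndarray:
    """Generalized flow of one Lorenz level, closed at first order.

    ``x`` is (3, n_orders); order 0 of the result is the exact flow, order
    k >= 1 is J(x0) @ x[:, k] (+ the rho-channel contribution of the cause
    derivative when a cause drives this level)."""
    n_orders = x.shape[1]
    out = np.empty_like(x)
    out[:, 0] = lorenz_flow(x[:, 0], params)
    J = lorenz_jacobian(x[:, 0], params)
    out[:, 1:] = J @ x[:, 1:]
    if v is not None:
        drho = np.array([0.0, x[0, 0], 0.0]) / params["tau"]
        for k in range(1, min(n_orders, v.shape[0])):
            out[:, k] += drho * v[k]
    return out


def model_flow(model: HierarchicalModel, hidden: Mapping[str, GeneralizedState],
               params: Mapping[str, float]) -> dict[str, np.ndarray]:
    """Generalized state derivatives for each level (generative direction).

    The top level evolves autonomously with its fixed rho; its output
    cause v = output_map @ x_top modulates the bottom level's rho around
    the learnable baseline: rho1 = params['rho_base'] + v.
    """
    x_top = hidden["top"].values
    x_bottom = hidden["bottom"].values
    if x_top.shape[0] != N_STATES or x_bottom.shape[0] != N_STATES:
        raise ValueError("each Lorenz level carries exactly three hidden states")
    top_params = dict(model.top.flow_params)
    v = model.top.output_map @ x_top  # (n_orders,) generalized cause
    bottom_params = dict(model.bottom.flow_params,
                         rho=float(params["rho_base"]) + v[0])
    return {"top": _generalized_level_flow(x_top, top_params),
            "bottom": _generalized_level_flow(x_bottom, bottom_params,
                                              v=v[:N_ORD_V])}


def generalized_from_flow(model: HierarchicalModel, x_top0: np.ndarray,
                          x_bottom0: np.ndarray, theta: float,
                          dt: float) -> Expectations:
    """Expectations whose derivative orders satisfy the model's own
    (first-order-closed) flow exactly, so every prediction error vanishes.

    ``theta`` is the song level's baseline rho (the learnable order
    parameter)."""
    top_params = dict(model.top.flow_params)
    x_t = np.zeros((N_STATES, N_ORD_X))
    x_t[:, 0] = x_top0
    J_t = lorenz_jacobian(x_top0, top_params)
    x_t[:, 1] = lorenz_flow(x_top0, top_params)
    for k in range(1, N_ORD_X - 1):
        x_t[:, k + 1] = J_t @ x_t[:, k]
    v = model.top.output_map @ x_t[:, :N_ORD_V]  # (3,)

    bottom_params = dict(model.bottom.flow_params, rho=float(theta) + v[0])
    drho = np.array([0.0, x_bottom0[0], 0.0]) / bottom_params["tau"]
    x_b = np.zeros((N_STATES, N_ORD_X))
    x_b[:, 0] = x_bottom0
    J_b = lorenz_jacobian(x_bottom0, bottom_params)
    x_b[:, 1] = lorenz_flow(x_bottom0, bottom_params)
    for k in range(1, N_ORD_X - 1):
        x_b[:, k + 1] = J_b @ x_b[:, k]
        if k < N_ORD_V:
            x_b[:, k + 1] += drho * v[k]
    return Expectations(x_top=GeneralizedState(x_t, dt),
                        cause=GeneralizedState(v[None, :], dt),
                        x_bottom=GeneralizedState(x_b, dt))


def predict_sensory(model: HierarchicalModel, expectations: Expectations) -> GeneralizedState:
    """Generalized sonogram prediction at the current expectations."""
    x_b = expectations.x_bottom.values
    song = model.song
    amp0, freq0 = song_observation(x_b[:, 0], song)
    z = song.a0 + song.a1 * x_b[1, 0]
    damp = song.a1 * float(expit(z))
    u = song.f_gain * (x_b[2, 0] - song.x3_ref) / song.f_band
    dfreq = song.f_gain * (1.0 - math.tanh(u) ** 2)
    pred = np.zeros((2, N_ORD_X))
    pred[0, 0], pred[1, 0] = amp0, freq0
    pred[0, 1:] = damp * x_b[1, 1:]
    pred[1, 1:] = dfreq * x_b[2, 1:]
    return GeneralizedState(pred, expectations.x_bottom.dt)


def prediction_errors(model: HierarchicalModel, expectations: Expectations,
                      params: Mapping[str, float],
                      sensory: GeneralizedState) -> dict[str, np.ndarray]:
    """Hierarchical prediction errors in generalized coordinates.

    z1: sensory minus sonogram prediction (2, 5);
    z2: cause minus top-level output prediction (3,);
    w1/w2: shift of expectations minus model flow at bottom/top (3, 4) —
    flow errors carry orders 0..n-1, since the shift of the top order is
    identically zero under the truncation.
    """
    if sensory.values.shape != (model.sensory_dim, N_ORD_X):
        raise ValueError("sensory signal must match (sensory_dim, 5) generalized shape")
    eps_z1 = sensory.values - predict_sensory(model, expectations).values

    x_t, x_b = expectations.x_top.values, expectations.x_bottom.values
    v = expectations.cause.values[0]
    eps_z2 = v - model.top.output_map @ x_t[:, :N_ORD_V]

    top_params = dict(model.top.flow_params)
    bottom_params = dict(model.bottom.flow_params,
                         rho=float(params["rho_base"]) + v[0])
    f_top = _generalized_level_flow(x_t, top_params)
    f_bot = _generalized_level_flow(x_b, bottom_params, v=v)

    return {"z1": eps_z1, "z2": eps_z2,
            "w1": x_b[:, 1:] - f_bot[:, :-1], "w2": x_t[:, 1:] - f_top[:, :-1]}


def cause_prior_precisions(model: HierarchicalModel) -> np.ndarray:
    """Diagonal precision of the zero-mean shrinkage prior on the cause.

    Causes are modelled as fluctuations about zero; the shrinkage prior
    anchors their scale."""
    w3 = order_weights(N_ORD_V, model.smoothness)
    return math.exp(model.cause_prior_log_precision) * w3 / model.scales.cause**2


def error_precisions(model: HierarchicalModel, gain: float = 1.0) -> dict[str, np.ndarray]:
    """Diagonal precisions matching `prediction_errors`, per order and scale."""
    if gain <= 0:
        raise ValueError("sensory gain must be strictly positive")
    s = model.scales
    w5 = order_weights(N_ORD_X, model.smoothness)
    w3 = order_weights(N_ORD_V, model.smoothness)
    pz = gain * math.exp(model.bottom.log_precision_output) * w5
    return {
        "z1": np.stack([pz / s.amplitude**2, pz / s.frequency**2]),
        "z2": math.exp(model.top.log_precision_output) * w3 / s.cause**2,
        "w1": np.broadcast_to(math.exp(model.bottom.log_precision_states)
                              * w5[:-1] / s.state**2, (N_STATES, N_ORD_X - 1)).copy(),
        "w2": np.broadcast_to(math.exp(model.top.log_precision_states)
                              * w5[:-1] / s.state**2, (N_STATES, N_ORD_X - 1)).copy(),
    }


# ---------------------------------------------------------------------------
# Generative-process simulation (the "true" song generator, noise-free)
# ---------------------------------------------------------------------------

def simulate_lorenz(params: Mapping[str, float], x0: np.ndarray, n_steps: int,
                    dt: float) -> np.ndarray:
    """RK4 reference run of a single Lorenz level; returns (n_steps+1, 3)."""
    traj = np.empty((n_steps + 1, N_STATES))
    traj[0] = np.asarray(x0, dtype=float)
    for i in range(n_steps):
        traj[i + 1] = _rk4(lambda x: lorenz_flow(x, params), traj[i], dt)
    return traj


def simulate_generative(model: HierarchicalModel, x_top0: np.ndarray,
                        x_bottom0: np.ndarray, theta: float, n_steps: int,
                        dt: float) -> dict[str, np.ndarray]:
    """Integrate the full two-level model (RK4) and voice the song.

    Returns trajectories for both levels, the cause, and the emitted
    (amplitude, frequency) channels, all of length n_steps + 1.
    """
    top_params = dict(model.top.flow_params)
    w = model.top.output_map

    def joint_flow(z: np.ndarray) -> np.ndarray:
        xt, xb = z[:N_STATES], z[N_STATES:]
        v = w @ xt
        fb = lorenz_flow(xb, dict(model.bottom.flow_params, rho=float(theta) + v))
        ft = lorenz_flow(xt, top_params)
        return np.concatenate([ft, fb])

    z = np.concatenate([np.asarray(x_top0, float), np.asarray(x_bottom0, float)])
    top = np.empty((n_steps + 1, N_STATES))
    bottom = np.empty((n_steps + 1, N_STATES))
    song = np.empty((n_steps + 1, 2))
    for i in range(n_steps + 1):
        top[i], bottom[i] = z[:N_STATES], z[N_STATES:]
        song[i] = song_observation(bottom[i], model.song)
        if i < n_steps:
            z = _rk4(joint_flow, z, dt)
    return {"top": top, "bottom": bottom, "cause": top @ w, "song": song}


def _rk4(f, x: np.ndarray, dt: float) -> np.ndarray:
    k1 = f(x)
    k2 = f(x + 0.5 * dt * k1)
    k3 = f(x + 0.5 * dt * k2)
    k4 = f(x + dt * k3)
    return x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


# ---------------------------------------------------------------------------
# Fused batched energy (the agent's fast path)
# ---------------------------------------------------------------------------

class BirdsongEnergy:
    """Vectorized Laplace free energy of the birdsong model.

    Evaluates F for a batch of flattened expectation vectors in one pass;
    this is what makes finite-difference gradient flows affordable at
    dt = 1/256.  Agrees with `prediction_errors` + `laplace_free_energy`
    (the straight-line reference path) to floating-point accuracy.
    """

    def __init__(self, model: HierarchicalModel, theta_prior_mean: float | None = None,
                 theta_prior_log_precision: float | None = None,
                 dt: float = 1.0 / 256.0):
        prior = model.order_parameters["rho_base"]
        self.seconds_model = model
        self.dt = float(dt)
        model = model.in_tick_units(dt)
        self.model = model  # tick-unit model: all internal math is per sample
        self.theta_prior_mean = float(prior.mean if theta_prior_mean is None
                                      else theta_prior_mean)
        self.theta_prior_log_precision = float(
            prior.log_precision if theta_prior_log_precision is None
            else theta_prior_log_precision)
        prec = error_precisions(model, gain=1.0)
        self._Wz = prec["z1"]            # (2, 5)
        self._Wv = prec["z2"]            # (3,)
        self._Wvp = cause_prior_precisions(model)  # (3,)
        self._Ww = prec["w1"][0]         # (4,) shared across the 3 state dims
        self._w_map = model.top.output_map
        top, bottom = model.top.flow_params, model.bottom.flow_params
        self._sigma_t, self._beta_t, self._tau_t = top["sigma"], top["beta"], top["tau"]
        self._rho_t = top["rho"]
        self._sigma_b, self._beta_b, self._tau_b = bottom["sigma"], bottom["beta"], bottom["tau"]
        self._pi_theta = math.exp(self.theta_prior_log_precision)
        # gain-independent part of the log-determinant constant
        self._logdet_wv = (-0.5 * float(np.sum(np.log(self._Wv) - LN2PI))
                           - 0.5 * float(np.sum(np.log(self._Wvp) - LN2PI))
                           - 0.5 * 2 * N_STATES * float(np.sum(np.log(self._Ww) - LN2PI))
                           - 0.5 * (math.log(self._pi_theta) - LN2PI))
        self._logdet_z_unit = -0.5 * float(np.sum(np.log(self._Wz) - LN2PI))

    # -- core -------------------------------------------------------------
    def _quadratics(self, mu: np.ndarray, s: np.ndarray, theta: np.ndarray,
                    gain: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        mu = np.atleast_2d(np.asarray(mu, dtype=float))
        B = mu.shape[0]
        theta = np.broadcast_to(np.asarray(theta, dtype=float), (B,))
        x1 = mu[:, _SL_BOTTOM].reshape(B, N_STATES, N_ORD_X)
        v = mu[:, _SL_CAUSE]
        x2 = mu[:, _SL_TOP].reshape(B, N_STATES, N_ORD_X)
        song = self.model.song

        # sensory prediction (first-order closure)
        z = song.a0 + song.a1 * x1[:, 1, 0]
        amp0 = np.logaddexp(0.0, z)
        damp = song.a1 * expit(z)
        u = song.f_gain * (x1[:, 2, 0] - song.x3_ref) / song.f_band
        th = np.tanh(u)
        freq0 = song.f_mid + song.f_band * th
        dfreq = song.f_gain * (1.0 - th**2)
        pred = np.empty((B, 2, N_ORD_X))
        pred[:, 0, 0], pred[:, 1, 0] = amp0, freq0
        pred[:, 0, 1:] = damp[:, None] * x1[:, 1, 1:]
        pred[:, 1, 1:] = dfreq[:, None] * x1[:, 2, 1:]
        eps_z = s[None, :, :] - pred
        quad_z = 0.5 * gain * np.einsum("bck,ck->b", eps_z**2, self._Wz)

        # cause error
        pred_v = np.einsum("j,bjk->bk", self._w_map, x2[:, :, :N_ORD_V])
        eps_v = v - pred_v
        quad_v = (0.5 * np.einsum("bk,k->b", eps_v**2, self._Wv)
                  + 0.5 * np.einsum("bk,k->b", v**2, self._Wvp))

        quad_w1 = self._flow_quad(x1, rho=theta + v[:, 0],
                                  sigma=self._sigma_b, beta=self._beta_b,
                                  tau=self._tau_b, v=v)
        quad_w2 = self._flow_quad(x2, rho=self._rho_t, sigma=self._sigma_t,
                                  beta=self._beta_t, tau=self._tau_t, v=None)
        quad_theta = 0.5 * self._pi_theta * (theta - self.theta_prior_mean) ** 2
        return quad_z, quad_v, quad_w1, quad_w2, quad_theta

    def _flow_quad(self, x: np.ndarray, rho: np.ndarray, sigma: float, beta: float,
                   tau: float, v: np.ndarray | None) -> np.ndarray:
        """0.5 * sum_k Ww[k] |Dx - f|_k^2 for one Lorenz level (batched)."""
        B = x.shape[0]
        x0, y0, z0 = x[:, 0, 0], x[:, 1, 0], x[:, 2, 0]
        f = np.empty_like(x)
        f[:, 0, 0] = sigma * (y0 - x0)
        f[:, 1, 0] = x0 * (rho - z0) - y0
        f[:, 2, 0] = x0 * y0 - beta * z0
        J = np.zeros((B, N_STATES, N_STATES))
        J[:, 0, 0], J[:, 0, 1] = -sigma, sigma
        J[:, 1, 0], J[:, 1, 1], J[:, 1, 2] = rho - z0, -1.0, -x0
        J[:, 2, 0], J[:, 2, 1], J[:, 2, 2] = y0, x0, -beta
        f[:, :, 1:] = np.einsum("bij,bjk->bik", J, x[:, :, 1:])
        f /= tau
        if v is not None:
            for k in range(1, N_ORD_V):
                f[:, 1, k] += x0 * v[:, k] / tau
        eps = x[:, :, 1:] - f[:, :, :-1]  # flow errors at orders 0..n-1
        return 0.5 * np.einsum("bik,k->b", eps**2, self._Ww)

    def logdet_const(self, gain: float) -> float:
        """Precision log-determinant constant for a given sensory gain."""
        if gain <= 0:
            raise ValueError("sensory gain must be strictly positive")
        return (self._logdet_wv + self._logdet_z_unit
                - 0.5 * 2 * N_ORD_X * math.log(gain))

    def F_batch(self, mu: np.ndarray, s: np.ndarray, theta, gain: float = 1.0) -> np.ndarray:
        qz, qv, qw1, qw2, qth = self._quadratics(mu, s, theta, gain)
        return qz + qv + qw1 + qw2 + qth + self.logdet_const(gain)

    def report(self, mu: np.ndarray, s: np.ndarray, theta: float,
               gain: float = 1.0) -> FreeEnergyReport:
        """Full decomposition at one point (accuracy = sensory fit)."""
        qz, qv, qw1, qw2, qth = (float(q[0]) for q in
                                 self._quadratics(mu, s, theta, gain))
        logdet_z = self._logdet_z_unit - 0.5 * 2 * N_ORD_X * math.log(gain)
        accuracy = -(qz + logdet_z)
        complexity = qv + qw1 + qw2 + qth + self._logdet_wv
        return FreeEnergyReport(F=complexity - accuracy, energy=complexity - accuracy,
                                entropy=0.0, complexity=complexity, accuracy=accuracy,
                                quadratic_terms={"z1": qz, "z2": qv, "w1": qw1,
                                                 "w2": qw2, "theta": qth})

    # -- derivatives ------------------------------------------------------
    def grads(self, mu: np.ndarray, s: np.ndarray, theta: float, gain: float = 1.0,
              eps_mu: float = 1e-5, eps_theta: float = 1e-4
              ) -> tuple[float, np.ndarray, float, float]:
        """(F, dF/dmu, dF/dtheta, d2F/dtheta2) by central finite differences,
        evaluated in a single batched pass."""
        mu = np.asarray(mu, dtype=float)
        d = mu.shape[0]
        h = eps_mu * np.maximum(1.0, np.abs(mu))
        batch = np.tile(mu, (2 * d + 3, 1))
        idx = np.arange(d)
        batch[1 + 2 * idx, idx] += h
        batch[2 + 2 * idx, idx] -= h
        h_th = eps_theta * max(1.0, abs(theta))
        thetas = np.full(2 * d + 3, float(theta))
        thetas[-2] += h_th
        thetas[-1] -= h_th
        F = self.F_batch(batch, s, thetas, gain)
        g_mu = (F[1:1 + 2 * d:2] - F[2:2 + 2 * d:2]) / (2 * h)
        g_th = (F[-2] - F[-1]) / (2 * h_th)
        c_th = (F[-2] - 2 * F[0] + F[-1]) / h_th**2
        if not (np.all(np.isfinite(g_mu)) and np.isfinite(g_th)):
            bad = int(np.argmax(~np.isfinite(np.append(g_mu, g_th))))
            raise FloatingPointError(f"non-finite free-energy gradient at coordinate {bad}")
        return float(F[0]), g_mu, float(g_th), float(c_th)

    def fd_hessian(self, mu: np.ndarray, s: np.ndarray, theta: float,
                   gain: float = 1.0, eps: float = 1e-4) -> np.ndarray:
        """Curvature d2F/dmu2 by forward differences of the central-FD
        gradient, evaluated in one batched pass and symmetrized; used to
        build the local-linearization propagator of the gradient flow."""
        mu = np.asarray(mu, dtype=float)
        d = mu.size
        h = eps * np.maximum(1.0, np.abs(mu))
        pts = np.vstack([mu[None, :], mu[None, :] + np.diag(h)])  # (d+1, d)
        hh = eps * np.maximum(1.0, np.abs(pts))                   # grad steps per point
        P = np.repeat(pts, 2 * d, axis=0).reshape(d + 1, 2 * d, d)
        dim = np.arange(2 * d) // 2
        sgn = np.where(np.arange(2 * d) % 2 == 0, 1.0, -1.0)
        P[:, np.arange(2 * d), dim] += sgn * hh[:, dim]
        F = self.F_batch(P.reshape(-1, d), s, theta, gain).reshape(d + 1, 2 * d)
        g = (F[:, 0::2] - F[:, 1::2]) / (2 * hh)  # (d+1, d) gradients
        H = ((g[1:] - g[0]) / h[:, None]).T
        return 0.5 * (H + H.T)
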
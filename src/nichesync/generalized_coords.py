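"""Generalized coordinates of motion: values plus temporal derivatives.

A trajectory is represented locally by its value and derivatives up to an
embedding order n.  The shift (derivative) operator D maps each order onto
the next, so that at zero prediction error expectations simply follow their
own flow.  The integrator realizes gradient flows by local linearization
(matrix exponential of the numerical Jacobian), which remains stable on the
stiff flows that precision-weighted prediction errors produce.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.linalg import expm


@dataclass(frozen=True)
class GeneralizedState:
    """A block of d variables in generalized coordinates.

    ``values[i, k]`` is the k-th temporal derivative of variable i
    (order 0 is the value itself).  ``dt`` is the sampling step in
    seconds; it is carried so that embeddings and integrations agree on
    the time base.
    """

    values: np.ndarray  # (d, n+1)
    dt: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D (d, n+1), got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("GeneralizedState values must be finite")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        object.__setattr__(self, "values", values)

    @property
    def n_vars(self) -> int:
        return self.values.shape[0]

    @property
    def order(self) -> int:
        """Embedding order n (number of derivatives carried)."""
        return self.values.shape[1] - 1


def shift_matrix(n_orders: int) -> np.ndarray:
    """Nilpotent shift operator on order columns: (Dx)_k = x_{k+1}."""
    D = np.zeros((n_orders, n_orders))
    if n_orders > 1:
        D[np.arange(n_orders - 1), np.arange(1, n_orders)] = 1.0
    return D


def shift(state: GeneralizedState) -> GeneralizedState:
    """Apply the derivative operator: order k of the output is order k+1
    of the input; the top order is zero (nilpotency)."""
    out = np.zeros_like(state.values)
    out[:, :-1] = state.values[:, 1:]
    return GeneralizedState(out, state.dt)


def embed(samples: np.ndarray, order: int, dt: float,
          times: np.ndarray | None = None) -> GeneralizedState:
    """Embed the tail of a uniformly sampled series in generalized coordinates.

    Fits the unique degree-``order`` polynomial through the final
    ``order + 1`` samples and reads off value and derivatives at the last
    sample (equivalent to backward finite differences of increasing order).

    Parameters
    ----------
    samples : (m,) or (m, d) array, m >= order + 1
    order : embedding order n
    dt : sampling step, seconds
    times : optional sample times; if given they must be uniform with step dt.
    """
    samples = np.atleast_1d(np.asarray(samples, dtype=float))
    if samples.ndim == 1:
        samples = samples[:, None]
    m, d = samples.shape
    if order < 0:
        raise ValueError("embedding order must be >= 0")
    if m < order + 1:
        raise ValueError(f"need at least {order + 1} samples to embed at order {order}, got {m}")
    if not dt > 0:
        raise ValueError("dt must be positive")
    if times is not None:
        times = np.asarray(times, dtype=float)
        if times.shape[0] != m:
            raise ValueError("times must match samples in length")
        steps = np.diff(times)
        if steps.size and not np.allclose(steps, dt, rtol=1e-8, atol=1e-12):
            raise ValueError("samples must be uniformly spaced at dt")

    tail = samples[-(order + 1):]  # (order+1, d)
    # Local time axis centred on the final sample; interpolating polynomial
    # in t - t_last so its coefficients are the Taylor derivatives sought.
    t = dt * (np.arange(order + 1) - order)
    # Vandermonde solve: coeffs[k] = f^{(k)}(t_last) / k!
    V = np.vander(t, N=order + 1, increasing=True)
    coeffs = np.linalg.solve(V, tail)  # (order+1, d)
    factorials = np.cumprod(np.concatenate(([1.0], np.arange(1, order + 1))))
    values = (coeffs * factorials[:, None]).T  # (d, order+1)
    return GeneralizedState(values, dt)


def to_tick_units(state: GeneralizedState) -> GeneralizedState:
    """Re-express derivatives per sample step: order k is scaled by dt^k.

    In sample units one step is one time unit, which keeps all derivative
    orders at comparable magnitude — the numerically sane regime for
    generalized filtering of fast flows.
    """
    k = np.arange(state.values.shape[1])
    return GeneralizedState(state.values * state.dt**k, state.dt)


def to_time_units(state: GeneralizedState) -> GeneralizedState:
    """Inverse of `to_tick_units`: derivatives per second."""
    k = np.arange(state.values.shape[1])
    return GeneralizedState(state.values / state.dt**k, state.dt)


def integrate_flow(flow: Callable[[np.ndarray], np.ndarray],
                   state: GeneralizedState, dt: float, *,
                   fd_eps: float = 1e-6) -> GeneralizedState:
    """One local-linearization step of ``d(state)/dt = flow(state)``.

    The flow is treated as a function of the flattened value block.  Its
    Jacobian is estimated by central finite differences (perturbation
    ``fd_eps`` of each variable's scale); the update is
    ``x + J^{-1} (expm(J dt) - I) f(x)``, which is exact on linear flows.
    The step falls back to explicit Euler when the propagator cannot be
    formed (non-finite exponential).
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    x0 = state.values.ravel()
    f0 = _eval_flow(flow, state, x0)
    n = x0.size
    J = np.empty((n, n))
    for j in range(n):
        h = fd_eps * max(1.0, abs(x0[j]))
        xp, xm = x0.copy(), x0.copy()
        xp[j] += h
        xm[j] -= h
        fp = _eval_flow(flow, state, xp)
        fm = _eval_flow(flow, state, xm)
        J[:, j] = (fp - fm) / (2 * h)
    step = local_linear_step(J, f0, dt)
    return GeneralizedState((x0 + step).reshape(state.values.shape), state.dt)


def phi1_matrix(J: np.ndarray, dt: float) -> np.ndarray:
    """dt * phi1(J dt) = integral_0^dt expm(J s) ds, by augmented exponential.

    Equals J^{-1}(expm(J dt) - I) when J is invertible but needs no
    inverse, which matters here: the shift operator makes these Jacobians
    nilpotent-dominated and often numerically singular.
    """
    n = J.shape[0]
    aug = np.zeros((2 * n, 2 * n))
    aug[:n, :n] = J * dt
    aug[:n, n:] = np.eye(n) * dt
    return expm(aug)[:n, n:]


def local_linear_step(J: np.ndarray, f0: np.ndarray, dt: float) -> np.ndarray:
    """Increment integral_0^dt expm(J s) ds @ f0 (exact on linear flows);
    explicit Euler (dt * f0) when the propagator is not finite (the phi1
    form itself is well defined even for singular J)."""
    M = phi1_matrix(J, dt)
    if not np.all(np.isfinite(M)):
        return dt * f0
    return M @ f0


def _eval_flow(flow, template: GeneralizedState, x: np.ndarray) -> np.ndarray:
    arg = GeneralizedState(x.reshape(template.values.shape), template.dt)
    out = flow(arg)
    out = out.values if isinstance(out, GeneralizedState) else np.asarray(out, dtype=float)
    out = out.ravel()
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("flow returned non-finite values during integration step")
    return out
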
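"""Quantifying synchrony and organism-niche complementarity.

Identical synchrony is distance from the diagonal manifold (the two
agents' expectations literally agree); generalized synchrony is the
goodness of the best affine map from one agent's expectations (optionally
including their temporal derivatives) to the other's.  Complementarity is
the sum of the two agents' free-energy traces — free energies are
extensive, so the sum scores the attunement of the whole agent-niche
ensemble (lower = more complementary).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.signal import get_window, stft


@dataclass(frozen=True)
class SynchronyReport:
    """Summary of one duet: identical / generalized synchrony and the
    complementarity (joint free-energy) trace."""

    identical_deviation: float
    generalized_r2: float
    per_epoch_identical: np.ndarray
    per_epoch_r2: np.ndarray
    complementarity: np.ndarray          # (T,) nats per tick
    per_epoch_complementarity: np.ndarray
    final_fraction: float
    degenerate: bool = False
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.degenerate:
            if not -1e-12 <= self.generalized_r2 <= 1.0 + 1e-12:
                raise ValueError("generalized R^2 must lie in [0, 1]")
            if self.identical_deviation < 0:
                raise ValueError("identical-synchrony deviation must be >= 0")


@dataclass(frozen=True)
class Sonogram:
    """Spectral power over (frequency bins, time frames)."""

    power: np.ndarray      # (n_freqs, n_frames), non-negative
    freqs: np.ndarray      # Hz
    frame_times: np.ndarray  # s
    window_seconds: float
    hop_seconds: float

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("sonogram power must be non-negative")
        if self.power.shape != (self.freqs.size, self.frame_times.size):
            raise ValueError("sonogram shape inconsistent with axes")


def identical_sync_deviation(traj_A: np.ndarray, traj_B: np.ndarray) -> float:
    """Normalized RMS distance from the diagonal (identity) manifold.

    RMS of A - B over ticks and dimensions, divided by the pooled
    standard deviation of the concatenated trajectories.  Raises on a
    degenerate (zero-variance) pool.
    """
    A, B = np.atleast_2d(np.asarray(traj_A, float)), np.atleast_2d(np.asarray(traj_B, float))
    if A.shape != B.shape:
        raise ValueError("trajectories must share length and dimension")
    num = float(np.sqrt(np.mean((A - B) ** 2)))
    pool = np.concatenate([A, B], axis=0)
    den = float(np.sqrt(np.mean(np.var(pool, axis=0))))
    if den == 0.0:
        raise ValueError("degenerate trajectories: zero pooled variance")
    return num / den


def generalized_sync_score(traj_A: np.ndarray, traj_B: np.ndarray,
                           derivatives_A: np.ndarray | None = None,
                           ridge: float = 1e-8) -> float:
    """R^2 of the optimal affine map from A's expectations (plus their
    derivatives, when supplied) to B's, averaged over B's dimensions.

    Falls back to a small ridge penalty when the design is
    rank-deficient.
    """
    A = np.atleast_2d(np.asarray(traj_A, float))
    B = np.atleast_2d(np.asarray(traj_B, float))
    if A.shape[0] != B.shape[0]:
        raise ValueError("trajectories must share length")
    X = A if derivatives_A is None else np.hstack([A, np.atleast_2d(derivatives_A)])
    X = np.column_stack([X, np.ones(X.shape[0])])
    XtX = X.T @ X
    Xty = X.T @ B
    try:
        beta = np.linalg.solve(XtX, Xty)
        if not np.all(np.isfinite(beta)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        lam = ridge * np.trace(XtX) / XtX.shape[0]
        beta = np.linalg.solve(XtX + lam * np.eye(XtX.shape[0]), Xty)
    resid = B - X @ beta
    ss_res = np.sum(resid**2, axis=0)
    ss_tot = np.sum((B - B.mean(axis=0)) ** 2, axis=0)
    if np.any(ss_tot == 0):
        raise ValueError("degenerate target trajectory: zero variance")
    return float(np.clip(np.mean(1.0 - ss_res / ss_tot), 0.0, 1.0))


def complementarity(F_trace_A: np.ndarray, F_trace_B: np.ndarray,
                    epoch_slices: list[slice] | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Joint free energy: the pointwise sum of the two traces (nats).

    Lower values mean greater organism-niche complementarity.  Returns
    (trace, per-epoch means); the latter is empty when no epoch structure
    is given.
    """
    FA = np.asarray(F_trace_A, float)
    FB = np.asarray(F_trace_B, float)
    if FA.shape != FB.shape:
        raise ValueError("free-energy traces must be aligned")
    trace = FA + FB
    if epoch_slices is None:
        return trace, np.empty(0)
    return trace, np.array([float(np.mean(trace[sl])) for sl in epoch_slices])


def duet_synchrony_report(result, level: str = "top",
                          include_derivatives: bool = True,
                          final_fraction: float = 0.25) -> SynchronyReport:
    """Score a duet's SimulationResult.

    Synchrony is measured on the second-level ("area X") expectations by
    default; headline scores use the final ``final_fraction`` of ticks
    (burn-in discarded), per-epoch values cover the whole run.
    """
    A = result.level_trajectory("A", level=level, order=0)
    B = result.level_trajectory("B", level=level, order=0)
    dA = result.level_trajectory("A", level=level, order=1)
    T = A.shape[0]
    tail = slice(int(round(T * (1 - final_fraction))), T)
    ident = identical_sync_deviation(A[tail], B[tail])
    r2 = generalized_sync_score(A[tail], B[tail],
                                dA[tail] if include_derivatives else None)
    slices = result.epoch_slices()
    per_ident = np.array([identical_sync_deviation(A[sl], B[sl]) for sl in slices])
    per_r2 = np.array([generalized_sync_score(A[sl], B[sl],
                                              dA[sl] if include_derivatives else None)
                       for sl in slices])
    comp, per_comp = complementarity(result.f_trace("A"), result.f_trace("B"),
                                     slices)
    return SynchronyReport(identical_deviation=ident, generalized_r2=r2,
                           per_epoch_identical=per_ident, per_epoch_r2=per_r2,
                           complementarity=comp,
                           per_epoch_complementarity=per_comp,
                           final_fraction=final_fraction,
                           meta={"level": level, "mode": result.mode,
                                 "seed": result.seed,
                                 "include_derivatives": include_derivatives})


def synthesize_waveform(amplitude: np.ndarray, frequency: np.ndarray,
                        dt: float, sample_rate: int = 16000) -> np.ndarray:
    """Amplitude-modulated sinusoid at the instantaneous frequency."""
    amplitude = np.asarray(amplitude, float)
    frequency = np.asarray(frequency, float)
    if amplitude.shape != frequency.shape or amplitude.ndim != 1:
        raise ValueError("amplitude and frequency must be matching 1-D channels")
    t_in = np.arange(amplitude.size) * dt
    t_out = np.arange(0.0, t_in[-1] if t_in.size > 1 else 0.0, 1.0 / sample_rate)
    amp = np.interp(t_out, t_in, amplitude)
    freq = np.interp(t_out, t_in, frequency)
    phase = 2.0 * np.pi * np.cumsum(freq) / sample_rate
    return amp * np.sin(phase)


def sonogram(amplitude: np.ndarray, frequency: np.ndarray, dt: float,
             window_seconds: float = 0.064, hop_seconds: float = 0.016,
             sample_rate: int = 16000) -> Sonogram:
    """Short-time spectral power of the synthesized song.

    The (amplitude, frequency) channels are rendered as a waveform at
    ``sample_rate`` and analysed with a Hann window.
    """
    nperseg = int(round(window_seconds * sample_rate))
    hop = int(round(hop_seconds * sample_rate))
    if nperseg < 2:
        raise ValueError("window must cover at least 2 samples")
    if not 0 < hop <= nperseg:
        raise ValueError("hop must be positive and no longer than the window")
    wave = synthesize_waveform(amplitude, frequency, dt, sample_rate)
    freqs, frame_times, Z = stft(wave, fs=sample_rate,
                                 window=get_window("hann", nperseg),
                                 nperseg=nperseg, noverlap=nperseg - hop,
                                 boundary=None, padded=False)
    return Sonogram(power=np.abs(Z) ** 2, freqs=freqs, frame_times=frame_times,
                    window_seconds=window_seconds, hop_seconds=hop_seconds)
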
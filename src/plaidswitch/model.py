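"""Seeded Euler–Maruyama integration of the three-population competition model.

Dynamics, per population i in {C, T_R, T_L} (time in ms):

    tau_r * dr_i/dt = -r_i + S(-inhibition_i - a_i + I_i + n_i)
    tau_a * da_i/dt = -a_i + gamma * r_i
    dn_i/dt         = -n_i / tau_s + sigma * sqrt(2 / tau_s) * xi_i(t)

with S a logistic transducer, ``inhibition_i`` the mutual-inhibition term
(beta1 couples C with each transparent population, beta2 couples T_R with
T_L) and xi_i independent unit white noise.  The sqrt(2/tau_s) scaling makes
``sigma`` the stationary standard deviation of the noise process.

All integration is explicit Euler (Euler–Maruyama for the noise) with one
seeded generator per trial; identical (parameters, seed) pairs reproduce
trajectories bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import signal

from .params import InvalidParameterError, ModelParameters

__all__ = [
    "IntegrationError",
    "NetworkState",
    "NetworkTrajectory",
    "transducer",
    "ou_update",
    "ou_trace",
    "adaptation_trace",
    "step_network",
    "simulate_trial",
]


class IntegrationError(RuntimeError):
    """Raised when the integration produces a non-finite state."""


def transducer(x, theta: float = 0.2, k: float = 0.1, base: float = math.e):
    """Sigmoidal input-output transducer ``S(x) = 1 / (1 + base^(-(x-theta)/k))``.

    Strictly increasing for ``base > 1`` with ``S(theta) = 1/2`` and limits
    0 and 1 at -inf/+inf.  ``x`` may be a scalar or array.
    """
    if k <= 0:
        raise InvalidParameterError("transducer slope k must be positive")
    if base <= 0 or base == 1.0:
        raise InvalidParameterError("transducer base must be positive and != 1")
    z = math.log(base) * (np.asarray(x, dtype=float) - theta) / k
    out = 1.0 / (1.0 + np.exp(-z))
    return float(out) if np.isscalar(x) else out


def ou_update(n: float, dt: float, tau_s: float, sigma: float,
              increment: float) -> float:
    """One Euler–Maruyama step of the Ornstein-Uhlenbeck noise process.

    ``increment`` is a standard-normal draw.  With ``sigma = 0`` this is a
    pure exponential decay with time constant ``tau_s``.
    """
    if dt <= 0 or tau_s <= 0:
        raise InvalidParameterError("dt and tau_s must be positive")
    if sigma < 0:
        raise InvalidParameterError("sigma must be non-negative")
    return n - dt * n / tau_s + sigma * math.sqrt(2.0 * dt / tau_s) * increment


def ou_trace(tau_s: float, sigma: float, dt: float, duration_s: float,
             seed: int, n0: float = 0.0) -> np.ndarray:
    """Simulate a single OU noise trace; returns samples including t = 0.

    Uses the identical AR(1) recursion as :func:`ou_update`, evaluated with
    a linear filter so long traces (millions of steps) stay cheap.
    """
    n_steps = int(math.floor(duration_s * 1000.0 / dt))
    rng = np.random.default_rng(seed)
    xi = rng.standard_normal(n_steps)
    phi = 1.0 - dt / tau_s
    scale = sigma * math.sqrt(2.0 * dt / tau_s)
    # n_t = phi * n_{t-1} + scale * xi_t, n_0 given
    drive = scale * xi
    drive[0] += phi * n0
    trace = signal.lfilter([1.0], [1.0, -phi], drive)
    return np.concatenate(([n0], trace))


def adaptation_trace(r_clamped: float, gamma: float, tau_a: float, dt: float,
                     duration_s: float, a0: float = 0.0) -> np.ndarray:
    """Euler-integrate the adaptation ODE with the driving rate clamped.

    ``tau_a * da/dt = -a + gamma * r``; the fixed point is ``gamma * r``.
    Returns samples including t = 0.
    """
    n_steps = int(math.floor(duration_s * 1000.0 / dt))
    out = np.empty(n_steps + 1)
    out[0] = a0
    phi = 1.0 - dt / tau_a
    drive = dt * gamma * r_clamped / tau_a
    a = a0
    for i in range(n_steps):
        a = phi * a + drive
        out[i + 1] = a
    return out


@dataclass
class NetworkState:
    """Instantaneous state of the three populations at time ``t`` (ms)."""

    r_C: float = 0.0
    r_TR: float = 0.0
    r_TL: float = 0.0
    a_C: float = 0.0
    a_TR: float = 0.0
    a_TL: float = 0.0
    n_C: float = 0.0
    n_TR: float = 0.0
    n_TL: float = 0.0
    t: float = 0.0


@dataclass
class NetworkTrajectory:
    """Time-sampled rates, adaptation, and noise of one simulated trial.

    Arrays have shape (n_samples, 3) with population order (C, T_R, T_L);
    ``times_ms`` has shape (n_samples,) and starts at 0.
    """

    times_ms: np.ndarray
    rates: np.ndarray
    adaptation: np.ndarray
    noise: np.ndarray
    params: ModelParameters
    seed: int

    def to_frame(self):
        """Tidy table, one row per sample (column order fixed)."""
        import pandas as pd

        cols = {"time_ms": self.times_ms}
        for j, pop in enumerate(("C", "TR", "TL")):
            cols[f"r_{pop}"] = self.rates[:, j]
        for j, pop in enumerate(("C", "TR", "TL")):
            cols[f"a_{pop}"] = self.adaptation[:, j]
        for j, pop in enumerate(("C", "TR", "TL")):
            cols[f"n_{pop}"] = self.noise[:, j]
        return pd.DataFrame(cols)


@njit(cache=True)
def _step_kernel(state, xi, dt, tau_r, tau_a, tau_s, beta1, beta2, gamma,
                 sigma, theta, k, logb, I_C, I_TR, I_TL):  # pragma: no cover
    rC, rTR, rTL, aC, aTR, aTL, nC, nTR, nTL = state
    sC = 1.0 / (1.0 + np.exp(-logb * ((-beta1 * rTR - beta1 * rTL - aC
                                       + I_C + nC) - theta) / k))
    sTR = 1.0 / (1.0 + np.exp(-logb * ((-beta1 * rC - beta2 * rTL - aTR
                                        + I_TR + nTR) - theta) / k))
    sTL = 1.0 / (1.0 + np.exp(-logb * ((-beta1 * rC - beta2 * rTR - aTL
                                        + I_TL + nTL) - theta) / k))
    amp = sigma * np.sqrt(2.0 * dt / tau_s)
    return (
        rC + dt * (-rC + sC) / tau_r,
        rTR + dt * (-rTR + sTR) / tau_r,
        rTL + dt * (-rTL + sTL) / tau_r,
        aC + dt * (-aC + gamma * rC) / tau_a,
        aTR + dt * (-aTR + gamma * rTR) / tau_a,
        aTL + dt * (-aTL + gamma * rTL) / tau_a,
        nC - dt * nC / tau_s + amp * xi[0],
        nTR - dt * nTR / tau_s + amp * xi[1],
        nTL - dt * nTL / tau_s + amp * xi[2],
    )


@njit(cache=True)
def _integrate_kernel(increments, dt, tau_r, tau_a, tau_s, beta1, beta2,
                      gamma, sigma, theta, k, logb, I_C, I_TR, I_TL,
                      state0, rates, adapt, noise):  # pragma: no cover
    state = state0
    rates[0, 0], rates[0, 1], rates[0, 2] = state[0], state[1], state[2]
    adapt[0, 0], adapt[0, 1], adapt[0, 2] = state[3], state[4], state[5]
    noise[0, 0], noise[0, 1], noise[0, 2] = state[6], state[7], state[8]
    for i in range(increments.shape[0]):
        state = _step_kernel(state, increments[i], dt, tau_r, tau_a, tau_s,
                             beta1, beta2, gamma, sigma, theta, k, logb,
                             I_C, I_TR, I_TL)
        ok = True
        for v in state:
            if not np.isfinite(v):
                ok = False
        if not ok:
            return i + 1
        rates[i + 1, 0], rates[i + 1, 1], rates[i + 1, 2] = (
            state[0], state[1], state[2])
        adapt[i + 1, 0], adapt[i + 1, 1], adapt[i + 1, 2] = (
            state[3], state[4], state[5])
        noise[i + 1, 0], noise[i + 1, 1], noise[i + 1, 2] = (
            state[6], state[7], state[8])
    return -1


def _param_tuple(p: ModelParameters):
    return (p.dt, p.tau_r, p.tau_a, p.tau_s, p.beta1, p.beta2, p.gamma,
            p.sigma, p.theta, p.k, math.log(p.transducer_base),
            p.I_C, p.I_TR, p.I_TL)


def step_network(state: NetworkState, params: ModelParameters,
                 increments) -> NetworkState:
    """Advance the full network by one Euler step.

    ``increments`` are the three standard-normal noise draws, in population
    order (C, T_R, T_L).  All derivatives are evaluated on the old state.
    """
    xi = np.asarray(increments, dtype=float)
    if xi.shape != (3,):
        raise ValueError("exactly three noise increments required")
    vec = (state.r_C, state.r_TR, state.r_TL, state.a_C, state.a_TR,
           state.a_TL, state.n_C, state.n_TR, state.n_TL)
    new = _step_kernel(vec, xi, *_param_tuple(params))
    if not all(math.isfinite(v) for v in new):
        raise IntegrationError(
            f"non-finite state after step at t = {state.t} ms")
    return NetworkState(*new, t=state.t + params.dt)


def simulate_trial(params: ModelParameters, seed: int,
                   initial_state: NetworkState | None = None) -> NetworkTrajectory:
    """Simulate one trial; deterministic given (params, seed).

    Noise increments are drawn from one seeded generator as an
    (n_steps, 3) block, populations in fixed order (C, T_R, T_L).  Rates,
    adaptation, and noise all start at zero unless ``initial_state`` is
    given.
    """
    n_steps = params.n_steps
    rng = np.random.default_rng(seed)
    increments = rng.standard_normal((n_steps, 3))
    s0 = initial_state or NetworkState()
    state0 = (s0.r_C, s0.r_TR, s0.r_TL, s0.a_C, s0.a_TR, s0.a_TL,
              s0.n_C, s0.n_TR, s0.n_TL)
    rates = np.empty((n_steps + 1, 3))
    adapt = np.empty((n_steps + 1, 3))
    noise = np.empty((n_steps + 1, 3))
    fail = _integrate_kernel(increments, *_param_tuple(params),
                             state0, rates, adapt, noise)
    if fail >= 0:
        raise IntegrationError(
            f"non-finite state at integration step {fail} "
            f"(t = {fail * params.dt} ms, seed = {seed})")
    times = np.arange(n_steps + 1, dtype=float) * params.dt
    return NetworkTrajectory(times_ms=times, rates=rates, adaptation=adapt,
                             noise=noise, params=params, seed=seed)
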
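"""Leaky-integrator unit dynamics and synchronous Euler integration.

Every neural population in the circuit is a leaky integrator: the
activation potential ``u`` relaxes toward its instantaneous input ``I``
with time constant ``tau``,

    tau * du/dt = -u + I,

and the emitted activity is a rectified, threshold-shifted saturation of
the potential,

    a = f(u) = max(0, 400 * tanh(u / 400) - thr),

so activities live on a 0-400 firing-rate scale and the slope of ``f``
is 1 near the origin (potentials, resting levels, noise and external
drives are all expressed on the same scale).  The input of a unit is the
sum of its resting potential, the weighted activities of its presynaptic
units and a per-step Gaussian noise sample:

    I = r + sum_i w_i * a_i + n.

Networks are advanced synchronously: every unit's potential is updated
from the activities of the *previous* step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ACTIVITY_CEILING",
    "UnitParams",
    "NoiseSpec",
    "NetworkState",
    "LeakyNetwork",
    "activate",
    "unit_input",
    "euler_step",
    "step_network",
]

#: Saturation level of the activation function (firing-rate units).
ACTIVITY_CEILING = 400.0


def activate(u, thr=0.0):
    """Activation function ``f(u) = [400*tanh(u/400) - thr]+``.

    Parameters
    ----------
    u : array_like
        Activation potential(s).
    thr : array_like
        Activation threshold(s), on the activity (0-400) scale. Must be
        non-negative.

    Returns
    -------
    ndarray or float
        Activity in ``[0, 400]``.
    """
    if np.any(np.asarray(thr) < 0):
        raise ValueError("activation threshold must be non-negative")
    return np.maximum(
        0.0, ACTIVITY_CEILING * np.tanh(np.asarray(u, dtype=float) / ACTIVITY_CEILING) - thr
    )


def unit_input(r, presyn_activities, weights, n=0.0):
    """Total drive of a unit: ``r + sum_i w_i * a_i + n``."""
    a = np.asarray(presyn_activities, dtype=float)
    w = np.asarray(weights, dtype=float)
    if a.shape != w.shape:
        raise ValueError(
            f"presynaptic activities and weights must have equal length, "
            f"got {a.shape} and {w.shape}"
        )
    return float(r) + float(np.dot(w, a)) + float(n)


def euler_step(u, I, tau, dt):
    """One forward-Euler step of ``tau * du/dt = -u + I``.

    Raises
    ------
    ValueError
        If ``dt <= 0`` or ``dt >= tau`` (explicit Euler is unstable for
        the leaky integrator once the step exceeds the time constant).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if np.any(dt >= np.asarray(tau)):
        raise ValueError(f"integration step dt={dt} must be smaller than tau={tau}")
    return u + (dt / np.asarray(tau, dtype=float)) * (-u + np.asarray(I, dtype=float))


@dataclass(frozen=True)
class UnitParams:
    """Constants of one leaky-integrator unit.

    tau : time constant (seconds), > 0
    r   : resting potential (activation-potential units)
    thr : activation threshold (activity units, 0-400 scale), >= 0
    """

    tau: float
    r: float = 0.0
    thr: float = 0.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.thr < 0:
            raise ValueError("thr must be non-negative")

    def check_dt(self, dt: float) -> None:
        if dt >= self.tau:
            raise ValueError(
                f"integration unstable: dt={dt} >= tau={self.tau}"
            )


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise added to a unit's input, sampled per unit per step."""

    mean: float = 0.0
    sd: float = 0.0

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("noise sd must be non-negative")

    def sample(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.sd == 0.0 and self.mean == 0.0:
            return np.zeros(size)
        return rng.normal(self.mean, self.sd, size)


@dataclass
class NetworkState:
    """Potentials and activities of every unit at one time step."""

    u: np.ndarray
    a: np.ndarray
    t: float = 0.0

    def copy(self) -> "NetworkState":
        return NetworkState(self.u.copy(), self.a.copy(), self.t)


class LeakyNetwork:
    """A generic weighted network of leaky-integrator units.

    Parameters
    ----------
    weights : (n, n) ndarray
        Signed connection matrix; ``weights[j, i]`` is the weight from
        unit ``i`` to unit ``j`` (inhibitory connections are negative).
    tau, r, thr : (n,) ndarrays
        Per-unit time constants, resting potentials and thresholds.
    noise_mean, noise_sd : (n,) ndarrays
        Per-unit Gaussian noise parameters; noise is drawn independently
        for each unit at each integration step.
    """

    def __init__(self, weights, tau, r, thr, noise_mean=None, noise_sd=None):
        W = np.asarray(weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be a square matrix")
        n = W.shape[0]
        self.W = W
        self.tau = self._vec(tau, n, "tau")
        self.r = self._vec(r, n, "r")
        self.thr = self._vec(thr, n, "thr")
        self.noise_mean = (
            np.zeros(n) if noise_mean is None else self._vec(noise_mean, n, "noise_mean")
        )
        self.noise_sd = (
            np.zeros(n) if noise_sd is None else self._vec(noise_sd, n, "noise_sd")
        )
        if np.any(self.tau <= 0):
            raise ValueError("all tau must be positive")
        if np.any(self.thr < 0):
            raise ValueError("all thr must be non-negative")
        if np.any(self.noise_sd < 0):
            raise ValueError("all noise sd must be non-negative")
        self.n = n

    @staticmethod
    def _vec(x, n, name):
        v = np.broadcast_to(np.asarray(x, dtype=float), (n,)).copy()
        return v

    def initial_state(self) -> NetworkState:
        u = np.zeros(self.n)
        return NetworkState(u=u, a=activate(u, self.thr), t=0.0)

    def step(self, state, rng, dt, external=None, step_index=None):
        """Advance the whole network one synchronous Euler step."""
        return step_network(state, self, external, rng, dt, step_index=step_index)

    def run(self, n_steps, dt, rng, external=None, state=None):
        """Integrate ``n_steps`` steps; returns (final state, activity trace).

        ``external`` may be None, a (n,) vector, or a (n_steps, n) array of
        per-step external drives.  The returned trace has shape
        ``(n_steps, n)`` and holds the activity after each step.
        """
        if np.any(dt >= self.tau):
            raise ValueError("dt must be smaller than every tau")
        if state is None:
            state = self.initial_state()
        trace = np.empty((n_steps, self.n))
        ext_t = None
        for k in range(n_steps):
            if external is not None:
                ext = np.asarray(external, dtype=float)
                ext_t = ext[k] if ext.ndim == 2 else ext
            state = step_network(state, self, ext_t, rng, dt, step_index=k)
            trace[k] = state.a
        return state, trace


def step_network(state, network, external, rng, dt, step_index=None):
    """One synchronous update of every unit from previous-step activities."""
    net = network
    if external is None:
        external = 0.0
    else:
        external = np.asarray(external, dtype=float)
        if external.shape != (net.n,):
            raise ValueError(
                f"external drive must have one entry per unit "
                f"({net.n}), got shape {external.shape}"
            )
    noise = (
        rng.normal(net.noise_mean, net.noise_sd)
        if np.any(net.noise_sd > 0) or np.any(net.noise_mean != 0)
        else 0.0
    )
    I = net.r + net.W @ state.a + noise + external
    u = state.u + (dt / net.tau) * (-state.u + I)
    if not np.all(np.isfinite(u)):
        where = "" if step_index is None else f" at step {step_index}"
        raise FloatingPointError(f"non-finite activation potential{where}")
    return NetworkState(u=u, a=activate(u, net.thr), t=state.t + dt)
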
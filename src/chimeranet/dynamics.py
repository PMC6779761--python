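"""Coupled FitzHugh-Nagumo dynamics on a two-layer network.

Every node carries an FHN oscillator (fast variable u, slow variable v,
timescale separation epsilon).  Nodes are diffusively coupled through a
rotational coupling matrix

    D(alpha) = [[cos a, sin a], [-sin a, cos a]],

which mixes u- and v-differences by the coupling phase alpha; near
alpha = pi/2 this cross-coupling is known to promote chimera states.
Intra-layer input is averaged over a node's intra-layer neighbors and
scaled by lambda_in; inter-layer input over its inter-layer neighbors,
scaled by lambda_out.  A node with no neighbors of a given kind simply
receives no input of that kind.

Integration is fixed-step classical Runge-Kutta (RK4), fully deterministic
given the initial state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network_model import LayeredNetwork

#: default uniform range for random initial conditions; brackets the FHN
#: limit cycle, whose u-amplitude is about 2.
IC_RANGE = (-2.0, 2.0)

#: integration aborts when |u| exceeds this bound (fail fast on divergence)
OVERFLOW_GUARD = 1e3


class InstabilityError(FloatingPointError):
    """The integration diverged; ``step`` is the offending RK4 step."""

    def __init__(self, message: str, step: int):
        super().__init__(message)
        self.step = step


def _normalize_angle(alpha: float) -> float:
    """Map an angle to the interval (-pi, pi]."""
    a = math.remainder(alpha, 2.0 * math.pi)  # (-pi, pi], -pi possible
    if a <= -math.pi:
        a = math.pi
    return a


@dataclass(frozen=True)
class FHNParameters:
    """Scalar parameters of the coupled FHN system.

    epsilon : timescale separation of the fast variable (default 0.05)
    a : excitability; an isolated node oscillates iff |a| < 1 (default 0.5)
    alpha : coupling phase in radians, normalized to (-pi, pi]
    lambda_in / lambda_out : intra- and inter-layer coupling strengths
    """

    epsilon: float = 0.05
    a: float = 0.5
    alpha: float = 0.0
    lambda_in: float = 0.0
    lambda_out: float = 0.0

    def __post_init__(self):
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if self.lambda_in < 0 or self.lambda_out < 0:
            raise ValueError("coupling strengths must be non-negative")
        if not math.isfinite(self.alpha):
            raise ValueError("alpha must be finite")
        object.__setattr__(self, "alpha", _normalize_angle(self.alpha))

    @property
    def d(self) -> np.ndarray:
        """The 2x2 rotational coupling matrix D(alpha)."""
        return coupling_matrix(self.alpha)


def coupling_matrix(alpha: float) -> np.ndarray:
    """Rotational coupling matrix ``[[cos a, sin a], [-sin a, cos a]]``.

    Orthogonal with determinant 1 for every alpha.
    """
    c, s = math.cos(alpha), math.sin(alpha)
    return np.array([[c, s], [-s, c]])


@dataclass
class SystemState:
    """Instantaneous state of all nodes (layer A first, then layer B)."""

    u: np.ndarray
    v: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape or self.u.ndim != 1:
            raise ValueError("u and v must be 1-d arrays of equal length")
        if not (np.isfinite(self.u).all() and np.isfinite(self.v).all()):
            raise ValueError("state must be finite")


@dataclass
class Trajectory:
    """Uniformly sampled states of all nodes over an integration run."""

    times: np.ndarray
    u: np.ndarray  # shape (n_samples, n_nodes)
    v: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.u.shape != self.v.shape or self.u.shape[0] != self.times.size:
            raise ValueError("u/v shapes inconsistent with times")

    @property
    def final_state(self) -> SystemState:
        return SystemState(self.u[-1].copy(), self.v[-1].copy(), float(self.times[-1]))

    def to_frame(self):
        """Long-format (time, node, u, v) table."""
        import pandas as pd

        n = self.u.shape[1]
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, n),
                "node": np.tile(np.arange(n), self.times.size),
                "u": self.u.ravel(),
                "v": self.v.ravel(),
            }
        )


def _coupling_operator(net: LayeredNetwork, params: FHNParameters):
    """Precompute the combined neighbor-averaging operator.

    Because the same D(alpha) multiplies intra- and inter-layer differences,
    the two normalized adjacencies can be folded into a single weighted
    matrix W = lambda_in * W_in + lambda_out * W_out (rows normalized by
    intra/inter degree, zero where the degree is zero) together with the
    per-node total weight m.  The coupling input is then W @ [u, v] - m * [u, v].
    """
    n_a, n_b = net.n_a, net.n_b
    n = n_a + n_b
    k_in = net.k_in.astype(float)
    k_out = net.k_out.astype(float)

    w_in = np.zeros((n, n))
    w_in[:n_a, :n_a] = net.adj_a
    w_in[n_a:, n_a:] = net.adj_b
    w_out = np.zeros((n, n))
    w_out[:n_a, n_a:] = net.adj_ab
    w_out[n_a:, :n_a] = net.adj_ab.T

    inv_in = np.where(k_in > 0, 1.0 / np.maximum(k_in, 1), 0.0)
    inv_out = np.where(k_out > 0, 1.0 / np.maximum(k_out, 1), 0.0)
    w = (
        params.lambda_in * inv_in[:, None] * w_in
        + params.lambda_out * inv_out[:, None] * w_out
    )
    m = params.lambda_in * (k_in > 0) + params.lambda_out * (k_out > 0)
    return w, m


def _rhs_factory(net: LayeredNetwork, params: FHNParameters):
    w, m = _coupling_operator(net, params)
    # the diagonal of w is zero (no self-loops), so the -m * (u_i, v_i)
    # self-term folds into the matrix: one GEMM per evaluation
    wd = w - np.diag(m)
    dt_mat = coupling_matrix(params.alpha).T.copy()
    eps, a = params.epsilon, params.a

    def rhs(y: np.ndarray) -> np.ndarray:
        # y has shape (n, 2): columns u, v
        c = (wd @ y) @ dt_mat  # columns: D-mixed coupling input to u and v
        u = y[:, 0]
        out = np.empty_like(y)
        out[:, 0] = (u - u**3 / 3.0 - y[:, 1] + c[:, 0]) / eps
        out[:, 1] = u + a + c[:, 1]
        return out

    return rhs


def derivatives(
    state: SystemState, params: FHNParameters, net: LayeredNetwork
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives (du/dt, dv/dt) of the full coupled system."""
    if state.u.size != net.n_total:
        raise ValueError(
            f"state has {state.u.size} nodes but network has {net.n_total}"
        )
    out = _rhs_factory(net, params)(np.column_stack((state.u, state.v)))
    return out[:, 0], out[:, 1]


def integrate(
    initial: SystemState,
    params: FHNParameters,
    net: LayeredNetwork,
    t_end: float,
    dt: float = 0.01,
    sample_stride: int = 50,
    seed=None,
) -> Trajectory:
    """Advance the coupled system with fixed-step RK4.

    Snapshots (including the initial state and the final step) are stored
    every ``sample_stride`` steps.  The run is deterministic; ``seed`` is
    accepted for interface symmetry but unused.  Raises
    :class:`InstabilityError` if any |u| exceeds the overflow guard.
    """
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    if sample_stride < 1:
        raise ValueError("sample_stride must be >= 1")
    rhs = _rhs_factory(net, params)
    n_steps = int(round(t_end / dt))
    y = np.column_stack((initial.u, initial.v)).astype(float)
    t0 = initial.t

    sampled_steps = list(range(0, n_steps + 1, sample_stride))
    if sampled_steps[-1] != n_steps:
        sampled_steps.append(n_steps)
    n_samp = len(sampled_steps)
    us = np.empty((n_samp, y.shape[0]))
    vs = np.empty((n_samp, y.shape[0]))
    times = t0 + dt * np.asarray(sampled_steps, dtype=float)

    us[0] = y[:, 0]
    vs[0] = y[:, 1]
    cursor = 1
    next_sample = sampled_steps[1] if n_samp > 1 else None
    half = dt / 2.0
    sixth = dt / 6.0
    for step in range(1, n_steps + 1):
        k1 = rhs(y)
        k2 = rhs(y + half * k1)
        k3 = rhs(y + half * k2)
        k4 = rhs(y + dt * k3)
        y = y + sixth * (k1 + 2.0 * (k2 + k3) + k4)
        umax = np.abs(y[:, 0]).max()
        if not umax < OVERFLOW_GUARD:
            raise InstabilityError(
                f"|u| reached {umax:.3g} at step {step} (t = {t0 + step * dt:.4g})",
                step=step,
            )
        if step == next_sample:
            us[cursor] = y[:, 0]
            vs[cursor] = y[:, 1]
            cursor += 1
            next_sample = sampled_steps[cursor] if cursor < n_samp else None
    return Trajectory(times, us, vs)


def random_initial_conditions(
    net: LayeredNetwork, seed=None, low: float = IC_RANGE[0], high: float = IC_RANGE[1]
) -> SystemState:
    """Seeded i.i.d. uniform initial conditions for u and v on [low, high]."""
    rng = np.random.default_rng(seed)
    n = net.n_total
    return SystemState(rng.uniform(low, high, n), rng.uniform(low, high, n))
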
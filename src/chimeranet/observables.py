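"""Diagnostics of collective states: firing counts, mean phase velocity,
velocity-sorted ordering, spatial coherence (g0, g1) and classification.

The mean phase velocity of node i over a post-transient window of length
DT is omega_i = 2*pi*M_i / DT, where M_i counts spikes (upward threshold
crossings of u).  Since a complex network has no spatial embedding, nodes
of each layer are re-indexed by ascending omega before any "spatial"
measure is taken; a chimera state then shows up as an omega plateau (the
frequency-locked subpopulation) next to a spread of drifting frequencies.

Spatial coherence g0 of one snapshot is the fraction of interior nodes
(along the omega-sorted index) whose discrete curvature of u is small
relative to the snapshot's value range; its time average g1 discriminates
synchronization (g1 = 1), disorder (g1 ~ 0) and partial synchronization
(0 < g1 < 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: relative curvature tolerance used for the binarized coherence measure
DELTA_REL_DEFAULT = 0.01

#: classification thresholds on g1 (symmetric about the limiting values)
SYNC_THRESHOLD = 0.95
DISORDER_THRESHOLD = 0.05

#: minimum mean firing count for a statistically meaningful omega profile
MIN_MEAN_FIRINGS = 50


class WindowError(ValueError):
    """Measurement window too short for the requested diagnostic."""


def count_firings(u_trace: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Per-node spike counts from a uniformly sampled u time series.

    A firing is an upward crossing: previous sample < threshold and current
    sample >= threshold.  ``u_trace`` has shape (n_samples, n_nodes).
    """
    u = np.atleast_2d(np.asarray(u_trace, dtype=float))
    if u.shape[0] < 2:
        raise WindowError("need at least 2 samples to count crossings")
    rising = (u[:-1] < threshold) & (u[1:] >= threshold)
    return rising.sum(axis=0).astype(np.int64)


def mean_phase_velocity(m: np.ndarray, delta_t: float) -> np.ndarray:
    """omega_i = 2*pi*M_i / delta_t, elementwise."""
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    return 2.0 * np.pi * np.asarray(m, dtype=float) / delta_t


@dataclass
class VelocityProfile:
    """Firing counts and mean phase velocities, with the per-layer sorted order.

    ``order`` is a permutation of absolute node indices: the first ``n_a``
    entries sort layer A by ascending omega, the rest sort layer B.  Ties
    keep the original index order (stable sort).
    """

    m: np.ndarray
    delta_t: float
    n_a: int
    omega: np.ndarray = None
    order: np.ndarray = None

    def __post_init__(self):
        self.m = np.asarray(self.m)
        if self.omega is None:
            self.omega = mean_phase_velocity(self.m, self.delta_t)
        if self.order is None:
            self.order = reorder_by_velocity(self)

    @property
    def omega_a_sorted(self) -> np.ndarray:
        return self.omega[self.order[: self.n_a]]

    @property
    def omega_b_sorted(self) -> np.ndarray:
        return self.omega[self.order[self.n_a :]]


def reorder_by_velocity(profile: VelocityProfile) -> np.ndarray:
    """Stable ascending-omega permutation, each layer sorted independently."""
    n_a = profile.n_a
    omega = np.asarray(profile.omega)
    order_a = np.argsort(omega[:n_a], kind="stable")
    order_b = np.argsort(omega[n_a:], kind="stable") + n_a
    return np.concatenate([order_a, order_b])


def spatial_coherence_g0(
    snapshot: np.ndarray,
    delta_rel: float = DELTA_REL_DEFAULT,
    scale: float | None = None,
) -> float:
    """Binarized spatial coherence of one (omega-sorted) layer snapshot.

    Computes the discrete curvature d_i = u_{i+1} - 2 u_i + u_{i-1} over the
    sorted index (endpoints excluded, free boundaries) and returns the
    fraction of interior nodes with |d_i| below ``delta_rel`` times the
    maximal possible curvature D_max = 4 * scale.  ``scale`` is the value
    range defining that reference curvature; it defaults to the snapshot's
    own span (max u - min u).  When scoring a whole run, pass the run-level
    u range instead (see :func:`coherence_from_samples`), so that a state
    whose spatial spread has collapsed far below the oscillation amplitude
    scores as coherent rather than having its numerical residue re-amplified.
    A snapshot constant to within the scale-zero limit has g0 = 1.
    """
    u = np.asarray(snapshot, dtype=float)
    if u.ndim != 1 or u.size < 3:
        raise ValueError("snapshot must be 1-d with at least 3 nodes")
    if scale is None:
        scale = u.max() - u.min()
    if scale == 0.0:
        return 1.0
    d = u[2:] - 2.0 * u[1:-1] + u[:-2]
    return float(np.mean(np.abs(d) < delta_rel * 4.0 * scale))


def _g0_series(
    u_sorted: np.ndarray, delta_rel: float, scale: float | None = None
) -> np.ndarray:
    """Vectorized g0 over snapshots; rows of shape (n_samples, n_layer).

    ``scale`` defaults to the u range over the whole window, the reference
    amplitude against which curvature is judged for every snapshot.
    """
    if scale is None:
        scale = float(u_sorted.max() - u_sorted.min())
    if scale == 0.0:
        return np.ones(u_sorted.shape[0])
    d = u_sorted[:, 2:] - 2.0 * u_sorted[:, 1:-1] + u_sorted[:, :-2]
    return np.mean(np.abs(d) < delta_rel * 4.0 * scale, axis=1)


def time_averaged_g1(g0_series: np.ndarray) -> float:
    """Arithmetic mean of the instantaneous coherence over the window."""
    g0 = np.asarray(g0_series, dtype=float)
    if g0.size == 0:
        raise ValueError("empty g0 series")
    return float(g0.mean())


def classify_state(
    g1: float,
    sync_threshold: float = SYNC_THRESHOLD,
    disorder_threshold: float = DISORDER_THRESHOLD,
) -> str:
    """Map g1 to {synchronized, partial, disordered}.

    The limiting values are g1 = 1 (full synchronization) and g1 ~ 0
    (incoherence); anything in between is partial synchronization, a term
    that deliberately does not distinguish chimera states from cluster
    synchronization.
    """
    if not 0.0 <= g1 <= 1.0:
        raise ValueError(f"g1 must lie in [0, 1], got {g1}")
    if g1 > sync_threshold:
        return "synchronized"
    if g1 < disorder_threshold:
        return "disordered"
    return "partial"


@dataclass
class CoherenceResult:
    """Per-layer coherence series, time averages and classifications."""

    g0_a: np.ndarray
    g0_b: np.ndarray
    g1_a: float
    g1_b: float
    label_a: str
    label_b: str


def coherence_from_samples(
    u_samples: np.ndarray,
    order: np.ndarray,
    n_a: int,
    delta_rel: float = DELTA_REL_DEFAULT,
    sync_threshold: float = SYNC_THRESHOLD,
    disorder_threshold: float = DISORDER_THRESHOLD,
) -> CoherenceResult:
    """Coherence diagnostics from post-transient u snapshots.

    ``order`` is the frozen omega-sorted permutation from a
    :class:`VelocityProfile` computed on the same run; it is applied to
    every snapshot before taking curvature.  The curvature threshold is
    relative to each layer's u range over the whole window (the attractor
    amplitude), so that fully synchronized runs score g0 = 1 even when a
    numerically tiny spread remains.
    """
    u = np.asarray(u_samples, dtype=float)
    g0_a = _g0_series(u[:, order[:n_a]], delta_rel)
    g0_b = _g0_series(u[:, order[n_a:]], delta_rel)
    g1_a = time_averaged_g1(g0_a)
    g1_b = time_averaged_g1(g0_b)
    return CoherenceResult(
        g0_a,
        g0_b,
        g1_a,
        g1_b,
        classify_state(g1_a, sync_threshold, disorder_threshold),
        classify_state(g1_b, sync_threshold, disorder_threshold),
    )


def velocity_profile(
    u_samples: np.ndarray,
    delta_t: float,
    n_a: int,
    threshold: float = 0.0,
    warn_low_counts: bool = True,
) -> VelocityProfile:
    """Build a :class:`VelocityProfile` from post-transient u snapshots."""
    m = count_firings(u_samples, threshold)
    if warn_low_counts and m.mean() < MIN_MEAN_FIRINGS:
        warnings.warn(
            f"mean firing count {m.mean():.1f} < {MIN_MEAN_FIRINGS}; "
            "omega profile may be noisy — extend the measurement window",
            stacklevel=2,
        )
    return VelocityProfile(m=m, delta_t=delta_t, n_a=n_a)


def omega_plateau_fraction(omega_sorted: np.ndarray, atol: float = 1e-3) -> float:
    """Fraction of a layer's nodes within ``atol`` of the minimum omega.

    In a chimera state the frequency-locked subpopulation forms a plateau
    at the low end of the sorted omega profile; a large plateau together
    with a spread of higher frequencies is the profile signature of
    coexisting coherence and incoherence.
    """
    omega = np.asarray(omega_sorted, dtype=float)
    return float(np.mean(omega <= omega.min() + atol))
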
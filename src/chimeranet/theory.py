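"""Analytic borderline of synchronization in the (alpha, lambda_out) plane.

At the border between synchronized and unsynchronized regions the state
differences du = u_j - u_i and dv = v_j - v_i are approximated as non-zero
constants.  The total coupling then reduces to

    y = (lambda_in + lambda_out) * [cos(alpha) * du + sin(alpha) * dv],

and a borderline is a level set of y.  Solving for the inter-layer coupling,

    lambda_out(alpha) = y / (cos(alpha) * du + sin(alpha) * dv) - lambda_in,

which is an arc-shaped convex curve over alpha in (-pi/2, pi/2) with its
minimum at alpha* = arctan(dv/du), and decreases linearly in lambda_in with
slope -1.  Larger y shifts the whole arc upward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


class SingularityError(ZeroDivisionError):
    """The direction term cos(alpha)*du + sin(alpha)*dv vanishes."""


def coupling_total_y(
    lambda_in: float,
    lambda_out: float,
    alpha: float,
    delta_u: float,
    delta_v: float,
) -> float:
    """Total coupling constant y on the borderline ansatz."""
    return (lambda_in + lambda_out) * (
        math.cos(alpha) * delta_u + math.sin(alpha) * delta_v
    )


def borderline_lambda_out(
    alpha,
    y: float,
    delta_u: float,
    delta_v: float,
    lambda_in: float,
    singular_tol: float = 1e-12,
):
    """Inter-layer coupling on the borderline, lambda_out(alpha).

    Accepts a scalar or an array of alpha values.  Raises
    :class:`SingularityError` where the direction term vanishes (within
    ``singular_tol``); singularities are reported, never clipped.
    """
    alpha_arr = np.asarray(alpha, dtype=float)
    denom = np.cos(alpha_arr) * delta_u + np.sin(alpha_arr) * delta_v
    if np.any(np.abs(denom) <= singular_tol):
        bad = np.atleast_1d(alpha_arr)[np.atleast_1d(np.abs(denom)) <= singular_tol]
        raise SingularityError(
            f"cos(a)*du + sin(a)*dv vanishes at alpha = {bad[:3]}"
        )
    out = y / denom - lambda_in
    return float(out) if np.isscalar(alpha) or alpha_arr.ndim == 0 else out


def borderline_minimum(
    y: float, delta_u: float, delta_v: float, lambda_in: float
) -> tuple[float, float]:
    """Location and value of the arc minimum.

    The minimum of lambda_out(alpha) sits at alpha* = arctan(dv/du) where
    the direction term reaches its maximum sqrt(du^2 + dv^2).
    """
    alpha_star = math.atan2(delta_v, delta_u)
    lam_star = y / math.hypot(delta_u, delta_v) - lambda_in
    return alpha_star, lam_star


@dataclass
class BorderlineCurve:
    """One borderline: lambda_out over an alpha grid at fixed (y, du, dv, lambda_in)."""

    y: float
    delta_u: float
    delta_v: float
    lambda_in: float
    alphas: np.ndarray
    lambda_out_values: np.ndarray = field(default=None)

    def __post_init__(self):
        self.alphas = np.asarray(self.alphas, dtype=float)
        if self.lambda_out_values is None:
            self.lambda_out_values = borderline_lambda_out(
                self.alphas, self.y, self.delta_u, self.delta_v, self.lambda_in
            )


def borderline_curve(
    y_values,
    delta_u: float = 3.0,
    delta_v: float = 0.5,
    lambda_in: float = 0.1,
    alpha_grid=None,
    n_grid: int = 257,
) -> list[BorderlineCurve]:
    """Family of borderlines, one per y, over a common alpha grid.

    Defaults mirror the reference arc family (du = 3.0, dv = 0.5,
    lambda_in = 0.1, alpha in (-pi/2, pi/2)).  The grid must avoid the
    singular direction alpha = arctan(-du/dv); the default grid spans the
    positive-denominator branch |alpha - alpha*| < pi/2 (with alpha* the
    arc minimum) clipped to (-pi/2, pi/2), where the curve is a convex arc.
    """
    if alpha_grid is None:
        alpha_star = math.atan2(delta_v, delta_u)
        lo = max(-np.pi / 2, alpha_star - np.pi / 2) + 0.05
        hi = min(np.pi / 2, alpha_star + np.pi / 2) - 0.05
        alpha_grid = np.linspace(lo, hi, n_grid)
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    return [
        BorderlineCurve(float(y), delta_u, delta_v, lambda_in, alpha_grid)
        for y in np.atleast_1d(y_values)
    ]
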
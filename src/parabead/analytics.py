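"""Traveling-wave steady state and the self-consistent bead speed.

For a bead moving at constant speed ``v`` the removal equation in the
co-moving coordinate ``xi = x - v*tau`` integrates in closed form,

    a(xi) = exp( -(1/v) * ∫_xi^∞ exp(-s^2/(2 c^2)) ds )
          = exp( -(c/v) * sqrt(pi/2) * erfc(xi / (c*sqrt(2))) ),

a wavefront that saturates to 1 ahead of the bead and to the wake floor
``exp(-c*sqrt(2*pi)/v)`` behind it.  Balancing the chemotactic force of this
profile against the drag (speed itself, in dimensionless form) closes a
scalar equation ``v = A0 * F(v; c)`` whose positive root is the predicted
steady-state speed.  The 2D analogue assumes straight-line motion along x, so
each surface point's removal history depends on its lateral offset only
through the Gaussian factor ``exp(-y^2/(2 c^2))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq, minimize_scalar
from scipy.special import erfc

from .fields import simpson_weights

__all__ = [
    "TravelingWave",
    "SpeedSolution",
    "comoving_profile_1d",
    "comoving_profile_2d",
    "comoving_force_2d",
    "self_consistent_speed_1d",
    "self_consistent_speed_2d",
    "find_crossover_c",
    "find_optimal_c",
    "speed_curve",
]

_XI_SUPPORT = 10.0  # the force kernel exp(-xi^2/2) is negligible beyond this
_V_BRACKET = (1e-3, 10.0)


@dataclass(frozen=True)
class TravelingWave:
    """Co-moving steady ParA profile for a bead at constant speed."""

    v: float
    c: float
    xi_grid: np.ndarray
    profile: np.ndarray

    @property
    def wake_floor(self) -> float:
        """Closed-form limit of the profile far behind the bead."""
        return math.exp(-self.c * math.sqrt(2.0 * math.pi) / self.v)


@dataclass(frozen=True)
class SpeedSolution:
    """Self-consistent steady-state speed (0 when no moving branch exists)."""

    v_star: float
    A0: float
    c: float
    converged: bool
    residual: float
    ndim: int = 1


def _removal_tail(xi: np.ndarray | float, c: float) -> np.ndarray | float:
    """``∫_xi^∞ exp(-s^2/(2 c^2)) ds`` via the complementary error function."""
    return c * math.sqrt(math.pi / 2.0) * erfc(np.asarray(xi) / (c * math.sqrt(2.0)))


def comoving_profile_1d(v: float, c: float, xi_grid: np.ndarray) -> TravelingWave:
    """Steady wavefront ``a(xi)`` seen from the bead moving at speed ``v``."""
    if v <= 0:
        raise ValueError(f"no traveling frame for v <= 0 (got {v})")
    if c <= 0:
        raise ValueError(f"c must be positive, got {c}")
    xi_grid = np.asarray(xi_grid, dtype=float)
    profile = np.exp(-_removal_tail(xi_grid, c) / v)
    return TravelingWave(v=v, c=c, xi_grid=xi_grid, profile=profile)


def _force_1d(v: float, c: float) -> float:
    """Steady-state force functional ``F(v; c)`` (per unit A0), adaptive quad."""

    def integrand(xi: float) -> float:
        a = math.exp(-float(_removal_tail(xi, c)) / v)
        return math.exp(-0.5 * xi * xi) * xi / (1.0 + xi * xi) * a

    val, _ = quad(integrand, -_XI_SUPPORT, _XI_SUPPORT, epsabs=1e-10, epsrel=1e-8, limit=200)
    return val


class _Force2D:
    """2D force functional on a cached tensor-product Simpson grid.

    The kernel and weights depend only on ``c`` (through the grid
    resolution), so repeated evaluations during root finding reuse them and
    only the exponential profile is recomputed per speed.
    """

    def __init__(self, c: float):
        if c <= 0:
            raise ValueError(f"c must be positive, got {c}")
        self.c = c
        h_target = min(0.04, c / 8.0)
        n_int = int(math.ceil(2.0 * _XI_SUPPORT / h_target))
        n_int += n_int % 2
        self.h = 2.0 * _XI_SUPPORT / n_int
        self.x = -_XI_SUPPORT + self.h * np.arange(n_int + 1)
        w = simpson_weights(n_int + 1, self.h)
        X = self.x[:, None]
        Y = self.x[None, :]
        rho2 = X * X + Y * Y
        self._kernel_x = (w[:, None] * w[None, :]) * np.exp(-0.5 * rho2) * X / (1.0 + rho2)
        self._kernel_y = (w[:, None] * w[None, :]) * np.exp(-0.5 * rho2) * Y / (1.0 + rho2)
        self._tail_x = np.asarray(_removal_tail(self.x, c))  # along-track history
        self._gauss_y = np.exp(-(self.x * self.x) / (2.0 * c * c))

    def profile(self, v: float) -> np.ndarray:
        if v <= 0:
            raise ValueError(f"no traveling frame for v <= 0 (got {v})")
        return np.exp(np.outer(self._tail_x, self._gauss_y) / (-v))

    def __call__(self, v: float) -> float:
        return float(np.sum(self._kernel_x * self.profile(v)))

    def force_vector(self, v: float) -> tuple[float, float]:
        a = self.profile(v)
        return float(np.sum(self._kernel_x * a)), float(np.sum(self._kernel_y * a))


def comoving_profile_2d(
    v: float, c: float, x_grid: np.ndarray, y_grid: np.ndarray
) -> np.ndarray:
    """Steady 2D profile ``a(x, y)`` for straight-line motion along x.

    The ``y = 0`` slice equals the 1D wavefront; far off-axis the surface is
    untouched (``a -> 1``).
    """
    if v <= 0:
        raise ValueError(f"no traveling frame for v <= 0 (got {v})")
    if c <= 0:
        raise ValueError(f"c must be positive, got {c}")
    x_grid = np.asarray(x_grid, dtype=float)
    y_grid = np.asarray(y_grid, dtype=float)
    tail = np.asarray(_removal_tail(x_grid, c))
    gauss = np.exp(-(y_grid * y_grid) / (2.0 * c * c))
    return np.exp(np.outer(tail, gauss) / (-v))


def comoving_force_2d(v: float, c: float) -> tuple[float, float]:
    """Steady-state force vector (f_x, f_y) per unit A0 on the 2D profile.

    ``f_y`` vanishes by mirror symmetry about the line of motion.
    """
    return _Force2D(c).force_vector(v)


def _solve_speed(force, A0: float, c: float, ndim: int) -> SpeedSolution:
    v_lo, v_hi = _V_BRACKET

    def gap(v: float) -> float:
        return A0 * force(v) - v

    g_lo = gap(v_lo)
    if g_lo <= 0.0:
        # force cannot beat drag even at crawling speed: stalled branch
        return SpeedSolution(v_star=0.0, A0=A0, c=c, converged=True, residual=abs(g_lo), ndim=ndim)
    g_hi = gap(v_hi)
    if g_hi >= 0.0:
        raise RuntimeError(
            f"speed equation not bracketed on [{v_lo}, {v_hi}] "
            f"(gap {g_lo:.3g} .. {g_hi:.3g}); A0={A0}, c={c}"
        )
    v_star = brentq(gap, v_lo, v_hi, xtol=1e-10, rtol=1e-12)
    residual = abs(gap(v_star))
    return SpeedSolution(
        v_star=float(v_star), A0=A0, c=c, converged=True, residual=residual, ndim=ndim
    )


def self_consistent_speed_1d(A0: float, c: float) -> SpeedSolution:
    """Positive root of ``v = A0 * F_1d(v; c)`` (0 if the bead cannot move)."""
    if A0 <= 0 or c <= 0:
        raise ValueError("A0 and c must be positive")
    return _solve_speed(lambda v: _force_1d(v, c), A0, c, ndim=1)


def self_consistent_speed_2d(A0: float, c: float) -> SpeedSolution:
    """Positive root of ``v = A0 * F_2d(v; c)`` for straight-line 2D motion."""
    if A0 <= 0 or c <= 0:
        raise ValueError("A0 and c must be positive")
    return _solve_speed(_Force2D(c), A0, c, ndim=2)


def find_crossover_c(
    A0: float, c_lo: float = 0.05, c_hi: float = 0.95, tol: float = 1e-3
) -> float | None:
    """``c`` at which the 1D and 2D steady speeds coincide.

    Below the crossover the thin 2D wake leaves attractive ParA alongside and
    behind the bead, so the 1D system is faster; above it, 2D wins.  Returns
    None when the speed difference does not change sign on the interval.
    """

    def diff(c: float) -> float:
        return self_consistent_speed_1d(A0, c).v_star - self_consistent_speed_2d(A0, c).v_star

    d_lo, d_hi = diff(c_lo), diff(c_hi)
    if d_lo == 0.0:
        return c_lo
    if d_hi == 0.0:
        return c_hi
    if d_lo * d_hi > 0:
        return None
    return float(brentq(diff, c_lo, c_hi, xtol=tol))


def find_optimal_c(
    A0: float, ndim: int = 1, c_lo: float = 0.05, c_hi: float = 1.0, xatol: float = 1e-3
) -> tuple[float, float]:
    """Kernel ratio maximizing the steady speed, and that maximal speed.

    Too small a ``c`` removes almost no ParA (no gradient, no motion); too
    large a ``c`` flattens the gradient — the speed peaks in between.
    """
    solver = self_consistent_speed_1d if ndim == 1 else self_consistent_speed_2d

    result = minimize_scalar(
        lambda c: -solver(A0, c).v_star,
        bounds=(c_lo, c_hi),
        method="bounded",
        options={"xatol": xatol},
    )
    v_max = -float(result.fun)
    if v_max <= 0.0:
        raise RuntimeError(f"speed curve is flat/stalled on ({c_lo}, {c_hi}) for A0={A0}")
    return float(result.x), v_max


def speed_curve(A0: float, c_values) -> "pandas.DataFrame":  # noqa: F821
    """Analytic 1D and 2D steady speeds tabulated over ``c_values``."""
    import pandas as pd

    rows = [
        {
            "c": float(c),
            "v1d": self_consistent_speed_1d(A0, c).v_star,
            "v2d": self_consistent_speed_2d(A0, c).v_star,
        }
        for c in c_values
    ]
    return pd.DataFrame(rows)
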
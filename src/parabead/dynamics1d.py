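"""Explicit-Euler time integration of the 1D ParA-ParB transport model.

The surface ParA concentration ``a(x, tau)`` is depleted by a Gaussian
removal kernel centered on the bead, and the overdamped bead moves with a
velocity proportional to the Simpson-quadrature force integral

    v = A0 * ∫ exp(-(x-x_p)^2/2) * (x-x_p)/(1+(x-x_p)^2) * a(x) dx .

Optional extensions: rebinding of removed ParA from a well-mixed buffer onto
a noisy binding-site field (with non-cooperative rate ``k_r`` and cooperative
rate ``k_c``), and conservative surface diffusion of bound ParA limited by
the binding-site distribution.

Numerical symmetry note: node offsets from the bead are computed relative to
the nearest grid node, and the force reduction pairs mirror-image nodes, so a
perfectly flat field with a centered bead yields a velocity of exactly 0.0 —
the unbroken-symmetry state is a fixed point of the discrete update too, not
just of the continuum equations.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field as dataclass_field
from typing import TYPE_CHECKING

import numpy as np

from .fields import (
    BeadState,
    BindingSiteField,
    BufferState,
    ParAField1D,
    init_binding_sites,
    init_para_field,
    simpson_weights,
)
from .params import (
    DiffusionParams,
    DimensionlessParams,
    NumericsConfig,
    RebindingParams,
)

if TYPE_CHECKING:  # pragma: no cover
    from .config import SimulationConfig

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "removal_rate",
    "bead_speed",
    "step_base",
    "step_rebinding",
    "step_diffusion",
    "equilibrate_surface",
    "simulate_1d",
]


@dataclass
class Trajectory:
    """Time series of a simulated run (1D or 2D).

    ``snapshots`` maps requested times to copies of the field values at the
    nearest integration step.
    """

    times: np.ndarray
    positions: np.ndarray
    speeds: np.ndarray
    positions_y: np.ndarray | None = None
    speeds_y: np.ndarray | None = None
    buffer: np.ndarray | None = None
    snapshots: dict = dataclass_field(default_factory=dict)
    grid: np.ndarray | None = None
    mode: str = "base"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.speeds = np.asarray(self.speeds, dtype=float)
        if self.times.ndim != 1 or len(self.times) != len(self.positions):
            raise ValueError("times and positions must be 1D and equally long")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def displacement(self) -> float:
        """Net displacement from the starting position (Euclidean in 2D)."""
        dx = self.positions[-1] - self.positions[0]
        if self.positions_y is not None:
            dy = self.positions_y[-1] - self.positions_y[0]
            return float(math.hypot(dx, dy))
        return float(abs(dx))


_INDEX_CACHE: dict[int, np.ndarray] = {}
_WEIGHT_CACHE: dict[tuple[int, float], np.ndarray] = {}


def _indices(n: int) -> np.ndarray:
    idx = _INDEX_CACHE.get(n)
    if idx is None:
        idx = _INDEX_CACHE[n] = np.arange(n, dtype=float)
    return idx


def _weights(n: int, dx: float) -> np.ndarray:
    key = (n, dx)
    w = _WEIGHT_CACHE.get(key)
    if w is None:
        w = _WEIGHT_CACHE[key] = simpson_weights(n, dx)
    return w


def _offsets(grid: np.ndarray, x_p: float, dx: float) -> np.ndarray:
    """Node offsets ``x - x_p`` computed relative to the nearest node.

    When the bead sits exactly on a node the result is exactly antisymmetric
    about it, which the mirror-paired reductions below turn into exact force
    cancellation for symmetric fields.
    """
    i_near = int(round(x_p / dx))
    i_near = min(max(i_near, 0), grid.size - 1)
    delta = x_p - dx * i_near
    u = dx * (_indices(grid.size) - i_near)
    if delta != 0.0:
        u -= delta
    return u


def _mirror_sum(s: np.ndarray) -> float:
    """Sum of ``s`` that cancels mirror-image pairs exactly."""
    return 0.5 * float(np.sum(s + s[::-1]))


def removal_rate(field: ParAField1D, x_p: float, c: float) -> np.ndarray:
    """Per-node ParA removal rate ``exp(-(x-x_p)^2/(2 c^2)) * a(x)``."""
    if c <= 0:
        raise ValueError(f"c must be positive, got {c}")
    if not (field.grid[0] - field.dx <= x_p <= field.grid[-1] + field.dx):
        raise ValueError(f"bead position {x_p} outside the domain")
    u = _offsets(field.grid, x_p, field.dx)
    return np.exp(u * u / (-2.0 * c * c)) * field.values


def bead_speed(field: ParAField1D, x_p: float, A0: float) -> float:
    """Bead velocity from the Simpson-quadrature force integral."""
    u = _offsets(field.grid, x_p, field.dx)
    kernel = np.exp(-0.5 * u * u) * u / (1.0 + u * u)
    w = _weights(field.grid.size, field.dx)
    return A0 * _mirror_sum(w * kernel * field.values)


def _clamp_nonnegative(values: np.ndarray) -> None:
    neg = values < 0
    if np.any(neg):
        warnings.warn(
            "Euler step drove the ParA concentration negative; clamping to 0 "
            "(consider a smaller dtau)",
            stacklevel=3,
        )
        values[neg] = 0.0


def _clamp_position(x_p: float, grid: np.ndarray) -> float:
    return min(max(x_p, float(grid[0])), float(grid[-1]))


def step_base(
    field: ParAField1D,
    bead: BeadState,
    params: DimensionlessParams,
    numerics: NumericsConfig,
) -> tuple[ParAField1D, BeadState]:
    """One Euler step of the minimal removal + force model.

    The velocity is evaluated on the pre-update field; field and bead then
    advance simultaneously.  The bead is clamped to the domain (at an edge it
    waits — in the base model, forever, since ParA never recovers).
    """
    v = bead_speed(field, bead.x_p, params.A0)
    new_values = field.values - numerics.dtau * removal_rate(field, bead.x_p, params.c)
    _clamp_nonnegative(new_values)
    x_new = _clamp_position(bead.x_p + numerics.dtau * v, field.grid)
    return ParAField1D(field.grid, new_values, validate=False), BeadState(x_p=x_new, v=v)


def _rebinding_gain(
    a: np.ndarray, sites: BindingSiteField, a_b: float, rb: RebindingParams
) -> np.ndarray:
    return a_b * (sites.values - a) * (rb.k_r + rb.k_c * a)


def _check_capacity(a: np.ndarray, d: np.ndarray) -> None:
    if np.any(a > d + 1e-9):
        raise ValueError("bound ParA exceeds the binding-site capacity d(x)")


def step_rebinding(
    field: ParAField1D,
    bead: BeadState,
    buffer: BufferState,
    sites: BindingSiteField,
    rb: RebindingParams,
    params: DimensionlessParams,
    numerics: NumericsConfig,
) -> tuple[ParAField1D, BeadState, BufferState]:
    """One Euler step with removal, buffer rebinding and the buffer budget.

    Removed ParA enters the well-mixed buffer uniformly (divided by the
    domain length), so the discrete update conserves
    ``∫ a dx + L * a_b`` exactly up to floating-point rounding.
    """
    a = field.values
    d = sites.values
    _check_capacity(a, d)
    stiffness = numerics.dtau * buffer.a_b * (rb.k_r + rb.k_c * float(a.max(initial=0.0)))
    if stiffness > 1.0:
        raise ValueError(
            "dtau too large to keep a <= d in the rebinding update; "
            f"reduce dtau below {numerics.dtau / stiffness:g}"
        )
    v = bead_speed(field, bead.x_p, params.A0)
    removal = removal_rate(field, bead.x_p, params.c)
    gain = _rebinding_gain(a, sites, buffer.a_b, rb)
    new_values = a + numerics.dtau * (gain - removal)
    _clamp_nonnegative(new_values)
    w = _weights(field.grid.size, field.dx)
    L = field.L
    da_b = float(w @ (removal - gain)) / L
    new_buffer = BufferState(
        a_b=max(buffer.a_b + numerics.dtau * da_b, 0.0),
        A_s=buffer.A_s,
        phi=buffer.phi,
    )
    x_new = _clamp_position(bead.x_p + numerics.dtau * v, field.grid)
    return (
        ParAField1D(field.grid, new_values, validate=False),
        BeadState(x_p=x_new, v=v),
        new_buffer,
    )


def _second_derivative(values: np.ndarray, dx: float) -> np.ndarray:
    """Central-difference second derivative with zero-flux (mirrored) ends."""
    d2 = np.empty_like(values)
    d2[1:-1] = values[:-2] - 2.0 * values[1:-1] + values[2:]
    d2[0] = 2.0 * (values[1] - values[0])
    d2[-1] = 2.0 * (values[-2] - values[-1])
    return d2 / (dx * dx)


def step_diffusion(
    field: ParAField1D,
    bead: BeadState,
    sites: BindingSiteField,
    dp: DiffusionParams,
    params: DimensionlessParams,
    numerics: NumericsConfig,
) -> tuple[ParAField1D, BeadState]:
    """One Euler step with removal and capacity-limited surface diffusion.

    The diffusive flux is ``kappa * [d * a'' - a * d'']``: ParA spreads only
    into regions with spare binding capacity, so the spatial noise in d(x)
    keeps seeding the gradient that powers the ratchet.  Second derivatives
    are central differences with zero-flux boundaries.
    """
    a = field.values
    d = sites.values
    _check_capacity(a, d)
    dx = field.dx
    cfl = dp.kappa * float(d.max(initial=0.0)) * numerics.dtau / (dx * dx)
    if cfl > 0.5:
        raise ValueError(
            f"diffusion CFL number {cfl:.3g} exceeds 1/2; reduce dtau or kappa, "
            "or coarsen the grid"
        )
    v = bead_speed(field, bead.x_p, params.A0)
    removal = removal_rate(field, bead.x_p, params.c)
    diff = dp.kappa * (d * _second_derivative(a, dx) - a * _second_derivative(d, dx))
    new_values = a + numerics.dtau * (diff - removal)
    _clamp_nonnegative(new_values)
    x_new = _clamp_position(bead.x_p + numerics.dtau * v, field.grid)
    return ParAField1D(field.grid, new_values, validate=False), BeadState(x_p=x_new, v=v)


def _equilibrate_core(
    d: np.ndarray,
    A_s: float,
    rb: RebindingParams,
    weights: np.ndarray,
    measure: float,
    rate_tol: float,
    max_steps: int,
) -> tuple[np.ndarray, float]:
    """Rebinding-only relaxation of an empty surface against buffer ParA.

    Dimension-agnostic: ``weights`` is the quadrature weight array matching
    ``d`` and ``measure`` the domain length (1D) or area (2D).  Adaptive
    Euler; stops when the fastest pointwise binding rate drops below
    ``rate_tol``.
    """
    if rb.k_r <= 0:
        raise ValueError(
            "equilibration requires k_r > 0: with no non-cooperative rate, "
            "nothing can bind to an empty surface"
        )
    a = np.zeros_like(d)
    a_b = A_s
    peak = np.inf
    for _ in range(max_steps):
        gain = a_b * (d - a) * (rb.k_r + rb.k_c * a)
        peak = float(np.abs(gain).max(initial=0.0))
        if peak < rate_tol:
            return a, a_b
        dtau = min(0.2, 0.5 / (a_b * (rb.k_r + rb.k_c * float(a.max(initial=0.0))) + 1e-30))
        a = a + dtau * gain
        a_b = max(a_b - dtau * float(np.sum(weights * gain)) / measure, 0.0)
    raise RuntimeError(
        f"surface equilibration did not converge within {max_steps} steps "
        f"(residual rate {peak:.3g})"
    )


def equilibrate_surface(
    sites: BindingSiteField,
    buffer: BufferState,
    rb: RebindingParams,
    numerics: NumericsConfig | None = None,
    *,
    rate_tol: float = 1e-8,
    max_steps: int = 2_000_000,
) -> tuple[ParAField1D, BufferState]:
    """Pre-bead equilibration: buffer ParA binds to the empty surface.

    Integrates the rebinding-only dynamics from ``a = 0``, ``a_b = A_s`` with
    an adaptive Euler step until the fastest pointwise binding rate falls
    below ``rate_tol``.  In the saturated regime (phi > 1) the surface ends
    at ``a ≈ d`` with buffer left over; undersaturated, the buffer empties
    onto the surface at uniform fractional occupancy.
    """
    if sites.grid is None:
        raise ValueError("binding-site field must carry its grid")
    grid = sites.grid
    w = simpson_weights(grid.size, float(grid[1] - grid[0]))
    L = float(grid[-1] - grid[0])
    a, a_b = _equilibrate_core(
        sites.values, buffer.a_b, rb, w, L, rate_tol, max_steps
    )
    return ParAField1D(grid, a), BufferState(a_b=a_b, A_s=buffer.A_s, phi=buffer.phi)


def _prepare_initial_state(config: "SimulationConfig"):
    """Build the initial field (and buffer/sites where relevant) for a run."""
    params = config.params
    numerics = config.numerics
    rng = np.random.default_rng(numerics.seed)
    if config.mode == "base":
        field = init_para_field(config.mean_a, params.delta_a, params.L, numerics.dx, rng)
        return field, None, None
    sites = init_binding_sites(config.D0, config.delta_d, params.L, numerics.dx, rng)
    if config.mode == "rebinding":
        buffer = BufferState.from_phi(config.phi, config.D0)
        field, buffer = equilibrate_surface(sites, buffer, config.rebinding)
        return field, sites, buffer
    if config.mode == "diffusion":
        # uniform fractional occupancy phi on the noisy capacity field
        field = ParAField1D(sites.grid, config.phi * sites.values)
        return field, sites, None
    raise ValueError(f"unknown mode {config.mode!r}")


def simulate_1d(config: "SimulationConfig") -> Trajectory:
    """Integrate a full 1D run and record the bead trajectory.

    The bead starts at the domain-center node.  Recording happens every step;
    field snapshots are taken at the requested times.  If
    ``config.stop_displacement`` is set, the run ends early once the bead has
    travelled that far (useful for speed fits that do not need the bead to
    approach the boundary).
    """
    params = config.params
    numerics = config.numerics
    numerics.validate_against(params)
    field, sites, buffer = _prepare_initial_state(config)
    n_mid = field.grid.size // 2
    bead = BeadState(x_p=float(field.grid[n_mid]))
    x_start = bead.x_p

    n_steps = int(round(numerics.tau_max / numerics.dtau))
    times = np.empty(n_steps + 1)
    positions = np.empty(n_steps + 1)
    speeds = np.empty(n_steps + 1)
    buffers = np.empty(n_steps + 1) if buffer is not None else None

    snap_taus = sorted(config.snapshot_taus)
    snap_steps = {int(round(t / numerics.dtau)): t for t in snap_taus}
    snapshots: dict[float, np.ndarray] = {}

    k = 0
    for step_idx in range(n_steps + 1):
        tau = step_idx * numerics.dtau
        if step_idx in snap_steps:
            snapshots[snap_steps[step_idx]] = field.values.copy()
        if step_idx == n_steps:
            times[step_idx] = tau
            positions[step_idx] = bead.x_p
            speeds[step_idx] = bead_speed(field, bead.x_p, params.A0)
            if buffers is not None:
                buffers[step_idx] = buffer.a_b
            k = step_idx
            break
        times[step_idx] = tau
        positions[step_idx] = bead.x_p
        if buffers is not None:
            buffers[step_idx] = buffer.a_b
        if config.mode == "base":
            field, bead = step_base(field, bead, params, numerics)
        elif config.mode == "rebinding":
            field, bead, buffer = step_rebinding(
                field, bead, buffer, sites, config.rebinding, params, numerics
            )
        else:
            field, bead = step_diffusion(
                field, bead, sites, config.diffusion, params, numerics
            )
        speeds[step_idx] = bead.v
        k = step_idx + 1
        if (
            config.stop_displacement is not None
            and abs(bead.x_p - x_start) >= config.stop_displacement
        ):
            times[k] = (step_idx + 1) * numerics.dtau
            positions[k] = bead.x_p
            speeds[k] = bead.v
            if buffers is not None:
                buffers[k] = buffer.a_b
            break

    return Trajectory(
        times=times[: k + 1],
        positions=positions[: k + 1],
        speeds=speeds[: k + 1],
        buffer=None if buffers is None else buffers[: k + 1],
        snapshots=snapshots,
        grid=field.grid,
        mode=config.mode,
    )
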
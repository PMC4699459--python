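"""2D extension: ParA field on a square lattice with a vector force integral.

The removal kernel is isotropic about the bead, ``exp(-rho^2 / (2 c^2))``
with ``rho`` the Euclidean distance to the bead, and each velocity component
integrates the matching vector kernel

    v_x = A0 * ∫∫ exp(-rho^2/2) * (x - x_p) / (1 + rho^2) * a(x, y) dx dy

by tensor-product Simpson quadrature (and likewise for ``v_y``).  Mirror
pairing along the force axis keeps symmetric configurations exactly
stationary, as in 1D.
"""

from __future__ import annotations

from typing import TYPE_CHECKING

import numpy as np

from .dynamics1d import (
    Trajectory,
    _clamp_nonnegative,
    _equilibrate_core,
    _offsets,
)
from .fields import (
    BeadState,
    BufferState,
    ParAField2D,
    init_para_field_2d,
    make_grid,
    simpson_weights,
)
from .params import DimensionlessParams, NumericsConfig, RebindingParams

if TYPE_CHECKING:  # pragma: no cover
    from .config import SimulationConfig

__all__ = [
    "removal_rate_2d",
    "bead_velocity_2d",
    "step_2d",
    "simulate_2d",
]


def _offset_grids(field: ParAField2D, x_p: float, y_p: float):
    ux = _offsets(field.grid, x_p, field.dx)[:, None]
    uy = _offsets(field.grid, y_p, field.dx)[None, :]
    return ux, uy


def removal_rate_2d(
    field: ParAField2D, x_p: float, y_p: float, c: float
) -> np.ndarray:
    """Per-node removal rate ``exp(-rho^2/(2 c^2)) * a`` (Euclidean rho)."""
    if c <= 0:
        raise ValueError(f"c must be positive, got {c}")
    ux, uy = _offset_grids(field, x_p, y_p)
    rho2 = ux * ux + uy * uy
    return np.exp(rho2 / (-2.0 * c * c)) * field.values


def _mirror_sum_axis(s: np.ndarray, axis: int) -> float:
    flipped = s[::-1, :] if axis == 0 else s[:, ::-1]
    return 0.5 * float(np.sum(s + flipped))


def bead_velocity_2d(
    field: ParAField2D, x_p: float, y_p: float, A0: float
) -> tuple[float, float]:
    """Vector bead velocity from the tensor-product Simpson force integral."""
    n = field.grid.size
    lo, hi = float(field.grid[0]), float(field.grid[-1])
    if not (lo <= x_p <= hi and lo <= y_p <= hi):
        raise ValueError(f"bead position ({x_p}, {y_p}) outside the domain")
    ux, uy = _offset_grids(field, x_p, y_p)
    rho2 = ux * ux + uy * uy
    common = np.exp(-0.5 * rho2) / (1.0 + rho2) * field.values
    w = simpson_weights(n, field.dx)
    W = w[:, None] * w[None, :]
    v_x = A0 * _mirror_sum_axis(W * common * ux, axis=0)
    v_y = A0 * _mirror_sum_axis(W * common * uy, axis=1)
    return v_x, v_y


def _clamp(p: float, lo: float, hi: float) -> float:
    return min(max(p, lo), hi)


def step_2d(
    field: ParAField2D,
    bead: BeadState,
    params: DimensionlessParams,
    numerics: NumericsConfig,
    buffer: BufferState | None = None,
    sites: np.ndarray | None = None,
    rebinding: RebindingParams | None = None,
) -> tuple[ParAField2D, BeadState, BufferState | None]:
    """One Euler step in 2D (base, or rebinding when a buffer is given).

    Velocity is evaluated on the pre-update field; the bead is clamped to
    the square domain.  Rebinding feeds removed ParA back through the
    well-mixed buffer, dividing by the surface area ``L^2``.
    """
    v_x, v_y = bead_velocity_2d(field, bead.x_p, bead.y_p, params.A0)
    removal = removal_rate_2d(field, bead.x_p, bead.y_p, params.c)
    new_values = field.values - numerics.dtau * removal
    new_buffer = buffer
    if buffer is not None:
        if sites is None or rebinding is None:
            raise ValueError("rebinding in 2D needs both sites and rate parameters")
        stiffness = numerics.dtau * buffer.a_b * (
            rebinding.k_r + rebinding.k_c * float(field.values.max(initial=0.0))
        )
        if stiffness > 1.0:
            raise ValueError(
                "dtau too large to keep a <= d in the 2D rebinding update; "
                f"reduce dtau below {numerics.dtau / stiffness:g}"
            )
        gain = buffer.a_b * (sites - field.values) * (
            rebinding.k_r + rebinding.k_c * field.values
        )
        new_values += numerics.dtau * gain
        w = simpson_weights(field.grid.size, field.dx)
        W = w[:, None] * w[None, :]
        area = field.L ** 2
        da_b = float(np.sum(W * (removal - gain))) / area
        new_buffer = BufferState(
            a_b=max(buffer.a_b + numerics.dtau * da_b, 0.0),
            A_s=buffer.A_s,
            phi=buffer.phi,
        )
    _clamp_nonnegative(new_values)
    lo, hi = float(field.grid[0]), float(field.grid[-1])
    new_bead = BeadState(
        x_p=_clamp(bead.x_p + numerics.dtau * v_x, lo, hi),
        y_p=_clamp(bead.y_p + numerics.dtau * v_y, lo, hi),
        v=v_x,
        v_y=v_y,
    )
    return ParAField2D(field.grid, new_values), new_bead, new_buffer


def simulate_2d(config: "SimulationConfig") -> Trajectory:
    """Integrate a full 2D run (base or rebinding mode).

    The bead starts at the central lattice node.  Snapshots store full 2D
    concentration matrices at the requested times.
    """
    params = config.params
    numerics = config.numerics
    numerics.validate_against(params)
    rng = np.random.default_rng(numerics.seed)
    if config.mode == "base":
        field = init_para_field_2d(
            config.mean_a, params.delta_a, params.L, numerics.dx, rng
        )
        sites = None
        buffer = None
    elif config.mode == "rebinding":
        grid = make_grid(params.L, numerics.dx)
        n = grid.size
        if config.delta_d > 0:
            d = rng.uniform(
                config.D0 - config.delta_d, config.D0 + config.delta_d, size=(n, n)
            )
        else:
            d = np.full((n, n), float(config.D0))
        w = simpson_weights(n, float(grid[1] - grid[0]))
        W = w[:, None] * w[None, :]
        area = float(grid[-1] - grid[0]) ** 2
        A_s = config.phi * config.D0
        a, a_b = _equilibrate_core(
            d, A_s, config.rebinding, W, area, rate_tol=1e-8, max_steps=2_000_000
        )
        field = ParAField2D(grid, a)
        sites = d
        buffer = BufferState(a_b=a_b, A_s=A_s, phi=config.phi)
    else:
        raise ValueError(f"2D simulation supports base/rebinding, not {config.mode!r}")

    mid = float(field.grid[field.grid.size // 2])
    bead = BeadState(x_p=mid, y_p=mid)
    x0, y0 = bead.x_p, bead.y_p

    n_steps = int(round(numerics.tau_max / numerics.dtau))
    times = np.empty(n_steps + 1)
    xs = np.empty(n_steps + 1)
    ys = np.empty(n_steps + 1)
    vxs = np.empty(n_steps + 1)
    vys = np.empty(n_steps + 1)
    buffers = np.empty(n_steps + 1) if buffer is not None else None
    snap_steps = {int(round(t / numerics.dtau)): t for t in sorted(config.snapshot_taus)}
    snapshots: dict[float, np.ndarray] = {}

    k = 0
    for step_idx in range(n_steps + 1):
        tau = step_idx * numerics.dtau
        if step_idx in snap_steps:
            snapshots[snap_steps[step_idx]] = field.values.copy()
        times[step_idx] = tau
        xs[step_idx] = bead.x_p
        ys[step_idx] = bead.y_p
        if buffers is not None:
            buffers[step_idx] = buffer.a_b
        if step_idx == n_steps:
            v_x, v_y = bead_velocity_2d(field, bead.x_p, bead.y_p, params.A0)
            vxs[step_idx], vys[step_idx] = v_x, v_y
            k = step_idx
            break
        field, bead, buffer = step_2d(
            field,
            bead,
            params,
            numerics,
            buffer=buffer,
            sites=sites,
            rebinding=config.rebinding if buffer is not None else None,
        )
        vxs[step_idx], vys[step_idx] = bead.v, bead.v_y
        k = step_idx + 1
        if (
            config.stop_displacement is not None
            and np.hypot(bead.x_p - x0, bead.y_p - y0) >= config.stop_displacement
        ):
            times[k] = (step_idx + 1) * numerics.dtau
            xs[k], ys[k] = bead.x_p, bead.y_p
            vxs[k], vys[k] = bead.v, bead.v_y
            if buffers is not None:
                buffers[k] = buffer.a_b
            break

    return Trajectory(
        times=times[: k + 1],
        positions=xs[: k + 1],
        speeds=vxs[: k + 1],
        positions_y=ys[: k + 1],
        speeds_y=vys[: k + 1],
        buffer=None if buffers is None else buffers[: k + 1],
        snapshots=snapshots,
        grid=field.grid,
        mode=config.mode,
    )
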
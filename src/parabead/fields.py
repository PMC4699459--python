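"""Gridded concentration fields and their seeded noisy initializers.

Grids are node-centered and include both endpoints, with an even interval
count so that composite Simpson quadrature applies to the whole domain.  The
node coordinates are materialized as ``dx * arange(n)``: offsets between any
node and an on-grid bead position are then exactly antisymmetric in floating
point, a property the dynamics code exploits to preserve the unbroken-symmetry
state exactly (a perfectly flat field with a centered bead never moves).
"""

from __future__ import annotations

from dataclasses import InitVar, dataclass, field

import numpy as np

__all__ = [
    "make_grid",
    "simpson_weights",
    "ParAField1D",
    "ParAField2D",
    "BindingSiteField",
    "BufferState",
    "BeadState",
    "init_para_field",
    "init_binding_sites",
    "init_para_field_2d",
]


def _n_intervals(L: float, dx: float) -> int:
    if L <= 0 or dx <= 0:
        raise ValueError("L and dx must be positive")
    n_int = int(round(L / dx))
    if n_int < 2:
        raise ValueError(f"domain L={L} too short for spacing dx={dx}")
    if n_int % 2:
        n_int += 1  # Simpson needs an even interval count; nudge dx
    return n_int


def make_grid(L: float, dx: float) -> np.ndarray:
    """Uniform node-centered grid on [0, L] with an even interval count.

    The effective spacing is ``L / round(L/dx)`` (adjusted minutely if the
    requested spacing does not divide L into an even number of intervals).
    """
    n_int = _n_intervals(L, dx)
    spacing = L / n_int
    return spacing * np.arange(n_int + 1)


def simpson_weights(n_nodes: int, dx: float) -> np.ndarray:
    """Composite Simpson's-rule weights for ``n_nodes`` equally spaced nodes.

    ``n_nodes`` must be odd (even interval count).
    """
    if n_nodes < 3 or n_nodes % 2 == 0:
        raise ValueError(f"Simpson's rule needs an odd node count, got {n_nodes}")
    w = np.full(n_nodes, 2.0)
    w[1::2] = 4.0
    w[0] = w[-1] = 1.0
    return w * (dx / 3.0)


@dataclass
class ParAField1D:
    """Surface-bound ParA concentration ``a(x, tau)`` on a 1D grid.

    ``validate=False`` skips the invariant checks; the integrators use it
    when rebuilding a field from an already-validated grid every step.
    """

    grid: np.ndarray
    values: np.ndarray
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        if not validate:
            return
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.values.shape:
            raise ValueError("grid and values must be 1D arrays of equal length")
        if self.grid.size < 3 or self.grid.size % 2 == 0:
            raise ValueError("grid must have an odd number of nodes (>= 3)")
        steps = np.diff(self.grid)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=0.0):
            raise ValueError("grid must be uniform")
        if np.any(self.values < 0):
            raise ValueError("ParA concentration must be non-negative")

    @property
    def dx(self) -> float:
        return float(self.grid[1] - self.grid[0])

    @property
    def L(self) -> float:
        return float(self.grid[-1] - self.grid[0])

    def copy(self) -> "ParAField1D":
        return ParAField1D(self.grid, self.values.copy())

    def total(self) -> float:
        """Simpson quadrature of the field over the domain."""
        return float(simpson_weights(self.grid.size, self.dx) @ self.values)


@dataclass
class BindingSiteField:
    """ParA binding-site concentration ``d(x)`` on the DNA substrate."""

    values: np.ndarray
    D0: float
    delta_d: float
    grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.D0 <= 0:
            raise ValueError(f"D0 must be positive, got {self.D0}")
        if not 0 <= self.delta_d <= self.D0:
            raise ValueError(
                f"delta_d must lie in [0, D0], got {self.delta_d} (D0={self.D0})"
            )
        lo, hi = self.D0 - self.delta_d, self.D0 + self.delta_d
        if np.any(self.values < lo - 1e-12) or np.any(self.values > hi + 1e-12):
            raise ValueError("binding-site values outside [D0-delta_d, D0+delta_d]")


@dataclass
class BufferState:
    """Well-mixed buffer ParA.

    ``phi = A_s / D0`` splits the dynamics into an undersaturated (phi < 1)
    and a saturated (phi > 1) regime.
    """

    a_b: float
    A_s: float
    phi: float

    def __post_init__(self) -> None:
        if self.a_b < 0:
            raise ValueError(f"buffer concentration must be non-negative, got {self.a_b}")

    @classmethod
    def from_phi(cls, phi: float, D0: float) -> "BufferState":
        if phi <= 0:
            raise ValueError(f"phi must be positive, got {phi}")
        A_s = phi * D0
        return cls(a_b=A_s, A_s=A_s, phi=phi)


@dataclass
class BeadState:
    """Bead position (and instantaneous speed) in dimensionless units."""

    x_p: float
    y_p: float | None = None
    v: float = 0.0
    v_y: float = 0.0


@dataclass
class ParAField2D:
    """Surface ParA ``a(x, y, tau)`` on a uniform square lattice [0,L]^2.

    ``values[i, j]`` is the concentration at ``(x=grid[i], y=grid[j])``.
    """

    grid: np.ndarray
    values: np.ndarray
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        if not validate:
            return
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        n = self.grid.size
        if self.values.shape != (n, n):
            raise ValueError("values must be square with side len(grid)")
        if n < 3 or n % 2 == 0:
            raise ValueError("grid must have an odd number of nodes (>= 3)")
        if np.any(self.values < 0):
            raise ValueError("ParA concentration must be non-negative")

    @property
    def dx(self) -> float:
        return float(self.grid[1] - self.grid[0])

    @property
    def L(self) -> float:
        return float(self.grid[-1] - self.grid[0])

    def copy(self) -> "ParAField2D":
        return ParAField2D(self.grid, self.values.copy())


def _uniform_noisy(
    mean: float, half_width: float, shape, seed: int | np.random.Generator
) -> np.ndarray:
    if half_width < 0:
        raise ValueError(f"noise half-width must be non-negative, got {half_width}")
    if half_width > mean:
        raise ValueError(
            f"noise half-width {half_width} exceeds mean {mean}: "
            "negative concentrations would result"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if half_width == 0:
        return np.full(shape, float(mean))
    return rng.uniform(mean - half_width, mean + half_width, size=shape)


def init_para_field(
    mean: float,
    delta_a: float,
    L: float,
    dx: float,
    seed: int | np.random.Generator,
) -> ParAField1D:
    """Spatially noisy initial ParA field: iid uniform on [mean±delta_a].

    Deterministic given the seed; ``delta_a = 0`` gives an exactly flat field.
    """
    grid = make_grid(L, dx)
    values = _uniform_noisy(mean, delta_a, grid.shape, seed)
    return ParAField1D(grid, values)


def init_binding_sites(
    D0: float,
    delta_d: float,
    L: float,
    dx: float,
    seed: int | np.random.Generator,
) -> BindingSiteField:
    """Noisy binding-site field d(x): iid uniform on [D0±delta_d], seeded."""
    grid = make_grid(L, dx)
    values = _uniform_noisy(D0, delta_d, grid.shape, seed)
    return BindingSiteField(values=values, D0=D0, delta_d=delta_d, grid=grid)


def init_para_field_2d(
    mean: float,
    delta_a: float,
    L: float,
    dx: float,
    seed: int | np.random.Generator,
) -> ParAField2D:
    """2D analogue of :func:`init_para_field` on a square lattice."""
    grid = make_grid(L, dx)
    n = grid.size
    values = _uniform_noisy(mean, delta_a, (n, n), seed)
    return ParAField2D(grid, values)
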
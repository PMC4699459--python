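"""Parameter containers and dedimensionalization.

The model lives in dimensionless variables: lengths are measured in units of
the bead radius ``R`` and time in units of the inverse ParA removal rate
``1/gamma0``.  Two numbers then control the physics:

``A0``
    dimensionless force scale, ``F0 * a0 / (beta * R)`` — the product of the
    force per unit ParA·ParB, the ParA concentration scale and the inverse
    drag, measured against the bead radius.
``c``
    ratio ``sigma_r / sigma_f`` of the ParA-removal lengthscale to the
    ParA-ParB attraction lengthscale.  Physically ``c <= 1``: ParB cannot
    hydrolyse ParA it is too far from to feel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "DimensionlessParams",
    "PhysicalParams",
    "NumericsConfig",
    "RebindingParams",
    "DiffusionParams",
    "ForceRangeEstimate",
    "dedimensionalize",
    "redimensionalize",
    "estimate_force_range",
]


@dataclass(frozen=True)
class DimensionlessParams:
    """Control knobs of the dimensionless model.

    Parameters
    ----------
    A0 : float
        Dimensionless force scale (speed is proportional to it).
    c : float
        Removal-to-force lengthscale ratio ``sigma_r / sigma_f``.
    L : float
        Surface length in units of the bead radius.
    delta_a : float
        Half-width of the uniform noise applied to the initial surface ParA
        concentration (same units as the mean concentration).
    """

    A0: float = 1.0
    c: float = 0.5
    L: float = 70.0
    delta_a: float = 0.05

    def __post_init__(self) -> None:
        if self.A0 <= 0:
            raise ValueError(f"A0 must be positive, got {self.A0}")
        if self.c <= 0:
            raise ValueError(f"c must be positive, got {self.c}")
        if self.c > 1:
            warnings.warn(
                f"c = {self.c} > 1 is unphysical (removal outreaching the "
                "attractive force); proceeding anyway",
                stacklevel=3,
            )
        if self.L <= 0:
            raise ValueError(f"L must be positive, got {self.L}")
        if self.delta_a < 0:
            raise ValueError(f"delta_a must be non-negative, got {self.delta_a}")


@dataclass(frozen=True)
class PhysicalParams:
    """Dimensionful parameters of the in vitro system.

    ``beta`` may be omitted, in which case the Stokes drag ``6*pi*eta*R`` is
    filled in from the viscosity and bead radius.  If both are supplied they
    must agree.
    """

    gamma0: float  # ParA removal rate, 1/time
    F0: float  # force scale per unit ParA*ParB
    R: float  # bead radius, length
    sigma_r: float  # removal range, length
    sigma_f: float  # force range, length
    a0: float  # ParA concentration scale
    eta: float | None = None  # buffer viscosity
    beta: float | None = None  # drag coefficient, force*time/length
    _beta: float = field(init=False, repr=False, default=0.0)

    def __post_init__(self) -> None:
        for name in ("gamma0", "F0", "R", "sigma_r", "sigma_f", "a0"):
            value = getattr(self, name)
            if value is None or value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.beta is None and self.eta is None:
            raise ValueError("provide beta, or eta to derive beta = 6*pi*eta*R")
        stokes = None if self.eta is None else 6.0 * math.pi * self.eta * self.R
        beta = self.beta if self.beta is not None else stokes
        if beta is None or beta <= 0:
            raise ValueError(f"beta must be positive, got {beta}")
        if self.beta is not None and stokes is not None:
            if not math.isclose(self.beta, stokes, rel_tol=1e-9):
                raise ValueError(
                    f"beta={self.beta} inconsistent with 6*pi*eta*R={stokes}"
                )
        object.__setattr__(self, "_beta", beta)

    @property
    def drag(self) -> float:
        """Drag coefficient (given, or Stokes ``6*pi*eta*R``)."""
        return self._beta


@dataclass(frozen=True)
class NumericsConfig:
    """Discretization and trajectory-analysis settings.

    Defaults follow the reference 1D setup: surface length 70 sampled at
    ``dx = 0.02`` and advanced by explicit Euler steps of ``dtau = 0.01``.
    """

    dx: float = 0.02
    dtau: float = 0.01
    tau_max: float = 100.0
    seed: int = 0
    speed_fit_window: float = 0.5  # trailing fraction of samples used for fits
    stall_displacement: float = 1.0  # bead radii; less than this means "stalled"

    def __post_init__(self) -> None:
        if self.dx <= 0:
            raise ValueError(f"dx must be positive, got {self.dx}")
        if self.dtau <= 0:
            raise ValueError(f"dtau must be positive, got {self.dtau}")
        if self.dtau > 0.1:
            raise ValueError(
                f"dtau = {self.dtau} too large for the explicit Euler update "
                "(require dtau <= 0.1)"
            )
        if self.tau_max <= 0:
            raise ValueError(f"tau_max must be positive, got {self.tau_max}")
        if not 0 < self.speed_fit_window <= 1:
            raise ValueError(
                f"speed_fit_window must lie in (0, 1], got {self.speed_fit_window}"
            )
        if self.stall_displacement <= 0:
            raise ValueError(
                f"stall_displacement must be positive, got {self.stall_displacement}"
            )

    def validate_against(self, params: DimensionlessParams) -> None:
        """Check grid resolution against the removal kernel width."""
        if self.dx > params.c / 5.0:
            raise ValueError(
                f"dx = {self.dx} under-resolves the removal kernel "
                f"(require dx <= c/5 = {params.c / 5.0:g})"
            )


@dataclass(frozen=True)
class RebindingParams:
    """Rates for ParA rebinding from the well-mixed buffer.

    ``k_r`` is the non-cooperative rate (binding to any free site); ``k_c``
    multiplies the locally bound ParA, favouring sites that already carry it.
    """

    k_r: float = 0.0
    k_c: float = 0.0

    def __post_init__(self) -> None:
        if self.k_r < 0:
            raise ValueError(f"k_r must be non-negative, got {self.k_r}")
        if self.k_c < 0:
            raise ValueError(f"k_c must be non-negative, got {self.k_c}")


@dataclass(frozen=True)
class DiffusionParams:
    """Surface diffusion coefficient for bound ParA (dimensionless)."""

    kappa: float = 0.0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError(f"kappa must be non-negative, got {self.kappa}")


def dedimensionalize(
    phys: PhysicalParams,
    *,
    domain_length: float | None = None,
    noise_amplitude: float = 0.0,
) -> DimensionlessParams:
    """Collapse dimensionful parameters into the model's two control knobs.

    Lengths are expressed in units of the bead radius ``R`` and times in units
    of ``1/gamma0``; the surviving parameters are ``A0 = F0*a0/(beta*R)`` and
    ``c = sigma_r/sigma_f``.

    Parameters
    ----------
    phys : PhysicalParams
        Dimensionful system parameters.
    domain_length : float, optional
        Physical surface length; converted to units of ``R``.  Defaults to the
        standard dimensionless length 70 when omitted.
    noise_amplitude : float, optional
        Physical half-width of the initial ParA noise; converted to units of
        ``a0``.
    """
    A0 = phys.F0 * phys.a0 / (phys.drag * phys.R)
    c = phys.sigma_r / phys.sigma_f
    L = 70.0 if domain_length is None else domain_length / phys.R
    return DimensionlessParams(A0=A0, c=c, L=L, delta_a=noise_amplitude / phys.a0)


def redimensionalize(
    dimless: DimensionlessParams,
    *,
    gamma0: float,
    R: float,
    a0: float,
    beta: float,
    sigma_f: float,
) -> PhysicalParams:
    """Inverse of :func:`dedimensionalize` given the scale factors.

    Returns a :class:`PhysicalParams` whose dedimensionalization reproduces
    ``dimless`` to machine precision.
    """
    return PhysicalParams(
        gamma0=gamma0,
        F0=dimless.A0 * beta * R / a0,
        R=R,
        sigma_r=dimless.c * sigma_f,
        sigma_f=sigma_f,
        a0=a0,
        beta=beta,
    )


@dataclass(frozen=True)
class ForceRangeEstimate:
    """Back-of-the-envelope force-range estimate from surface coverage."""

    required_parA: float  # one-significant-figure rounding of n_parB / ratio
    required_parA_raw: float  # unrounded quotient
    area_um2: float  # surface area covered by that much ParA
    sigma_f_um: float  # radius of the equivalent disc


def _round_one_sig_fig(x: float) -> float:
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, -exponent)


def estimate_force_range(
    n_parB: float,
    parB_to_parA_ratio: float,
    surface_density_per_um2: float,
) -> ForceRangeEstimate:
    """Estimate the ParA-ParB force range from bead and surface numbers.

    A bead carrying ``n_parB`` ParB must engage roughly ``n_parB / ratio``
    surface ParA to move.  At the measured surface density those molecules
    cover an area ``A``; the force range ``sigma_f`` is taken as the radius of
    the disc with that area, ``sqrt(A / pi)``.
    """
    if n_parB <= 0 or parB_to_parA_ratio <= 0:
        raise ValueError("n_parB and parB_to_parA_ratio must be positive")
    if surface_density_per_um2 <= 0:
        raise ValueError("surface density must be positive")
    raw = n_parB / parB_to_parA_ratio
    required = _round_one_sig_fig(raw)
    area = required / surface_density_per_um2
    sigma_f = math.sqrt(area / math.pi)
    return ForceRangeEstimate(
        required_parA=required,
        required_parA_raw=raw,
        area_um2=area,
        sigma_f_um=sigma_f,
    )
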
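"""Trajectory post-processing: lag/speed fits, regime laws and sweeps.

Bead speeds are obtained the way a bench scientist would read a displacement
trace: ignore the initial lag, then fit a line to displacement versus time.
On top of that sit the regime fits for rebinding runs — the undersaturated
acceleration law ``v(tau) = v0*L/(L - v0*tau)`` and the saturation boundary
``phi_stop(k_r) = 1/(k_r*dtau_stop) + 1`` — plus a generic replicated
parameter sweep.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .config import SimulationConfig
from .dynamics1d import Trajectory, simulate_1d
from .params import DiffusionParams, DimensionlessParams, RebindingParams

logger = logging.getLogger(__name__)

__all__ = [
    "SpeedFit",
    "AccelFit",
    "PhiStopFit",
    "fit_speed",
    "fit_acceleration",
    "find_phi_stop",
    "fit_delta_tau",
    "sweep",
]


@dataclass(frozen=True)
class SpeedFit:
    """Steady speed and motion-onset time from a displacement trace."""

    lag_time: float
    speed: float
    r_squared: float
    stalled: bool = False


@dataclass(frozen=True)
class AccelFit:
    """Fit of the undersaturated acceleration law ``v0*L/(L - v0*tau)``."""

    v0: float
    L: float
    r_squared: float


@dataclass(frozen=True)
class PhiStopFit:
    """Fit of the stall boundary ``phi_stop = 1/(k_r*delta_tau) + 1``."""

    phi_stop_values: dict
    delta_tau: float
    r_squared: float


def _displacement_series(traj: Trajectory) -> np.ndarray:
    dx = traj.positions - traj.positions[0]
    if traj.positions_y is not None:
        dy = traj.positions_y - traj.positions_y[0]
        return np.hypot(dx, dy)
    return np.abs(dx)


def _speed_series(traj: Trajectory) -> np.ndarray:
    if traj.speeds is not None and len(traj.speeds) == len(traj.times):
        v = np.abs(traj.speeds)
        if traj.speeds_y is not None:
            v = np.hypot(traj.speeds, traj.speeds_y)
        return v
    return np.abs(np.gradient(_displacement_series(traj), traj.times))


def fit_speed(
    traj: Trajectory,
    *,
    lag_threshold: float = 0.1,
    tail_window: float = 0.5,
    stall_displacement: float = 1.0,
) -> SpeedFit:
    """Linear fit to displacement vs time, ignoring the initial lag.

    The lag is the first time the instantaneous speed exceeds
    ``lag_threshold`` times the mean speed over the trailing ``tail_window``
    fraction of the run; the slope is fit over that tail (restricted to
    post-lag samples).  A bead that never travels ``stall_displacement`` is
    reported stalled with zero speed and ``lag_time = tau_max``.
    """
    if len(traj.times) < 100:
        raise ValueError(f"trajectory too short to fit ({len(traj.times)} samples)")
    disp = _displacement_series(traj)
    speeds = _speed_series(traj)
    n = len(traj.times)
    tail_start = int(n * (1.0 - tail_window))
    tail_mean = float(np.mean(speeds[tail_start:]))
    if disp[-1] < stall_displacement or tail_mean <= 0.0:
        return SpeedFit(lag_time=float(traj.times[-1]), speed=0.0, r_squared=0.0, stalled=True)
    moving = np.nonzero(speeds > lag_threshold * tail_mean)[0]
    lag_idx = int(moving[0]) if moving.size else tail_start
    start = max(lag_idx, tail_start)
    if n - start < 10:
        start = tail_start
    t = traj.times[start:]
    y = disp[start:]
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return SpeedFit(
        lag_time=float(traj.times[lag_idx]),
        speed=float(abs(slope)),
        r_squared=r2,
    )


def fit_acceleration(
    traj: Trajectory, L: float, *, onset_threshold: float = 0.5
) -> AccelFit:
    """Single-parameter fit of the speed series to ``v0*L/(L - v0*tau)``.

    Valid in the undersaturated regime (phi << 1), where the wavefront keeps
    growing and the bead accelerates persistently.  The law presumes motion
    is already established, so the clock is re-zeroed where the speed first
    reaches ``onset_threshold`` times its tail mean (a series accelerating
    from the first sample is used as-is); data past the pole ``v0*tau -> L``
    are truncated with a warning.
    """
    speeds = _speed_series(traj)
    tail_mean = float(np.mean(speeds[len(speeds) // 2 :]))
    if tail_mean <= 0:
        raise ValueError("bead never moved; no acceleration to fit")
    moving = np.nonzero(speeds > onset_threshold * tail_mean)[0]
    start = int(moving[0]) if moving.size else 0
    t = traj.times[start:] - traj.times[start]
    v = speeds[start:]
    if len(t) < 4:
        raise ValueError("too few moving samples to fit the acceleration law")

    v0_init = max(float(v[0]), 1e-6)

    def residuals(p: np.ndarray) -> np.ndarray:
        v0 = p[0]
        denom = L - v0 * t
        bad = denom <= 0
        if np.any(bad):
            denom = np.where(bad, np.nan, denom)
        model = v0 * L / denom
        return np.nan_to_num(model - v, nan=1e6)

    sol = least_squares(residuals, x0=[v0_init], bounds=(1e-12, np.inf))
    v0 = float(sol.x[0])
    if v0 * t[-1] >= L:
        cut = np.searchsorted(v0 * t, L * 0.999)
        warnings.warn(
            "acceleration law diverges inside the data (v0*tau -> L); "
            f"truncating fit to the first {cut} samples",
            stacklevel=2,
        )
        t, v = t[:cut], v[:cut]
        sol = least_squares(residuals, x0=[v0], bounds=(1e-12, np.inf))
        v0 = float(sol.x[0])
    model = v0 * L / (L - v0 * t)
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - float(np.sum((model - v) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return AccelFit(v0=v0, L=L, r_squared=r2)


def _run_stalls(config: SimulationConfig, phi: float) -> bool:
    stall = config.numerics.stall_displacement
    cfg = config.with_(mode="rebinding", phi=phi, stop_displacement=stall * 1.5)
    traj = simulate_1d(cfg)
    return traj.displacement < stall


def find_phi_stop(
    k_r: float,
    k_c: float,
    base_config: SimulationConfig,
    *,
    phi_hi: float = 2.0,
    tol: float = 0.01,
) -> float | None:
    """Saturation ratio above which the bead never commences motion.

    Bisects on phi in (1, phi_hi]: a run counts as stalled when its total
    displacement stays below ``stall_displacement`` (default one bead
    radius) within ``tau_max``.  Returns None (open boundary) if even
    ``phi_hi`` does not stall the bead.
    """
    if k_r <= 0 and k_c <= 0:
        raise ValueError("phi_stop needs a rebinding channel (k_r > 0 or k_c > 0)")
    config = base_config.with_(rebinding=RebindingParams(k_r=k_r, k_c=k_c))
    if not _run_stalls(config, phi_hi):
        logger.info("no stall up to phi_hi=%s for k_r=%s k_c=%s", phi_hi, k_r, k_c)
        return None
    lo, hi = 1.0, phi_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _run_stalls(config, mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def fit_delta_tau(phi_stop_curve: dict) -> PhiStopFit:
    """Least-squares fit of ``phi_stop(k_r) = 1/(k_r*delta_tau) + 1``.

    The form is linear in ``1/delta_tau`` against ``1/k_r``, so the fit has
    a closed-form solution.  A non-decreasing curve contradicts the law and
    triggers a model-mismatch warning.
    """
    items = sorted((float(k), float(p)) for k, p in phi_stop_curve.items())
    if len(items) < 4:
        raise ValueError("need phi_stop at >= 4 rebinding rates")
    k_r = np.array([k for k, _ in items])
    phi = np.array([p for _, p in items])
    if np.any(np.diff(phi) >= 0):
        warnings.warn(
            "phi_stop(k_r) is not strictly decreasing; the 1/(k_r*delta_tau)+1 "
            "law may not apply",
            stacklevel=2,
        )
    x = 1.0 / k_r
    y = phi - 1.0
    inv_delta_tau = float(np.dot(x, y) / np.dot(x, x))
    if inv_delta_tau <= 0:
        raise ValueError("fitted delta_tau is non-positive; model mismatch")
    model = inv_delta_tau * x + 1.0
    ss_tot = float(np.sum((phi - phi.mean()) ** 2))
    r2 = 1.0 - float(np.sum((model - phi) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return PhiStopFit(
        phi_stop_values=dict(items), delta_tau=1.0 / inv_delta_tau, r_squared=r2
    )


_SWEEPABLE = ("A0", "c", "delta_a", "k_r", "k_c", "phi", "kappa")


def _config_with_value(base: SimulationConfig, parameter: str, value: float) -> SimulationConfig:
    if parameter in ("A0", "c", "delta_a"):
        p = base.params
        kwargs = {"A0": p.A0, "c": p.c, "L": p.L, "delta_a": p.delta_a}
        kwargs[parameter] = value
        return base.with_(params=DimensionlessParams(**kwargs))
    if parameter in ("k_r", "k_c"):
        r = base.rebinding
        kwargs = {"k_r": r.k_r, "k_c": r.k_c}
        kwargs[parameter] = value
        return base.with_(rebinding=RebindingParams(**kwargs))
    if parameter == "phi":
        return base.with_(phi=value)
    if parameter == "kappa":
        return base.with_(diffusion=DiffusionParams(kappa=value))
    raise ValueError(f"parameter must be one of {_SWEEPABLE}, got {parameter!r}")


def _replicate_seed(base_seed: int, replicate: int) -> int:
    return int(np.random.SeedSequence((base_seed, replicate)).generate_state(1)[0] % 2**31)


def sweep(
    parameter: str,
    values,
    base_config: SimulationConfig,
    n_replicates: int = 20,
    seeds=None,
) -> pd.DataFrame:
    """Replicated speed measurements across one parameter.

    Each (value, replicate) pair runs a fresh simulation with its own seed
    derived from ``(base seed, replicate index)``, fits the steady speed, and
    the table reports mean +/- standard error per value.  Failed replicates
    are logged and excluded, not fatal.
    """
    rows = []
    numerics = base_config.numerics
    for value in values:
        cfg_v = _config_with_value(base_config, parameter, float(value))
        fits = []
        for rep in range(n_replicates):
            seed = seeds[rep] if seeds is not None else _replicate_seed(numerics.seed, rep)
            from dataclasses import replace as _replace

            cfg = cfg_v.with_(numerics=_replace(numerics, seed=seed))
            try:
                traj = simulate_1d(cfg)
                fit = fit_speed(
                    traj,
                    tail_window=numerics.speed_fit_window,
                    stall_displacement=numerics.stall_displacement,
                )
                fits.append(fit.speed)
            except Exception:  # noqa: BLE001 - record and continue
                logger.exception(
                    "replicate %d failed for %s=%s", rep, parameter, value
                )
        arr = np.asarray(fits)
        rows.append(
            {
                "value": float(value),
                "mean_speed": float(arr.mean()) if arr.size else np.nan,
                "std_speed": float(arr.std(ddof=1)) if arr.size > 1 else np.nan,
                "stderr": float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else np.nan,
                "n": int(arr.size),
            }
        )
    return pd.DataFrame(rows)
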
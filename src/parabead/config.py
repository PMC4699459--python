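"""Run configuration: a flat key-value file mapped onto the model types.

The on-disk format is YAML restricted to a flat mapping of scalars (plus an
optional list of snapshot times), so configs stay diff-able and serializable
to delimited text.  Unknown keys and invariant violations are reported
together in a single itemized error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .params import (
    DiffusionParams,
    DimensionlessParams,
    NumericsConfig,
    RebindingParams,
)

__all__ = ["SimulationConfig", "load_config", "save_config", "config_to_dict"]

_MODES = ("base", "rebinding", "diffusion")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one simulation run."""

    mode: str = "base"
    params: DimensionlessParams = field(default_factory=DimensionlessParams)
    numerics: NumericsConfig = field(default_factory=NumericsConfig)
    rebinding: RebindingParams = field(default_factory=RebindingParams)
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    mean_a: float = 1.0  # mean initial surface ParA (base mode)
    D0: float = 1.0  # mean binding-site concentration
    delta_d: float = 0.05  # binding-site noise half-width
    phi: float = 0.5  # buffer saturation ratio A_s / D0
    snapshot_taus: tuple = ()
    stop_displacement: float | None = None
    ndim: int = 1

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.mean_a <= 0:
            raise ValueError(f"mean_a must be positive, got {self.mean_a}")
        if self.params.delta_a > self.mean_a:
            raise ValueError("delta_a exceeds mean_a: negative ParA would result")
        if self.D0 <= 0:
            raise ValueError(f"D0 must be positive, got {self.D0}")
        if not 0 <= self.delta_d <= self.D0:
            raise ValueError(f"delta_d must lie in [0, D0], got {self.delta_d}")
        if self.phi <= 0:
            raise ValueError(f"phi must be positive, got {self.phi}")
        if self.ndim not in (1, 2):
            raise ValueError(f"ndim must be 1 or 2, got {self.ndim}")

    def with_(self, **kwargs) -> "SimulationConfig":
        """Copy with replaced top-level fields (convenience for sweeps)."""
        return replace(self, **kwargs)


_KEY_MAP = {
    # flat key -> (section, attribute)
    "A0": ("params", "A0"),
    "c": ("params", "c"),
    "L": ("params", "L"),
    "delta_a": ("params", "delta_a"),
    "dx": ("numerics", "dx"),
    "dtau": ("numerics", "dtau"),
    "tau_max": ("numerics", "tau_max"),
    "seed": ("numerics", "seed"),
    "speed_fit_window": ("numerics", "speed_fit_window"),
    "stall_displacement": ("numerics", "stall_displacement"),
    "k_r": ("rebinding", "k_r"),
    "k_c": ("rebinding", "k_c"),
    "kappa": ("diffusion", "kappa"),
}
_TOP_KEYS = (
    "mode",
    "mean_a",
    "D0",
    "delta_d",
    "phi",
    "snapshot_taus",
    "stop_displacement",
    "ndim",
)


def config_to_dict(config: SimulationConfig) -> dict:
    """Flatten a config to the on-disk key-value form."""
    out: dict = {"mode": config.mode, "ndim": config.ndim}
    for key, (section, attr) in _KEY_MAP.items():
        out[key] = getattr(getattr(config, section), attr)
    out.update(
        mean_a=config.mean_a,
        D0=config.D0,
        delta_d=config.delta_d,
        phi=config.phi,
        snapshot_taus=list(config.snapshot_taus),
        stop_displacement=config.stop_displacement,
    )
    return out


def _config_from_dict(raw: dict) -> SimulationConfig:
    errors: list[str] = []
    sections: dict[str, dict] = {"params": {}, "numerics": {}, "rebinding": {}, "diffusion": {}}
    top: dict = {}
    for key, value in raw.items():
        if key in _KEY_MAP:
            section, attr = _KEY_MAP[key]
            sections[section][attr] = value
        elif key in _TOP_KEYS:
            top[key] = value
        else:
            errors.append(f"unknown key: {key!r}")
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    if top.get("ndim") == 2:
        # desk-scale 2D defaults: a smaller square domain than the 1D surface
        sections["params"].setdefault("L", 20.0)
        sections["numerics"].setdefault("dx", 0.05)
    if "snapshot_taus" in top and top["snapshot_taus"] is not None:
        top["snapshot_taus"] = tuple(top["snapshot_taus"])
    parts = {}
    builders = {
        "params": DimensionlessParams,
        "numerics": NumericsConfig,
        "rebinding": RebindingParams,
        "diffusion": DiffusionParams,
    }
    for name, cls in builders.items():
        try:
            parts[name] = cls(**sections[name])
        except (TypeError, ValueError) as exc:
            errors.append(f"{name}: {exc}")
    config = None
    if not errors:
        try:
            config = SimulationConfig(**parts, **top)
            config.numerics.validate_against(config.params)
        except ValueError as exc:
            errors.append(str(exc))
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return config


def load_config(path: str | Path) -> SimulationConfig:
    """Read and validate a flat YAML config; defaults fill missing keys.

    An empty file yields the full default configuration (base 1D mode,
    L = 70, dx = 0.02, dtau = 0.01).
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a flat key-value mapping")
    return _config_from_dict(raw)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    """Write a config as flat YAML; ``load_config`` round-trips it exactly."""
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=True))
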
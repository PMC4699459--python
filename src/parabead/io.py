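"""Run outputs: delimited-text trajectories, field snapshots, manifests."""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig, config_to_dict
from .dynamics1d import Trajectory

__all__ = ["RunManifest", "write_outputs", "trajectory_frame"]


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit, plus its inventory."""

    config: dict
    seed: int
    code_version: str
    started: str
    finished: str
    outputs: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    """Trajectory as a tidy table (tau, x_p, v[, y_p, v_y][, a_b])."""
    data = {"tau": traj.times, "x_p": traj.positions}
    if traj.positions_y is not None:
        data["y_p"] = traj.positions_y
    data["v"] = traj.speeds
    if traj.speeds_y is not None:
        data["v_y"] = traj.speeds_y
    if traj.buffer is not None:
        data["a_b"] = traj.buffer
    return pd.DataFrame(data)


def write_outputs(
    traj: Trajectory,
    config: SimulationConfig,
    out_dir: str | Path,
    *,
    started: str | None = None,
) -> RunManifest:
    """Write trajectory CSV, snapshot files and a JSON manifest.

    File naming is deterministic, so identical config + seed reproduce
    byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inventory: list[str] = []

    traj_path = out / "trajectory.csv"
    trajectory_frame(traj).to_csv(traj_path, index=False, float_format="%.12g")
    inventory.append(traj_path.name)

    for tau, values in sorted(traj.snapshots.items()):
        name = f"snapshot_tau{tau:g}.csv"
        path = out / name
        if values.ndim == 1:
            frame = pd.DataFrame({"x": traj.grid, "a": values})
            frame.to_csv(path, index=False, float_format="%.12g")
        else:
            np.savetxt(path, values, delimiter=",", fmt="%.12g")
        inventory.append(name)

    now = datetime.datetime.now(datetime.timezone.utc).isoformat()
    manifest = RunManifest(
        config=config_to_dict(config),
        seed=config.numerics.seed,
        code_version=__version__,
        started=started or now,
        finished=now,
        outputs=inventory,
    )
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
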
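"""Configuration files and result persistence.

Configs are flat YAML key/value files whose keys must be a subset of the
Config fields; unknown keys are rejected with the offending name.
Trajectories are CSV (one row per sample, fixed column order); ensemble
summaries and manifests are JSON with full-precision floats.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from .domain_model import CONFIG_KEYS, Config
from .runner import TRAJECTORY_COLUMNS, Trajectory

PathLike = Union[str, Path]


def load_config(path: PathLike) -> Config:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must hold a key/value mapping")
    unknown = sorted(set(raw) - set(CONFIG_KEYS))
    if unknown:
        raise ValueError(f"unknown config key(s) in {path}: {', '.join(unknown)}")
    return Config(**raw)


def dump_config(config: Config, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def write_trajectory(trajectory: Trajectory, path: PathLike) -> None:
    trajectory.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def read_trajectory_frame(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory file {path} missing column(s): {missing}")
    return df


def write_summary(summary: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def write_ensemble(
    trajectories: list[Trajectory], out_dir: PathLike
) -> dict:
    """Write one trajectory CSV per replicate plus a manifest of digests."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"replicates": []}
    for traj in trajectories:
        name = f"trajectory_seed{traj.seed}.csv"
        write_trajectory(traj, out / name)
        manifest["replicates"].append(
            {
                "seed": traj.seed,
                "file": name,
                "digest": traj.digest(),
                "goats_removed_total": traj.goats_removed_total,
                "conservation_residual": traj.conservation_residual,
            }
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
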
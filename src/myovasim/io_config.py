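"""Configuration documents, file formats and batch orchestration.

Configs are YAML/JSON mappings validated against :class:`SimConfig` and
:class:`MotorParams` (unknown keys are rejected, units are fixed: nm, s,
pN).  Trajectories, outcome tables, force traces and localization clouds
travel as CSV; summaries, mixtures and run manifests as JSON.  Batches
derive child seeds from the master seed with a counter-based SeedSequence
split, so they are reproducible and order-independent.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .actin_geometry import interacts
from .motor_mechanics import MotorParams
from .transport_simulator import (
    OutcomeRecord,
    SimConfig,
    Trajectory,
    make_intersection,
    run_intersection,
)

__all__ = [
    "load_config",
    "save_config",
    "config_to_dict",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_outcomes_csv",
    "read_outcomes_csv",
    "write_force_csv",
    "read_force_csv",
    "child_seeds",
    "batch_outcomes",
    "RunManifest",
]

_MOTOR_FIELDS = {f.name for f in dataclasses.fields(MotorParams)}
_SIM_FIELDS = {f.name for f in dataclasses.fields(SimConfig)}


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    if not isinstance(d.get("geometry"), str):
        d["geometry"] = "single_filament"  # intersections carry their own doc
    return d


def load_config(source: str | Path | dict) -> SimConfig:
    """Build a validated :class:`SimConfig` from a YAML/JSON document or a
    mapping.  Defaults apply to missing keys; unknown keys raise; a seed is
    required (reproducibility is not optional)."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = dict(source)
    doc = doc or {}
    if not isinstance(doc, dict):
        raise ValueError("config document must be a mapping")
    unknown = set(doc) - _SIM_FIELDS - {"motor"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    motor_doc = doc.pop("motor", {}) or {}
    unknown_m = set(motor_doc) - _MOTOR_FIELDS
    if unknown_m:
        raise ValueError(f"unknown motor keys: {sorted(unknown_m)}")
    if "seed" not in doc:
        raise ValueError("config requires a seed")
    motor = MotorParams(**motor_doc)
    return SimConfig(motor=motor, **doc)


def save_config(config: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def write_trajectory_csv(trajectory: Trajectory, path: str | Path) -> None:
    """Trajectory as CSV: t_s, x_nm, y_nm, z_nm and per-filament engaged
    counts (engaged_0 = original filament)."""
    df = pd.DataFrame({
        "t_s": trajectory.times,
        "x_nm": trajectory.centers[:, 0],
        "y_nm": trajectory.centers[:, 1],
        "z_nm": trajectory.centers[:, 2],
    })
    for fid in range(trajectory.engaged_per_filament.shape[1]):
        df[f"engaged_{fid}"] = trajectory.engaged_per_filament[:, fid]
    if trajectory.forces is not None:
        df["force_pN"] = trajectory.forces
    df.to_csv(path, index=False)


def read_trajectory_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a trajectory CSV back as ``(times, centers)``."""
    df = pd.read_csv(path)
    return df["t_s"].to_numpy(), df[["x_nm", "y_nm", "z_nm"]].to_numpy()


def write_outcomes_csv(records: list[OutcomeRecord], path: str | Path) -> None:
    pd.DataFrame([{
        "alpha_deg": r.alpha, "d_nm": r.d, "outcome": r.outcome,
        "dwell_s": r.dwell_at_intersection, "reached": r.reached,
    } for r in records]).to_csv(path, index=False)


def read_outcomes_csv(path: str | Path) -> list[OutcomeRecord]:
    df = pd.read_csv(path)
    return [OutcomeRecord(alpha=float(r.alpha_deg), d=float(r.d_nm),
                          outcome=str(r.outcome),
                          dwell_at_intersection=float(r.dwell_s),
                          reached=bool(r.reached))
            for r in df.itertuples()]


def write_force_csv(times: np.ndarray, force: np.ndarray,
                    path: str | Path) -> None:
    pd.DataFrame({"t_s": times, "force_pN": force}).to_csv(path, index=False)


def read_force_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["t_s"].to_numpy(), df["force_pN"].to_numpy()


def child_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic, collision-resistant child seeds via a counter-based
    SeedSequence split of the master seed (kept below 2**31)."""
    ss = np.random.SeedSequence(int(master_seed))
    return [int(s) % (2 ** 31 - 1)
            for s in ss.generate_state(n, dtype=np.uint64)]


@dataclasses.dataclass
class RunManifest:
    """Provenance record written next to every batch output."""

    seed: int
    n_runs: int
    package_version: str
    config: dict
    summary: dict

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def batch_outcomes(
    n_runs: int,
    seed: int,
    d_range: tuple[float, float] = (50.0, 250.0),
    max_time: float = 25.0,
    config_overrides: dict | None = None,
    randomize_polarity: bool = True,
) -> tuple[list[OutcomeRecord], dict]:
    """Run a seeded batch of intersection transits over the (alpha, d) grid
    and summarize directional outcomes.

    Separations are uniform on ``d_range``; initial binding azimuths are
    uniform on [0, 360) (so measured approach angles are too); the
    intersecting filament's polarity is coin-flipped per run unless
    ``randomize_polarity`` is false.  The summary's fractions are over
    records that reached the crossing with an interacting measured
    geometry, with Wilson binomial confidence intervals; fractions sum
    to 1.

    Returns ``(all_records, summary)``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    seeds = child_seeds(seed, n_runs)
    overrides = dict(config_overrides or {})
    motor_doc = overrides.pop("motor", None)
    records: list[OutcomeRecord] = []
    for i in range(n_runs):
        d = float(rng.uniform(*d_range))
        pol = (1 if rng.random() < 0.5 else -1) if randomize_polarity else 1
        inter = make_intersection(d, pol)
        kwargs: dict[str, Any] = {"seed": seeds[i], "geometry": inter,
                                  "max_time": max_time}
        kwargs.update(overrides)
        if motor_doc is not None:
            kwargs["motor"] = MotorParams(**motor_doc)
        _, rec = run_intersection(SimConfig(**kwargs))
        records.append(rec)
    kept = [r for r in records
            if r.reached and interacts(r.alpha, r.d)]
    n = len(kept)
    counts = {
        "straight": sum(1 for r in kept if r.outcome == "straight"),
        "turn_left": sum(1 for r in kept if r.outcome == "turn_left"),
        "turn_right": sum(1 for r in kept if r.outcome == "turn_right"),
        "terminate": sum(1 for r in kept if r.outcome == "terminate"),
    }

    def wilson(k: int, n: int, z: float = 1.96) -> tuple[float, float]:
        if n == 0:
            return (0.0, 1.0)
        p = k / n
        denom = 1 + z * z / n
        centre = (p + z * z / (2 * n)) / denom
        hw = z * ((p * (1 - p) / n + z * z / (4 * n * n)) ** 0.5) / denom
        return (max(centre - hw, 0.0), min(centre + hw, 1.0))

    summary = {
        "n_runs": n_runs,
        "n_reached": sum(1 for r in records if r.reached),
        "n_interacting": n,
        "counts": counts,
        "fractions": {k: (v / n if n else 0.0) for k, v in counts.items()},
        "ci95": {k: wilson(v, n) for k, v in counts.items()},
    }
    return records, summary
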
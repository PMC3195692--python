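"""Population-level simulation of stretch-induced cell reorientation.

Integrates many independent cells through the cyclic-stretch protocol,
applies pharmacological scenarios as parameter switches, and emits
orientation/circularity trajectories plus per-snapshot angle samples.

Scenarios
---------
control
    Parameters pass through unchanged.
mt_disrupted
    Microtubule polymerization blocked (nocodazole / colchicine class):
    the MT attachment probability is forced to zero and initial MT cohorts
    are empty, so K_MT = 0 for the whole run.
mt_stabilized
    Microtubule dynamics frozen (paclitaxel class): MT attachment and
    detachment probabilities are both zero and the initial MT cohorts are
    filled to capacity, so the MT count at every FA is constant in time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from . import _engine
from .fiber_mechanics import MechanicsParams
from .orientation_stats import AngleSample
from .strain_field import StrainParams

__all__ = [
    "SimConfig",
    "CellTrajectory",
    "PopulationTrajectory",
    "apply_scenario",
    "simulate_cell",
    "simulate_population",
    "load_config",
    "write_manifest",
]

Scenario = Literal["control", "mt_disrupted", "mt_stabilized"]


class SimConfig(BaseModel):
    """Full run configuration (serializable as YAML or JSON).

    ``duration`` and ``snapshot_times`` are in hours; the stretch
    frequency inside ``strain`` is in cycles per minute.  Unknown keys are
    rejected.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    strain: StrainParams = StrainParams()
    mechanics: MechanicsParams = MechanicsParams()
    n_cells: int = 200
    n_fa: int = 100
    duration: float = 2.0
    substeps_per_cycle: int = 4
    scenario: Scenario = "control"
    seed: int = 0
    snapshot_times: tuple = (0.0, 0.5, 1.0, 2.0)
    fa_spread_deg: float = 5.0

    @field_validator("n_cells")
    @classmethod
    def _cells(cls, v):
        if v < 1:
            raise ValueError("n_cells must be >= 1")
        return v

    @field_validator("n_fa")
    @classmethod
    def _nfa(cls, v):
        if v < 10:
            raise ValueError("n_fa must be >= 10")
        return v

    @field_validator("duration")
    @classmethod
    def _dur(cls, v):
        if v < 0:
            raise ValueError("duration must be >= 0")
        return v

    @field_validator("substeps_per_cycle")
    @classmethod
    def _sub(cls, v):
        if v < 1:
            raise ValueError("substeps_per_cycle must be >= 1")
        return v

    @field_validator("fa_spread_deg")
    @classmethod
    def _spread(cls, v):
        if v <= 0:
            raise ValueError("fa_spread_deg must be positive")
        return v

    @model_validator(mode="after")
    def _snapshots_valid(self):
        times = tuple(float(t) for t in self.snapshot_times)
        if len(times) == 0:
            raise ValueError("snapshot_times must not be empty")
        if any(t < 0 or t > self.duration for t in times):
            raise ValueError("snapshot_times must lie within [0, duration]")
        if list(times) != sorted(times) or len(set(times)) != len(times):
            raise ValueError("snapshot_times must be strictly increasing")
        object.__setattr__(self, "__dict__", {**self.__dict__, "snapshot_times": times})
        return self


def apply_scenario(config: SimConfig) -> MechanicsParams:
    """Mechanics parameters after applying the pharmacological scenario."""
    m = config.mechanics
    if config.scenario == "control":
        return m
    if config.scenario == "mt_disrupted":
        return m.model_copy(update={"mt_attach_slope": 0.0})
    if config.scenario == "mt_stabilized":
        return m.model_copy(update={"mt_attach_slope": 0.0, "mt_detach_enabled": False})
    raise ValueError(f"unknown scenario: {config.scenario!r}")


def _mt_full(config: SimConfig) -> bool:
    return config.scenario == "mt_stabilized"


def _cell_rng(seed: int, cell_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(cell_index,))
    return np.random.default_rng(ss)


@dataclass
class CellTrajectory:
    """Orientation/circularity time series of a single cell."""

    times_h: np.ndarray
    theta: np.ndarray  # degrees, folded to [0, 90]
    cv: np.ndarray
    final_fa_angles: np.ndarray  # degrees in [0, 180)


@dataclass
class PopulationTrajectory:
    """Per-cell orientation series plus per-snapshot angle samples."""

    times_h: np.ndarray
    theta: np.ndarray  # (n_times, n_cells)
    cv: np.ndarray  # (n_times, n_cells)
    final_fa_angles: np.ndarray  # (n_cells, n_fa)
    config: SimConfig | None = None

    @property
    def n_cells(self) -> int:
        return self.theta.shape[1]

    def angle_sample(self, time_h: float, label: str | None = None) -> AngleSample:
        """Folded cell orientations at one snapshot, as an AngleSample."""
        idx = np.flatnonzero(np.isclose(self.times_h, time_h))
        if idx.size == 0:
            raise ValueError(f"no snapshot at t = {time_h} h (have {self.times_h})")
        if label is None:
            label = f"t={time_h}h"
        return AngleSample(self.theta[idx[0]].copy(), label)

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "cell_id": np.tile(np.arange(self.n_cells), self.times_h.size),
            "time_h": np.repeat(self.times_h, self.n_cells),
            "theta_deg": self.theta.ravel(),
            "cv": self.cv.ravel(),
        }
        return pd.DataFrame(rows)

    def write_trajectories_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_angle_samples_csv(self, path) -> None:
        frames = []
        for t in self.times_h:
            s = self.angle_sample(t)
            frames.append(pd.DataFrame({"label": s.label, "angle_deg": s.angles}))
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def simulate_cell(
    theta0: float,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    cell_index: int = 0,
) -> CellTrajectory:
    """Simulate one cell starting at folded orientation ``theta0``.

    Deterministic given ``(config.seed, cell_index)``; a population run is
    exactly the collection of its single-cell runs.
    """
    if not 0.0 <= theta0 <= 90.0:
        raise ValueError("theta0 must lie in [0, 90]")
    if rng is None:
        rng = _cell_rng(config.seed, cell_index)
    params = apply_scenario(config)
    times, theta, cv, alpha = _engine.run_population(
        [theta0], config.strain, params,
        n_fa=config.n_fa, duration_h=config.duration,
        substeps_per_cycle=config.substeps_per_cycle,
        snapshot_times_h=config.snapshot_times,
        fa_spread_deg=config.fa_spread_deg,
        mt_full=_mt_full(config), rngs=[rng],
    )
    return CellTrajectory(times, theta[:, 0], cv[:, 0], alpha[0])


def simulate_population(initial_angles, config: SimConfig) -> PopulationTrajectory:
    """Simulate ``n_cells`` cells with independent per-cell substreams.

    ``initial_angles`` are folded orientations in [0, 90], one per cell;
    the result is fully reproducible from ``(config, initial_angles)`` and
    independent of any batching order.
    """
    initial_angles = np.asarray(initial_angles, dtype=float)
    if initial_angles.size != config.n_cells:
        raise ValueError(
            f"len(initial_angles) = {initial_angles.size} != n_cells = {config.n_cells}")
    if initial_angles.size and (initial_angles.min() < 0 or initial_angles.max() > 90):
        raise ValueError("initial angles must lie in [0, 90]")
    params = apply_scenario(config)
    rngs = [_cell_rng(config.seed, i) for i in range(config.n_cells)]
    times, theta, cv, alpha = _engine.run_population(
        initial_angles, config.strain, params,
        n_fa=config.n_fa, duration_h=config.duration,
        substeps_per_cycle=config.substeps_per_cycle,
        snapshot_times_h=config.snapshot_times,
        fa_spread_deg=config.fa_spread_deg,
        mt_full=_mt_full(config), rngs=rngs,
    )
    return PopulationTrajectory(times, theta, cv, alpha, config=config)


def load_config(path) -> SimConfig:
    """Load and validate a YAML or JSON run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError("run config must be a mapping")
    return SimConfig(**data)


def write_manifest(config: SimConfig, path) -> None:
    """Echo the validated config, seed and code version next to run outputs."""
    from . import __version__

    manifest = {
        "config": json.loads(config.model_dump_json()),
        "seed": config.seed,
        "version": __version__,
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
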
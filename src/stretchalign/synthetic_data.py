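"""Synthetic cell-angle populations emulating the measured inputs.

The experiments this package emulates report unstretched cell
orientations "distributed randomly" on [0, 90] degrees (mean 43, SD 24
over >100 cells), measured in 4-5 independent replicates of at least 100
cells each.  Two generator modes are provided:

* ``uniform`` (default): i.i.d. uniform on [0, 90] -- the minimal reading
  of "random" (mean 45, SD ~26);
* ``beta``: a scaled beta distribution whose first two moments match the
  requested targets exactly, for emulating the printed 43/24 moments.

Angles are rounded to whole degrees before output, matching the
integer-degree measurement convention of :mod:`stretchalign.orientation_stats`.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator

from .orientation_stats import AngleSample

__all__ = ["GeneratorSpec", "generate_unstretched_angles", "generate_replicates"]

_MIN_CELLS = 100  # the emulated experiments measured >100 cells per replicate


class GeneratorSpec(BaseModel):
    """Specification of a synthetic unstretched-angle population."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    n_cells: int = 120
    n_replicates: int = 5
    distribution: Literal["uniform", "beta"] = "uniform"
    target_mean: float = 43.0
    target_sd: float = 24.0
    seed: int = 0

    @field_validator("n_replicates")
    @classmethod
    def _reps(cls, v):
        if v < 1:
            raise ValueError("n_replicates must be >= 1")
        return v

    @field_validator("target_mean")
    @classmethod
    def _mean(cls, v):
        if not 0.0 < v < 90.0:
            raise ValueError("target_mean must lie in (0, 90)")
        return v

    @field_validator("target_sd")
    @classmethod
    def _sd(cls, v):
        if v <= 0:
            raise ValueError("target_sd must be positive")
        return v


def _beta_shape(spec: GeneratorSpec) -> tuple[float, float]:
    m = spec.target_mean / 90.0
    v = (spec.target_sd / 90.0) ** 2
    k = m * (1.0 - m) / v - 1.0
    a, b = m * k, (1.0 - m) * k
    if a <= 1 or b <= 1:
        # a, b <= 1 would put the mass at the edges (bimodal/degenerate);
        # the emulated populations are unimodal spreads on [0, 90]
        raise ValueError(
            f"moment targets (mean={spec.target_mean}, sd={spec.target_sd}) are "
            "not attainable by a unimodal beta distribution on [0, 90]")
    return a, b


def generate_unstretched_angles(
    spec: GeneratorSpec,
    rng: np.random.Generator | None = None,
    label: str = "unstretched",
) -> AngleSample:
    """Draw one unstretched-population angle sample, rounded to whole degrees.

    Deterministic per ``(spec, seed)`` when ``rng`` is not supplied.
    """
    if spec.n_cells < _MIN_CELLS:
        raise ValueError(f"n_cells must be >= {_MIN_CELLS} (per-replicate sample size)")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.distribution == "uniform":
        raw = rng.random(spec.n_cells) * 90.0
    else:
        a, b = _beta_shape(spec)
        raw = rng.beta(a, b, spec.n_cells) * 90.0
    angles = np.floor(raw + 0.5)  # integer-degree measurement convention
    return AngleSample(angles, label)


def generate_replicates(spec: GeneratorSpec) -> list:
    """Independent replicate samples r1..rk from per-replicate substreams."""
    out = []
    for r in range(spec.n_replicates):
        ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(r,))
        rng = np.random.default_rng(ss)
        out.append(generate_unstretched_angles(spec, rng=rng, label=f"r{r + 1}"))
    return out
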
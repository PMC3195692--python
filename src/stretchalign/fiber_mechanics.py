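"""Stochastic stress-fiber / microtubule cohorts anchored at a focal adhesion.

Each focal adhesion (FA) couples the substrate to the cytoskeleton through a
stiff linear spring K_FA in series with two parallel fiber populations: actin
stress fibers (SF, per-fiber stiffness 2.6 in relative units) and microtubules
(MT, 1.7).  Fibers attach and detach stochastically:

* SFs attach at a constant probability per free slot per stretch cycle.
* MTs attach at a rate proportional to the mean absolute strain currently
  carried by the SFs at the same FA (strain-regulated polymerization toward
  strained adhesions).
* Any fiber detaches with probability P_d = 1 - exp(-x^2 / 0.2) per update,
  where x is the strain on that fiber.  This corresponds to a rupture
  threshold that is normally distributed with zero mean and 10% variance,
  and is symmetric: both tension and compression rupture.

A fiber attaching while the substrate carries transmitted strain ``eps``
takes rest length 1 + eps, so fibers within one cohort carry different
strains at any instant; the fiber strain when the transmitted strain is
``eps'`` is x = (1 + eps') / (1 + eps) - 1.

The fraction of substrate strain delivered to the fiber cohorts is the
series-coupling factor T = K_FA / (K_FA + K_SF + K_MT): MT recruitment
raises K_MT and thereby unloads the stress fibers (strain homeostasis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator

__all__ = [
    "MechanicsParams",
    "FiberCohort",
    "fiber_strain",
    "detach_probability",
    "mt_attach_probability",
    "assembly_stiffness",
    "transmission_factor",
    "step_cohorts",
]

# Below this exponent the rupture probability is evaluated by its 2nd-order
# series instead of exp(); keeps the hot loop cheap for the many nearly
# unloaded fibers. The batched engine kernel uses the identical branch so
# that batched and per-fiber updates agree bit for bit.
_PD_SERIES_CUTOFF = 1e-3


class MechanicsParams(BaseModel):
    """Parameters of the FA / stress-fiber / microtubule spring assembly.

    Stiffnesses are dimensionless (only ratios enter the strain balance);
    the SF:MT per-fiber ratio 2.6:1.7 follows measured Young's moduli of
    actin filaments and microtubules.

    ``p_attach_sf`` is the attachment probability per free SF slot per
    stretch *cycle*; it is converted internally to a per-substep
    probability.  ``mt_attach_slope`` multiplies the mean absolute SF
    strain to give the per-free-slot MT attachment probability per substep.
    Both are unreported by the experiments this model emulates and were
    calibrated once against the 2 h orientation endpoint (mean 69 deg,
    SD 11 deg); see docs/methods.md.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    sf_unit_stiffness: float = 2.6
    mt_unit_stiffness: float = 1.7
    k_fa_ratio: float = 10.0
    p_attach_sf: float = 0.002
    mt_attach_slope: float = 0.05
    rupture_scale: float = 0.2
    capacity_sf: int = 20
    capacity_mt: int = 20
    n_seed_sf: int = 5
    mt_detach_enabled: bool = True

    @field_validator(
        "sf_unit_stiffness", "mt_unit_stiffness", "k_fa_ratio",
        "mt_attach_slope", "rupture_scale",
    )
    @classmethod
    def _nonneg(cls, v: float, info) -> float:
        if info.field_name == "mt_attach_slope":
            if v < 0:
                raise ValueError("mt_attach_slope must be >= 0")
            return v
        if v <= 0:
            raise ValueError(f"{info.field_name} must be positive, got {v}")
        return v

    @field_validator("p_attach_sf")
    @classmethod
    def _prob(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"p_attach_sf must be in [0, 1], got {v}")
        return v

    @field_validator("capacity_sf", "capacity_mt")
    @classmethod
    def _cap(cls, v: int) -> int:
        if v < 1:
            raise ValueError("cohort capacity must be >= 1")
        return v

    @field_validator("n_seed_sf")
    @classmethod
    def _seed(cls, v: int, info) -> int:
        if v < 1:
            raise ValueError("n_seed_sf must be >= 1")
        return v

    def fa_stiffness(self) -> float:
        """K_FA: ``k_fa_ratio`` times the full-cohort cytoskeletal stiffness."""
        return self.k_fa_ratio * (
            self.capacity_sf * self.sf_unit_stiffness
            + self.capacity_mt * self.mt_unit_stiffness
        )

    def p_attach_substep(self, substeps_per_cycle: int) -> float:
        """Per-substep SF attachment probability equivalent to ``p_attach_sf`` per cycle."""
        if substeps_per_cycle < 1:
            raise ValueError("substeps_per_cycle must be >= 1")
        return 1.0 - (1.0 - self.p_attach_sf) ** (1.0 / substeps_per_cycle)


@dataclass
class FiberCohort:
    """Fixed-capacity set of fibers of one type attached at one focal adhesion.

    Slots are explicit so that the per-fiber reference update and the
    batched engine consume random draws in the same order.  ``attach_strains``
    holds the transmitted substrate strain recorded at each fiber's
    attachment instant (its rest length is 1 + that strain) and is only
    meaningful where ``attached`` is True.
    """

    fiber_type: str  # "SF" or "MT"
    unit_stiffness: float
    capacity: int
    attached: np.ndarray = field(default=None)  # bool, shape (capacity,)
    attach_strains: np.ndarray = field(default=None)  # float64, shape (capacity,)

    def __post_init__(self):
        if self.fiber_type not in ("SF", "MT"):
            raise ValueError("fiber_type must be 'SF' or 'MT'")
        if self.unit_stiffness <= 0:
            raise ValueError("unit_stiffness must be positive")
        if self.attached is None:
            self.attached = np.zeros(self.capacity, dtype=bool)
        if self.attach_strains is None:
            self.attach_strains = np.zeros(self.capacity, dtype=float)
        self.attached = np.asarray(self.attached, dtype=bool)
        self.attach_strains = np.asarray(self.attach_strains, dtype=float)
        if self.attached.shape != (self.capacity,) or self.attach_strains.shape != (self.capacity,):
            raise ValueError("slot arrays must have shape (capacity,)")
        live = self.attach_strains[self.attached]
        if live.size and not np.all((live > -1.0) & (live < 1.0)):
            raise ValueError("attach strains must lie in (-1, 1)")

    @classmethod
    def from_strains(cls, fiber_type: str, strains, unit_stiffness: float,
                     capacity: int) -> "FiberCohort":
        """Build a cohort with the given attach strains in the first slots."""
        strains = np.asarray(strains, dtype=float)
        if strains.size > capacity:
            raise ValueError("more fibers than capacity")
        attached = np.zeros(capacity, dtype=bool)
        attach_strains = np.zeros(capacity, dtype=float)
        attached[: strains.size] = True
        attach_strains[: strains.size] = strains
        return cls(fiber_type, unit_stiffness, capacity, attached, attach_strains)

    @property
    def count(self) -> int:
        return int(self.attached.sum())

    @property
    def stiffness(self) -> float:
        return self.count * self.unit_stiffness

    @property
    def strains(self) -> np.ndarray:
        """Attach strains of currently attached fibers (slot order)."""
        return self.attach_strains[self.attached]

    def copy(self) -> "FiberCohort":
        return FiberCohort(self.fiber_type, self.unit_stiffness, self.capacity,
                           self.attached.copy(), self.attach_strains.copy())


def fiber_strain(current_strain, attach_strain):
    """Strain carried by a fiber of rest length 1 + attach_strain.

    x = (1 + current) / (1 + attach) - 1.  Zero when the transmitted strain
    equals the strain at attachment; a fiber attached at peak stretch is
    compressed at the trough.
    """
    cur = np.asarray(current_strain, dtype=float)
    att = np.asarray(attach_strain, dtype=float)
    if np.any(att <= -1.0):
        raise ValueError("attach_strain must be > -1")
    out = (1.0 + cur) / (1.0 + att) - 1.0
    return out if (cur.ndim or att.ndim) else float(out)


def _pd_scalar(x: float, inv_scale: float) -> float:
    # Shared numeric contract with the batched engine kernel: same branch,
    # same operation order, so Bernoulli comparisons agree bit for bit.
    y = (x * x) * inv_scale
    if y < _PD_SERIES_CUTOFF:
        return y * (1.0 - 0.5 * y)
    return 1.0 - math.exp(-y)


def detach_probability(x, rupture_scale: float = 0.2):
    """Rupture probability P_d = 1 - exp(-x^2 / rupture_scale) per update.

    Even in ``x`` (tension and compression both rupture), strictly
    increasing in |x|, bounded in [0, 1).  The default scale 0.2
    corresponds to a normally distributed breaking threshold with zero
    mean and 10% variance.
    """
    if rupture_scale <= 0:
        raise ValueError("rupture_scale must be positive")
    inv = 1.0 / rupture_scale
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        return _pd_scalar(float(arr), inv)
    flat = arr.ravel()
    out = np.array([_pd_scalar(float(v), inv) for v in flat])
    return out.reshape(arr.shape)


def mt_attach_probability(mean_sf_strain: float, params: MechanicsParams) -> float:
    """Per-free-slot MT attachment probability per substep.

    Linear in the mean absolute strain on the local stress fibers, clipped
    to [0, 1]; zero when the SFs carry no strain (no strained SFs, no MT
    recruitment).
    """
    return min(1.0, params.mt_attach_slope * abs(mean_sf_strain))


def assembly_stiffness(sf: FiberCohort, mt: FiberCohort) -> tuple[float, float]:
    """(K_SF, K_MT): cohort counts times per-fiber stiffness."""
    return sf.stiffness, mt.stiffness


def transmission_factor(k_fa: float, k_sf: float, k_mt: float) -> float:
    """Fraction of substrate strain delivered to the fiber cohorts.

    Series coupling of the FA spring with the parallel SF/MT pair:
    T = K_FA / (K_FA + K_SF + K_MT) in (0, 1]; strictly decreasing in the
    cytoskeletal stiffness, tending to 1 for a rigid focal adhesion.
    """
    if k_fa <= 0:
        raise ValueError("K_FA must be positive")
    if k_sf < 0 or k_mt < 0:
        raise ValueError("cohort stiffnesses must be non-negative")
    return k_fa / (k_fa + k_sf + k_mt)


def step_cohorts(
    fa_angle: float,
    substrate_strain_now: float,
    sf: FiberCohort,
    mt: FiberCohort,
    params: MechanicsParams,
    rng: np.random.Generator,
    substeps_per_cycle: int = 1,
) -> tuple[FiberCohort, FiberCohort, float]:
    """One stochastic update of both cohorts at a single focal adhesion.

    Reference per-fiber implementation (explicit Python loop over slots);
    the batched engine in :mod:`stretchalign._engine` reproduces it bit for
    bit given the same random stream.

    Update order:

    1. transmitted strain ``eps_t = T * substrate_strain_now`` with T from
       the current cohort stiffnesses;
    2. mean absolute SF strain over attached fibers (pre-detachment);
    3. detachment: each attached fiber ruptures with ``detach_probability``
       of its own strain (MT detachment can be disabled, modeling
       pharmacological stabilization);
    4. attachment: slots free *at the start of the substep* gain a fiber
       with probability ``p_attach_substep`` (SF) or
       ``mt_attach_probability`` (MT); new fibers record ``eps_t`` as
       their attach strain.

    Random draw contract (per call): one float32 uniform per SF slot, then
    one per MT slot; an attached slot uses its draw for the detachment
    test, a free slot for the attachment test.

    Parameters
    ----------
    fa_angle : float
        Anchor angle of the FA in degrees (bookkeeping only; the strain at
        that angle is supplied pre-computed).
    substrate_strain_now : float
        Substrate strain eps(alpha, delta(t), nu) at the FA angle.
    substeps_per_cycle : int
        Number of updates per stretch cycle; scales the SF attachment
        probability so that ``p_attach_sf`` stays a per-cycle quantity.

    Returns
    -------
    (sf', mt', mean_sf_strain)
        Updated cohort copies and the pre-detachment mean absolute SF strain.
    """
    del fa_angle  # strain is supplied already evaluated at the FA angle
    sf_new = sf.copy()
    mt_new = mt.copy()

    k_fa = params.fa_stiffness()
    t_factor = transmission_factor(k_fa, sf.stiffness, mt.stiffness)
    eps_t = t_factor * substrate_strain_now

    u_sf = rng.random(sf.capacity, dtype=np.float32)
    u_mt = rng.random(mt.capacity, dtype=np.float32)

    inv_scale = 1.0 / params.rupture_scale
    p_sf = params.p_attach_substep(substeps_per_cycle)

    # mean absolute SF strain, pre-detachment, ascending slot order
    total = 0.0
    n_att = 0
    for s in range(sf.capacity):
        if sf.attached[s]:
            x = (1.0 + eps_t) / (1.0 + sf.attach_strains[s]) - 1.0
            total += abs(x)
            n_att += 1
    mean_sf = total / n_att if n_att else 0.0

    for s in range(sf.capacity):
        if sf.attached[s]:
            x = (1.0 + eps_t) / (1.0 + sf.attach_strains[s]) - 1.0
            if u_sf[s] < _pd_scalar(x, inv_scale):
                sf_new.attached[s] = False
        else:
            if u_sf[s] < p_sf:
                sf_new.attached[s] = True
                sf_new.attach_strains[s] = eps_t

    q_mt = mt_attach_probability(mean_sf, params)
    for s in range(mt.capacity):
        if mt.attached[s]:
            x = (1.0 + eps_t) / (1.0 + mt.attach_strains[s]) - 1.0
            if params.mt_detach_enabled and u_mt[s] < _pd_scalar(x, inv_scale):
                mt_new.attached[s] = False
        else:
            if u_mt[s] < q_mt:
                mt_new.attached[s] = True
                mt_new.attach_strains[s] = eps_t

    return sf_new, mt_new, mean_sf
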
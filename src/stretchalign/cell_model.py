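"""Single-cell state: focal adhesions in angle, orientation and circularity.

A cell is represented by the angular positions of its ``N_FA`` focal
adhesions on [0, 180) (orientations are axial: alpha and alpha + 180 are
the same direction).  Shape and orientation are read out statistically:

* orientation theta = mode of the FA angular density, folded to [0, 90],
  estimated on a 5-degree histogram (the binning used for the experimental
  orientation histograms);
* circularity = circular variance of the doubled FA angles,
  cv = 1 - |mean exp(2 i alpha)|, with cv -> 0 for a tightly oriented
  (elongated) cell and cv -> 1 for a uniform FA distribution (round cell).

Focal adhesions whose stress-fiber and microtubule cohorts have both
emptied bear no cytoskeletal load and dissolve; they immediately re-form
at an angle drawn uniformly on [0, 180), so N_FA is conserved.  Alignment
emerges from differential survival (strain-dependent fiber rupture), not
from any angular bias at re-insertion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fiber_mechanics import FiberCohort, MechanicsParams, transmission_factor
from .strain_field import StrainParams, substrate_strain
from .orientation_stats import fold_axial

__all__ = [
    "FocalAdhesion",
    "CellState",
    "initialize_cell",
    "circular_variance",
    "orientation_mode",
    "fa_turnover",
]

_MODE_BIN_DEG = 5.0


@dataclass
class FocalAdhesion:
    """One focal adhesion: axial anchor angle plus its SF and MT cohorts."""

    alpha: float  # degrees in [0, 180)
    sf: FiberCohort
    mt: FiberCohort

    def __post_init__(self):
        if not 0.0 <= self.alpha < 180.0:
            raise ValueError("alpha must lie in [0, 180)")

    @property
    def is_empty(self) -> bool:
        return self.sf.count == 0 and self.mt.count == 0


@dataclass
class CellState:
    """Collection of focal adhesions with derived orientation readouts."""

    focal_adhesions: list
    theta: float = 0.0  # folded orientation, degrees in [0, 90]
    cv: float = 0.0  # circular variance in [0, 1]

    @property
    def n_fa(self) -> int:
        return len(self.focal_adhesions)

    @property
    def fa_angles(self) -> np.ndarray:
        return np.array([fa.alpha for fa in self.focal_adhesions])

    def refresh(self) -> "CellState":
        """Recompute theta and cv from the current FA angles (in place)."""
        angles = self.fa_angles
        self.theta = orientation_mode(angles)
        self.cv = circular_variance(angles)
        return self


def circular_variance(fa_angles) -> float:
    """Axial circular variance: 1 minus the resultant length of doubled angles.

    cv = 1 - |(1/N) sum_j exp(2 i alpha_j)| in [0, 1].  Identical angles
    give 0; uniform angles give 1 in the large-N limit (equal mass at 0
    and 90 degrees gives exactly 1: the doubled angles are antipodal).
    """
    angles = np.asarray(fa_angles, dtype=float)
    if angles.size == 0:
        raise ValueError("need at least one angle")
    z = np.exp(2j * np.deg2rad(angles))
    return float(np.clip(1.0 - np.abs(z.mean()), 0.0, 1.0))


def _axial_mean_folded(angles: np.ndarray) -> float:
    """Circular mean direction of axial data, folded to [0, 90]."""
    z = np.exp(2j * np.deg2rad(angles))
    if np.abs(z.mean()) < 1e-12:
        return 0.0
    mu = np.rad2deg(np.angle(z.mean())) / 2.0  # in (-90, 90]
    return float(fold_axial(mu))


def orientation_mode(fa_angles) -> float:
    """Mode of the folded FA angular density at 5-degree resolution.

    Angles are folded to [0, 90], histogrammed in eighteen 5-degree bins,
    and the center of the fullest bin is returned.  Ties are broken
    deterministically toward the bin center closest to the axial circular
    mean of the sample (then toward the lower center).
    """
    angles = np.asarray(fa_angles, dtype=float)
    if angles.size < 10:
        raise ValueError("mode estimation needs at least 10 angles")
    folded = fold_axial(angles)
    edges = np.arange(0.0, 90.0 + _MODE_BIN_DEG, _MODE_BIN_DEG)
    counts, _ = np.histogram(folded, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    best = np.flatnonzero(counts == counts.max())
    if best.size == 1:
        return float(centers[best[0]])
    ref = _axial_mean_folded(angles)
    tied = centers[best]
    return float(tied[np.argmin(np.abs(tied - ref))])  # argmin takes lowest on ties


def _seed_fa(alpha: float, mechanics: MechanicsParams, attach_strain: float = 0.0,
             mt_full: bool = False) -> FocalAdhesion:
    """Fresh focal adhesion with a seed SF cohort (and optionally full MTs)."""
    sf = FiberCohort.from_strains(
        "SF", [attach_strain] * mechanics.n_seed_sf,
        mechanics.sf_unit_stiffness, mechanics.capacity_sf)
    if mt_full:
        mt = FiberCohort.from_strains(
            "MT", [attach_strain] * mechanics.capacity_mt,
            mechanics.mt_unit_stiffness, mechanics.capacity_mt)
    else:
        mt = FiberCohort("MT", mechanics.mt_unit_stiffness, mechanics.capacity_mt)
    return FocalAdhesion(float(alpha), sf, mt)


def initialize_cell(
    theta0: float,
    n_fa: int,
    spread: float = 5.0,
    rng: np.random.Generator | None = None,
    mechanics: MechanicsParams | None = None,
    mt_full: bool = False,
) -> CellState:
    """Cell oriented at ``theta0`` with FAs wrapped-normally spread around it.

    FA angles are drawn from a Gaussian with mean ``theta0`` and SD
    ``spread`` (default 5 degrees), wrapped onto [0, 180).  Cohorts are
    seeded with ``n_seed_sf`` stress fibers at zero attach strain
    (unstretched membrane); ``mt_full`` pre-fills the MT cohorts, as under
    pharmacological microtubule stabilization.
    """
    if n_fa < 10:
        raise ValueError("n_fa must be >= 10 for reliable mode estimation")
    if spread <= 0:
        raise ValueError("spread must be positive")
    rng = np.random.default_rng() if rng is None else rng
    mechanics = MechanicsParams() if mechanics is None else mechanics
    alphas = np.mod(rng.normal(theta0, spread, size=n_fa), 180.0)
    fas = [_seed_fa(a, mechanics, 0.0, mt_full) for a in alphas]
    return CellState(fas).refresh()


def fa_turnover(
    cell: CellState,
    rng: np.random.Generator,
    mechanics: MechanicsParams | None = None,
    strain: StrainParams | None = None,
    delta: float = 0.0,
    mt_full: bool = False,
) -> CellState:
    """Dissolve load-free FAs and re-form them at uniform random angles.

    Every FA whose SF and MT cohorts are both empty is replaced by a fresh
    FA at an angle drawn uniformly on [0, 180), with a seed SF cohort whose
    attach strain equals the transmitted substrate strain at the new angle
    under the instantaneous uniaxial strain ``delta`` (0 for an unloaded
    membrane).  N_FA is conserved.  New angles are drawn in FA index order
    with a single uniform draw per dissolved FA.
    """
    mechanics = MechanicsParams() if mechanics is None else mechanics
    empty_idx = [i for i, fa in enumerate(cell.focal_adhesions) if fa.is_empty]
    if not empty_idx:
        return cell
    new_alphas = rng.random(len(empty_idx)) * 180.0
    k_fa = mechanics.fa_stiffness()
    k_seed_sf = mechanics.n_seed_sf * mechanics.sf_unit_stiffness
    k_seed_mt = mechanics.capacity_mt * mechanics.mt_unit_stiffness if mt_full else 0.0
    t_seed = transmission_factor(k_fa, k_seed_sf, k_seed_mt)
    fas = list(cell.focal_adhesions)
    for i, a in zip(empty_idx, new_alphas):
        if strain is not None:
            eps0 = t_seed * substrate_strain(a, delta, strain.nu)
        else:
            eps0 = 0.0
        fas[i] = _seed_fa(a, mechanics, eps0, mt_full)
    return CellState(fas).refresh()
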
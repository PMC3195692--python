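"""Cell-level readouts: circular variance, orientation mode, FA turnover."""

import numpy as np
import pytest

from stretchalign.cell_model import (
    CellState,
    FocalAdhesion,
    circular_variance,
    fa_turnover,
    initialize_cell,
    orientation_mode,
)
from stretchalign.fiber_mechanics import FiberCohort, MechanicsParams
from stretchalign.strain_field import StrainParams


class TestCircularVariance:
    def test_identical_angles_give_zero(self):
        assert circular_variance(np.full(50, 37.0)) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_angles_approach_one(self):
        rng = np.random.default_rng(0)
        cv = circular_variance(rng.random(200_0) * 180.0)
        assert cv == pytest.approx(1.0, abs=0.05)

    def test_orthogonal_pair_is_exactly_one(self):
        # doubled angles are antipodal, resultant vanishes
        assert circular_variance([0.0, 90.0] * 10) == pytest.approx(1.0, abs=1e-12)

    def test_invariances(self):
        rng = np.random.default_rng(1)
        a = rng.random(64) * 180.0
        base = circular_variance(a)
        assert circular_variance(rng.permutation(a)) == pytest.approx(base)
        shifted = np.mod(a + 180.0, 360.0)  # alpha and alpha+180 are the same axis
        assert circular_variance(shifted) == pytest.approx(base, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            circular_variance([])


class TestOrientationMode:
    def test_tight_cluster_at_70(self):
        rng = np.random.default_rng(2)
        a = rng.normal(70.0, 1.0, 100)
        assert orientation_mode(a) == pytest.approx(67.5, abs=5.0)
        assert abs(orientation_mode(a) - 70.0) <= 2.5  # within one bin half-width

    def test_cluster_at_30_matches_kde_argmax(self):
        from scipy.stats import gaussian_kde

        rng = np.random.default_rng(7)
        a = rng.normal(30.0, 3.0, 400)
        kde = gaussian_kde(a)
        grid = np.linspace(0, 90, 901)
        peak = grid[np.argmax(kde(grid))]
        assert abs(orientation_mode(a) - peak) <= 2.5

    def test_tie_break_is_deterministic(self):
        # two exactly equal maximal bins
        a = np.concatenate([np.full(20, 12.0), np.full(20, 72.0), [40.0] * 5])
        results = {orientation_mode(np.random.default_rng(s).permutation(a))
                   for s in range(10)}
        assert len(results) == 1

    def test_invariance_under_relabeling_and_axial_shift(self):
        rng = np.random.default_rng(3)
        a = rng.normal(50.0, 8.0, 80) % 180.0
        base = orientation_mode(a)
        assert orientation_mode(rng.permutation(a)) == base
        assert orientation_mode(np.mod(a + 180.0, 360.0)) == base

    def test_too_few_angles_rejected(self):
        with pytest.raises(ValueError):
            orientation_mode(np.arange(9.0))


class TestInitializeCell:
    def test_mode_near_theta0(self):
        cell = initialize_cell(30.0, n_fa=100, spread=5.0,
                               rng=np.random.default_rng(0))
        assert abs(cell.theta - 30.0) <= 5.0
        assert cell.n_fa == 100

    def test_small_spread_gives_small_cv(self):
        rng = np.random.default_rng(1)
        tight = initialize_cell(40.0, 200, spread=0.5, rng=rng).cv
        loose = initialize_cell(40.0, 200, spread=30.0, rng=np.random.default_rng(1)).cv
        assert tight < 0.01 < loose

    def test_wrapping_at_zero_seam(self):
        # FAs of a cell at theta0 = 0 straddle the 0/180 seam without bias
        cell = initialize_cell(0.0, 500, spread=5.0, rng=np.random.default_rng(2))
        assert cell.theta <= 5.0
        assert cell.cv < 0.05
        folded = np.minimum(cell.fa_angles, 180.0 - cell.fa_angles)
        # wrapped draws match a plain normal folded onto [0, 90) in spread
        assert np.std(folded) == pytest.approx(5.0 * np.sqrt(1 - 2 / np.pi), rel=0.25)

    def test_seed_cohorts(self):
        mech = MechanicsParams(n_seed_sf=7)
        cell = initialize_cell(10.0, 20, rng=np.random.default_rng(3), mechanics=mech)
        assert all(fa.sf.count == 7 and fa.mt.count == 0 for fa in cell.focal_adhesions)
        cell_mt = initialize_cell(10.0, 20, rng=np.random.default_rng(3),
                                  mechanics=mech, mt_full=True)
        assert all(fa.mt.count == mech.capacity_mt for fa in cell_mt.focal_adhesions)

    def test_too_few_fas_rejected(self):
        with pytest.raises(ValueError):
            initialize_cell(30.0, n_fa=5)


def _cell_with_counts(angles, sf_counts, mech):
    fas = []
    for a, n in zip(angles, sf_counts):
        sf = FiberCohort.from_strains("SF", [0.0] * n, mech.sf_unit_stiffness,
                                      mech.capacity_sf)
        mt = FiberCohort("MT", mech.mt_unit_stiffness, mech.capacity_mt)
        fas.append(FocalAdhesion(float(a), sf, mt))
    return CellState(fas).refresh()


class TestFaTurnover:
    def test_no_empty_fas_is_identity(self):
        mech = MechanicsParams()
        cell = _cell_with_counts(np.linspace(0, 170, 20), [3] * 20, mech)
        out = fa_turnover(cell, np.random.default_rng(0), mech)
        assert out is cell

    def test_full_rerandomization_raises_cv(self):
        mech = MechanicsParams()
        rng = np.random.default_rng(1)
        tight = initialize_cell(20.0, 200, spread=5.0, rng=rng, mechanics=mech)
        emptied = _cell_with_counts(tight.fa_angles, [0] * 200, mech)
        out = fa_turnover(emptied, rng, mech)
        assert out.n_fa == 200
        assert out.cv > tight.cv  # circularization
        assert out.cv > 0.8  # near-uniform resample
        # uniform re-insertion: folded mean near 45
        folded = np.minimum(out.fa_angles, 180.0 - out.fa_angles)
        assert folded.mean() == pytest.approx(45.0, abs=5.0)

    def test_reformed_fa_records_transmitted_strain(self):
        mech = MechanicsParams(n_seed_sf=5)
        strain = StrainParams()
        cell = _cell_with_counts(np.linspace(0, 170, 12), [0] * 12, mech)
        out = fa_turnover(cell, np.random.default_rng(5), mech, strain=strain, delta=0.2)
        from stretchalign.strain_field import substrate_strain
        from stretchalign.fiber_mechanics import transmission_factor

        t_seed = transmission_factor(mech.fa_stiffness(),
                                     5 * mech.sf_unit_stiffness, 0.0)
        for fa in out.focal_adhesions:
            expected = t_seed * substrate_strain(fa.alpha, 0.2, strain.nu)
            np.testing.assert_allclose(fa.sf.strains, expected, atol=1e-12)

    def test_reformation_rate_higher_at_high_strain_angle(self):
        """An FA parallel to the stretch axis (large |eps|) loses its fibers
        and re-forms more often than one near the minimum-strain direction."""
        from stretchalign.fiber_mechanics import step_cohorts
        from stretchalign.strain_field import cyclic_delta, substrate_strain

        mech = MechanicsParams()
        strain = StrainParams()

        def reformation_events(alpha0, seed, n_cycles=400, m_sub=4):
            sf = FiberCohort.from_strains("SF", [0.0] * mech.n_seed_sf,
                                          mech.sf_unit_stiffness, mech.capacity_sf)
            mt = FiberCohort("MT", mech.mt_unit_stiffness, mech.capacity_mt)
            rng = np.random.default_rng(seed)
            events = 0
            alpha = alpha0
            for k in range(n_cycles * m_sub):
                delta = cyclic_delta(k / (strain.frequency * m_sub), strain)
                eps = substrate_strain(alpha, delta, strain.nu)
                sf, mt, _ = step_cohorts(alpha, eps, sf, mt, mech, rng,
                                         substeps_per_cycle=m_sub)
                if sf.count == 0 and mt.count == 0:
                    events += 1
                    alpha = rng.random() * 180.0
                    sf = FiberCohort.from_strains(
                        "SF", [0.0] * mech.n_seed_sf, mech.sf_unit_stiffness,
                        mech.capacity_sf)
                    alpha = alpha0  # pin the angle: we compare hazard, not drift
            return events

        high = sum(reformation_events(0.0, s) for s in range(3))
        low = sum(reformation_events(68.8, s) for s in range(3))
        assert high > low
        assert low == 0  # minimum-strain FAs essentially never dissolve

    def test_n_fa_conserved(self):
        mech = MechanicsParams()
        cell = _cell_with_counts(np.linspace(0, 170, 30), [0, 2] * 15, mech)
        out = fa_turnover(cell, np.random.default_rng(9), mech)
        assert out.n_fa == 30
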
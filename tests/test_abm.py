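"""Stochastic lattice dynamics: single-event enumeration, invariants,
qualitative population fates."""

import numpy as np
import pytest

from lineagegrid.abm import (
    FeedbackABMParams,
    FeedforwardParams,
    FieldParams,
    Simulation,
    local_self_renewal_prob,
    local_ta_self_renewal_prob,
    run_feedback_abm,
)
from lineagegrid.lattice import CellKind, Lattice, count_cells

NO_FIELD = FieldParams(0.0, 1.0, 0.0, 0.0)
N = 11  # smallest convenient grid above the 9-spot minimum


def lattice_with(placements):
    states = np.zeros((N, N), dtype=np.int8)
    for (r, c), kind in placements.items():
        states[r, c] = kind
    return Lattice(states)


def quiet_params(**kw):
    base = dict(p_div=0.0, p0_self=0.7, p_sdeath=0.0, p_ddeath=0.0, p_mig=0.0,
                field=NO_FIELD, n=N, horizon=10, seed=1)
    base.update(kw)
    return FeedbackABMParams(**base)


def quiet_ff_params(**kw):
    base = dict(p_div=0.0, p0_self=0.7, p_sdeath=0.0, p_ddeath=0.0, p_mig=0.0,
                q_div=0.0, q_tdeath=0.0, field=NO_FIELD,
                ff_field=FieldParams(0.0, 1.0, 0.0, 2.0), n=N, horizon=10, seed=1)
    base.update(kw)
    return FeedforwardParams(**base)


class TestLocalProbabilities:
    def test_stem_self_renewal_formula(self):
        assert local_self_renewal_prob(0.0, 1.6, 0.7) == pytest.approx(0.7)
        assert local_self_renewal_prob(1.0, 1.6, 0.7) == pytest.approx(0.7 / 2.6)
        assert local_self_renewal_prob(1e6, 1.6, 0.7) == pytest.approx(0.7 / (1 + 1.6e6))
        # strictly decreasing in z
        zs = np.linspace(0, 10, 50)
        ps = [local_self_renewal_prob(z, 1.6, 0.7) for z in zs]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        with pytest.raises(ValueError):
            local_self_renewal_prob(-1.0, 1.6, 0.7)

    def test_ta_self_renewal_formula(self):
        assert local_ta_self_renewal_prob(0.0, 5.0) == 0.0
        assert local_ta_self_renewal_prob(1.0, 2.0) == pytest.approx(2.0 / 3.0)
        assert local_ta_self_renewal_prob(1e9, 2.0) == pytest.approx(1.0, abs=1e-8)
        ws = np.linspace(0, 10, 50)
        qs = [local_ta_self_renewal_prob(w, 2.0) for w in ws]
        assert all(a < b for a, b in zip(qs, qs[1:]))
        with pytest.raises(ValueError):
            local_ta_self_renewal_prob(1.0, -2.0)


class TestSingleSamplingEvents:
    def test_certain_self_renewal_doubles_a_lone_stem(self):
        params = quiet_params(p_div=1.0, p0_self=1.0)
        sim = Simulation(params, init_lattice=lattice_with({(5, 5): CellKind.STEM}))
        counts = sim.step()
        assert (counts.stem, counts.ta, counts.diff) == (2, 0, 0)

    def test_division_aborts_when_fully_enclosed(self):
        placements = {(5, 5): CellKind.STEM}
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr or dc:
                    placements[(5 + dr, 5 + dc)] = CellKind.DIFF
        sim = Simulation(quiet_params(p_div=1.0, p0_self=1.0),
                         init_lattice=lattice_with(placements))
        for _ in range(20):
            counts = sim.step()
        assert counts.stem == 1 and counts.diff == 8

    def test_certain_differentiation_converts_the_mother(self):
        # two-compartment: a lone stem becomes two differentiated cells
        sim = Simulation(quiet_params(p_div=1.0, p0_self=0.0),
                         init_lattice=lattice_with({(5, 5): CellKind.STEM}))
        counts = sim.step()
        assert (counts.stem, counts.diff) == (0, 2)

    def test_certain_death_of_a_lone_diff_cell(self):
        sim = Simulation(quiet_params(p_ddeath=1.0),
                         init_lattice=lattice_with({(5, 5): CellKind.DIFF}))
        counts = sim.step()
        assert counts.total == 0

    def test_stem_differentiation_yields_two_ta_cells(self):
        sim = Simulation(quiet_ff_params(p_div=1.0, p0_self=0.0), model="feedforward",
                         init_lattice=lattice_with({(5, 5): CellKind.STEM}))
        counts = sim.step()
        assert (counts.stem, counts.ta, counts.diff) == (0, 2, 0)

    def test_ta_without_feedforward_factor_terminally_differentiates(self):
        sim = Simulation(quiet_ff_params(q_div=1.0), model="feedforward",
                         init_lattice=lattice_with({(5, 5): CellKind.TA}))
        counts = sim.step()  # w = 0 everywhere -> q_self = 0
        assert (counts.stem, counts.ta, counts.diff) == (0, 0, 2)

    def test_ta_with_saturating_factor_self_renews(self):
        sim = Simulation(quiet_ff_params(q_div=1.0), model="feedforward",
                         init_lattice=lattice_with({(5, 5): CellKind.TA}))
        sim.w[:] = 1e9  # q_self ~ 1
        counts = sim.step()
        assert (counts.stem, counts.ta, counts.diff) == (0, 2, 0)

    def test_migration_conserves_the_cell(self):
        sim = Simulation(quiet_params(p_mig=1.0),
                         init_lattice=lattice_with({(5, 5): CellKind.DIFF}))
        for _ in range(10):
            counts = sim.step()
        assert counts.total == 1 and counts.diff == 1


class TestStructuralInvariants:
    def test_single_occupancy_and_bookkeeping_consistency(self):
        params = FeedbackABMParams(
            n=30, horizon=150, seed=7, p_div=0.3, p0_self=0.7, p_sdeath=0.01,
            p_ddeath=0.05, p_mig=0.3, field=FieldParams(2.0, 0.5, 0.3, 0.5),
        )
        sim = Simulation(params)
        for _ in range(params.horizon):
            sim.step()
            # occupancy list matches the grid exactly
            occ = set(zip(sim.occ_r[: sim.n_cells].tolist(),
                          sim.occ_c[: sim.n_cells].tolist()))
            rows, cols = np.nonzero(sim.grid)
            assert occ == set(zip(rows.tolist(), cols.tolist()))
            assert sim.n_cells == len(occ)

    def test_population_change_bounded_by_samplings(self):
        params = FeedbackABMParams(n=30, horizon=200, seed=3, p_div=1.0,
                                   p0_self=0.9, p_ddeath=0.2, p_mig=0.1,
                                   field=NO_FIELD)
        sim = Simulation(params)
        prev = sim.counts().total
        for _ in range(params.horizon):
            cur = sim.step().total
            assert abs(cur - prev) <= max(prev, 1)
            prev = cur

    def test_seeded_runs_are_bit_identical(self):
        params = FeedbackABMParams(n=40, horizon=300, seed=11,
                                   p_sdeath=8.3e-5, p_ddeath=4.17e-3,
                                   field=FieldParams(8.33, 8.3e-3, 0.83, 4e-3))
        a = run_feedback_abm(params)
        b = run_feedback_abm(params)
        assert np.array_equal(a.series.stem, b.series.stem)
        assert np.array_equal(a.series.diff, b.series.diff)
        assert np.array_equal(a.lattice.states, b.lattice.states)
        assert np.allclose(a.field_z.conc, b.field_z.conc, rtol=0, atol=0)

    def test_different_seeds_differ(self):
        base = FeedbackABMParams(n=40, horizon=200, p_ddeath=4.17e-3,
                                 field=FieldParams(8.33, 8.3e-3, 0.83, 4e-3))
        a = run_feedback_abm(base.with_(seed=1))
        b = run_feedback_abm(base.with_(seed=2))
        assert not np.array_equal(a.series.total, b.series.total)

    def test_series_counts_match_final_snapshot(self):
        params = FeedbackABMParams(n=30, horizon=100, seed=5, p_ddeath=4.17e-3,
                                   field=FieldParams(8.33, 8.3e-3, 0.83, 4e-3))
        res = run_feedback_abm(params)
        final = count_cells(res.lattice)
        assert res.series.stem[-1] == final.stem
        assert res.series.diff[-1] == final.diff


class TestPopulationFates:
    def test_subcritical_self_renewal_goes_extinct(self):
        """p0_self < 0.5 makes the stem lineage a dying branching process."""
        extinct = 0
        for seed in range(10):
            params = FeedbackABMParams(
                n=30, horizon=6000, seed=seed, p0_self=0.4,
                p_sdeath=0.0, p_ddeath=4.17e-3, field=NO_FIELD,
            )
            res = run_feedback_abm(params)
            extinct += res.series.total[-1] == 0
        assert extinct >= 9

    def test_unfettered_growth_fills_the_grid(self):
        """Without feedback (h = 0) and p0_self > 0.5 the lattice saturates."""
        params = FeedbackABMParams(
            n=50, horizon=4000, seed=2, p0_self=0.7,
            p_sdeath=8.3e-5, p_ddeath=4.17e-3, field=NO_FIELD,
        )
        res = run_feedback_abm(params)
        assert res.series.total[-1] >= 0.8 * 50 * 50

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            FeedbackABMParams(p_div=1.5)
        with pytest.raises(ValueError):
            FeedbackABMParams(n=8)
        with pytest.raises(ValueError):
            Simulation(FeedbackABMParams(), model="nonsense")
        with pytest.raises(ValueError):
            Simulation(FeedbackABMParams(), model="combined")
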
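"""Gillespie engine: propensity assembly, SSA sampling, event dispatch."""

import numpy as np
import pytest

from tmesim import stochastic_engine as eng
from tmesim.agents import (EFFECTOR, G1, M, SUPPRESSOR, CancerCell,
                           ImmuneCell)
from tmesim.lattice import Lattice
from tmesim.oxygen_field import OxygenField
from tmesim.state import SimulationState


def make_state(extents=(10, 10, 10)):
    return SimulationState(lattice=Lattice(extents),
                           oxygen=OxygenField(extents))


class TestPropensities:
    def test_empty_state_all_zero(self):
        p = eng.compute_propensities(make_state(), eng.RateParams())
        assert p.total == 0.0
        assert all(v == 0.0 for v in p.entries.values())

    def test_division_scales_linearly_with_cancer_count(self):
        state = make_state()
        params = eng.RateParams(division=0.1)
        for i in range(7):
            state.add_cancer(CancerCell(site=(i, 0, 0)))
        p = eng.compute_propensities(state, params)
        assert p.entries[eng.CANCER_DIVISION] == pytest.approx(0.1 * 7)
        assert p.entries[eng.CANCER_NATURAL_DEATH] == pytest.approx(
            params.cancer_death * 7)

    def test_full_receptor_occupancy_suppresses_pdl1_exhaustion_term(self):
        state = make_state()
        state.add_cancer(CancerCell(site=(1, 1, 1), pdl1_positive=True))
        params = eng.RateParams(exhaustion=1.0, exh_weight_pdl1=1.0,
                                exh_weight_suppressor=1.0)
        state.receptor_occupancy = 0.0
        p0 = eng.compute_propensities(state, params)
        state.receptor_occupancy = 1.0
        p1 = eng.compute_propensities(state, params)
        assert p0.entries[eng.EFFECTOR_EXHAUSTION] > 0
        assert p1.entries[eng.EFFECTOR_EXHAUSTION] == 0.0

    def test_kill_counters_raise_pdl1_and_suppressor_propensities(self):
        state = make_state()
        state.add_cancer(CancerCell(site=(1, 1, 1)))
        params = eng.RateParams()
        before = eng.compute_propensities(state, params)
        state.cum_kills_effector += 10
        after = eng.compute_propensities(state, params)
        assert after.entries[eng.PDL1_EXPRESSION] > before.entries[eng.PDL1_EXPRESSION]
        assert after.entries[eng.SUPPRESSOR_INFILTRATION] > 0
        assert (after.entries[eng.EFFECTOR_INFILTRATION]
                > before.entries[eng.EFFECTOR_INFILTRATION])

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            eng.RateParams(division=-1.0)


class TestSampleEvent:
    def test_single_entry_always_chosen(self, rng):
        p = eng.PropensityVector({"a": 0.0, "b": 2.0})
        for _ in range(100):
            event, wait = eng.sample_event(p, rng)
            assert event == "b" and wait > 0

    def test_zero_total_signals_no_event(self, rng):
        event, wait = eng.sample_event(eng.PropensityVector({"a": 0.0}), rng)
        assert event is None and np.isinf(wait)

    def test_selection_frequency_three_to_one(self, rng):
        p = eng.PropensityVector({"a": 3.0, "b": 1.0})
        n = 10_000
        hits = sum(eng.sample_event(p, rng)[0] == "a" for _ in range(n))
        se = np.sqrt(0.75 * 0.25 / n)
        assert abs(hits / n - 0.75) < 3 * se

    def test_mean_waiting_time_is_inverse_total(self, rng):
        p = eng.PropensityVector({"a": 2.5, "b": 1.5})  # total 4
        n = 10_000
        waits = np.array([eng.sample_event(p, rng)[1] for _ in range(n)])
        assert abs(waits.mean() - 0.25) < 3 * 0.25 / np.sqrt(n)


class TestBirthDeathOracles:
    def test_pure_birth_matches_yule_mean(self):
        # mean of a Yule process is N0 * exp(b t)
        b, t, n0, reps = 0.5, 2.0, 2, 600
        rng = np.random.default_rng(7)
        finals = np.array([eng.simulate_birth_death(b, 0.0, n0, t, rng)
                           for _ in range(reps)])
        expected = n0 * np.exp(b * t)
        se = finals.std(ddof=1) / np.sqrt(reps)
        assert abs(finals.mean() - expected) < 3 * se

    def test_extinction_probability_is_death_over_birth(self):
        # from N0=1 with d < b, P(extinction) = d/b
        b, d, reps = 1.0, 0.4, 1500
        rng = np.random.default_rng(11)
        extinct = sum(eng.simulate_birth_death(b, d, 1, 40.0, rng,
                                               n_max=200) == 0
                      for _ in range(reps))
        p_hat = extinct / reps
        se = np.sqrt(0.4 * 0.6 / reps)
        assert abs(p_hat - d / b) < 3 * se


class TestExecuteEvent:
    def test_kill_without_adjacent_pair_is_vacuous(self, rng):
        state = make_state()
        state.add_cancer(CancerCell(site=(1, 1, 1)))
        state.add_immune(ImmuneCell(site=(8, 8, 8), role=EFFECTOR))
        eng.execute_event(state, eng.EFFECTOR_KILL, rng, eng.RateParams())
        assert state.n_cancer == 1
        assert state.event_log.records[-1].get("vacuous") is True

    def test_kill_removes_cancer_and_counts(self, rng):
        state = make_state()
        state.add_cancer(CancerCell(site=(4, 4, 4)))
        state.add_immune(ImmuneCell(site=(4, 4, 5), role=EFFECTOR))
        eng.execute_event(state, eng.EFFECTOR_KILL, rng, eng.RateParams())
        assert state.n_cancer == 0
        assert state.cum_kills_effector == 1

    def test_infiltration_places_fresh_cell_on_free_site(self, rng):
        state = make_state()
        state.immune_lifespan = 99.0
        eng.execute_event(state, eng.EFFECTOR_INFILTRATION, rng,
                          eng.RateParams())
        (cell,) = state.immune.values()
        assert cell.role == EFFECTOR and cell.age == 0.0
        assert cell.lifespan == 99.0
        assert state.lattice.occupant(cell.site) is not None

    def test_exhaustion_requires_pdl1_or_suppressor_contact(self, rng):
        state = make_state()
        state.add_cancer(CancerCell(site=(4, 4, 4), pdl1_positive=False))
        state.add_immune(ImmuneCell(site=(4, 4, 5), role=EFFECTOR))
        eng.execute_event(state, eng.EFFECTOR_EXHAUSTION, rng, eng.RateParams())
        assert state.n_effectors_exhausted == 0  # PDL1- contact: no pair
        state.cancer[0].pdl1_positive = True
        eng.execute_event(state, eng.EFFECTOR_EXHAUSTION, rng, eng.RateParams())
        assert state.n_effectors_exhausted == 1
        assert state.cum_exhaustions == 1

    def test_suppressor_contact_also_exhausts(self, rng):
        state = make_state()
        state.add_immune(ImmuneCell(site=(4, 4, 4), role=EFFECTOR))
        state.add_immune(ImmuneCell(site=(4, 4, 5), role=SUPPRESSOR))
        eng.execute_event(state, eng.EFFECTOR_EXHAUSTION, rng, eng.RateParams())
        assert state.n_effectors_exhausted == 1

    def test_division_uses_ready_cells_only(self, rng):
        state = make_state()
        state.add_cancer(CancerCell(site=(4, 4, 4), phase=G1))
        eng.execute_event(state, eng.CANCER_DIVISION, rng, eng.RateParams())
        assert state.n_cancer == 1  # nobody ready: vacuous
        cid = state.add_cancer(CancerCell(site=(6, 6, 6), phase=M,
                                          division_ready=True))
        eng.execute_event(state, eng.CANCER_DIVISION, rng, eng.RateParams())
        assert state.n_cancer == 3
        assert not state.cancer[cid].division_ready
        assert state.cancer[cid].phase == G1

    def test_ready_index_consistent_after_events(self, rng):
        state = make_state()
        for i in range(5):
            state.add_cancer(CancerCell(site=(i, 0, 0), phase=M,
                                        division_ready=True))
        for _ in range(10):
            eng.execute_event(state, eng.CANCER_DIVISION, rng, eng.RateParams())
            assert state.ready_cancer == state.rebuild_ready_index()

    def test_unknown_event_raises(self, rng):
        with pytest.raises(eng.DispatchError):
            eng.execute_event(make_state(), "teleportation", rng,
                              eng.RateParams())


class TestWindow:
    def test_fixed_seed_gives_identical_logs(self):
        def one_run():
            rng = np.random.default_rng(42)
            state = make_state()
            for i in range(10):
                state.add_cancer(CancerCell(site=(i, 5, 5), phase=M,
                                            division_ready=True))
            params = eng.RateParams(division=0.5, cancer_death=0.2)
            for _ in range(20):
                eng.run_gillespie_window(state, params, 1.0, rng)
            return state.event_log.records

        assert one_run() == one_run()

    def test_window_advances_time_exactly(self, rng):
        state = make_state()
        state.add_cancer(CancerCell(site=(5, 5, 5)))
        eng.run_gillespie_window(state, eng.RateParams(), 0.5, rng)
        assert state.time == pytest.approx(0.5)
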
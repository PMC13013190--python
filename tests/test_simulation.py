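"""Orchestrator: initialisation, census, hybrid loop, outputs, determinism."""

import numpy as np
import pandas as pd
import pytest

from tmesim.agents import G1, S, TumourScaling, CancerCell
from tmesim.config import RunConfig, load_fixture
from tmesim.lattice import Lattice
from tmesim.oxygen_field import OxygenField, OxygenParams
from tmesim.pkpd import RegimenSpec
from tmesim.simulation import (census, initialize, precompute_pharmacology,
                               run, write_outputs)
from tmesim.state import SimulationState
from tmesim.stochastic_engine import RateParams


def quiet_rates(**overrides):
    """All base rates zero except explicit overrides."""
    zeros = dict(division=0.0, cancer_death=0.0, pdl1_base=0.0,
                 pdl1_per_kill=0.0, effector_kill=0.0,
                 infiltration_effector=0.0, infiltration_suppressor=0.0,
                 immune_division=0.0, immune_move=0.0, exhaustion=0.0)
    zeros.update(overrides)
    return RateParams(**zeros)


class TestInitialize:
    def test_counts_and_seeding_ratio(self, rng):
        cfg = RunConfig(initial_cancer=100, immune_ratio=0.01)
        state = initialize(cfg, rng)
        assert state.n_cancer == 100
        assert state.n_immune == 1  # 1:100 immune:cancer
        assert state.n_pdl1_positive == 0
        assert np.all(state.oxygen.c == 1.0)

    def test_tumour_volume_to_agent_scaling(self):
        scaling = TumourScaling()
        assert scaling.agents_for_volume_cm3(0.1) == 100
        assert scaling.agents_for_volume_cm3(1.0) == 1000
        assert scaling.agents_for_volume_cm3(1000.0) == 1_000_000

    def test_compact_nodule_at_centre(self, rng):
        cfg = RunConfig(initial_cancer=50, immune_ratio=0.0)
        state = initialize(cfg, rng)
        centre = (np.array(cfg.lattice_extents) - 1) / 2
        sites = np.array([c.site for c in state.cancer.values()])
        radii = np.linalg.norm(sites - centre, axis=1)
        assert radii.max() < 4.0  # 50 cells pack inside radius ~2.3

    def test_zero_immune_start_is_valid(self, rng):
        cfg = RunConfig(initial_cancer=10, immune_ratio=0.0)
        state = initialize(cfg, rng)
        assert state.n_immune == 0

    def test_capacity_exceeded_raises(self, rng):
        cfg = RunConfig(lattice_extents=(4, 4, 4), initial_cancer=100)
        with pytest.raises(ValueError):
            initialize(cfg, rng)


class TestCensus:
    def test_phase_counts_partition_population(self, rng):
        state = initialize(RunConfig(initial_cancer=60), rng)
        rec = census(state)
        assert (rec["n_G1"] + rec["n_S"] + rec["n_G2"] + rec["n_M"]
                + rec["n_G0"]) == rec["n_cancer"] == 60

    def test_explicit_small_state(self):
        state = SimulationState(lattice=Lattice((5, 5, 5)),
                                oxygen=OxygenField((5, 5, 5)))
        state.add_cancer(CancerCell(site=(0, 0, 0), phase=G1))
        state.add_cancer(CancerCell(site=(1, 0, 0), phase=G1))
        state.add_cancer(CancerCell(site=(2, 0, 0), phase=S))
        rec = census(state)
        assert rec["n_G1"] == 2 and rec["n_S"] == 1
        assert rec["n_G2"] == rec["n_M"] == rec["n_G0"] == 0

    def test_pdl1_partition(self, rng):
        state = initialize(RunConfig(initial_cancer=30), rng)
        for cid in list(state.cancer)[:7]:
            state.cancer[cid].pdl1_positive = True
        rec = census(state)
        assert rec["n_pdl1_pos"] == 7
        assert rec["n_cancer"] == 30


class TestHybridLoop:
    def test_frozen_system_is_constant(self):
        cfg = RunConfig(initial_cancer=30, immune_ratio=0.0,
                        horizon_days=3.0, rates=quiet_rates(),
                        oxygen=OxygenParams(consumption=0.0))
        result = run(cfg)
        ts = result.timeseries
        assert ts.n_cancer.nunique() == 1
        # no cells enter G0: full oxygen and free space at the rim only
        # matter for cycling, so phase totals keep summing to the count
        phases = ts[["n_G1", "n_S", "n_G2", "n_M", "n_G0"]].sum(axis=1)
        assert (phases == ts.n_cancer).all()

    def test_division_only_run_matches_yule_mean_growth(self):
        # with a division rate far below the cycle flux, the ready pool is
        # never exhausted and the population is a Yule process with b = r
        b, t_h, reps = 0.005, 200.0, 40
        finals = []
        for seed in range(reps):
            cfg = RunConfig(lattice_extents=(30, 30, 30), initial_cancer=20,
                            immune_ratio=0.0, horizon_days=t_h / 24.0,
                            seed=seed, rates=quiet_rates(division=b),
                            oxygen=OxygenParams(consumption=0.0))
            finals.append(run(cfg).final_state.n_cancer)
        finals = np.array(finals, dtype=float)
        expected = 20 * np.exp(b * t_h)
        se = finals.std(ddof=1) / np.sqrt(reps)
        assert abs(finals.mean() - expected) < 3 * se

    def test_extinction_is_absorbing_stop(self):
        cfg = RunConfig(initial_cancer=5, immune_ratio=0.0, horizon_days=30.0,
                        rates=quiet_rates(cancer_death=0.5),
                        oxygen=OxygenParams(consumption=0.0))
        result = run(cfg)
        assert result.stop_reason == "extinction"
        assert result.final_state.n_cancer == 0
        assert result.timeseries.n_cancer.iloc[-1] == 0

    def test_population_accounting_matches_event_log(self, untreated_run):
        ts = untreated_run.timeseries
        ev = untreated_run.event_log.to_dataframe()
        real = ev[ev.get("vacuous").isna()] if "vacuous" in ev else ev
        births = (real.event == "cancer_division").sum()
        deaths = real.event.isin([
            "cancer_natural_death", "effector_kill", "rt_cancer_death",
            "chemo_cancer_death", "ddri_cancer_death", "necrosis_death",
        ]).sum()
        assert ts.n_cancer.iloc[0] + births - deaths == ts.n_cancer.iloc[-1]

    def test_lethal_size_ceiling_stops_run(self):
        cfg = RunConfig(initial_cancer=30, immune_ratio=0.0, horizon_days=40.0,
                        lethal_agent_count=60,
                        rates=quiet_rates(division=0.01),
                        oxygen=OxygenParams(consumption=0.0))
        result = run(cfg)
        assert result.stop_reason == "lethal_size"
        assert result.final_state.n_agents >= 60


class TestDeterminismAndOutputs:
    def test_same_seed_reproduces_byte_identical_outputs(self, tmp_path):
        cfg = load_fixture("untreated")
        cfg.horizon_days = 5.0
        run_a = run(cfg)
        cfg2 = load_fixture("untreated")
        cfg2.horizon_days = 5.0
        run_b = run(cfg2)
        pa = write_outputs(run_a, tmp_path / "a")
        pb = write_outputs(run_b, tmp_path / "b")
        for key in ("timeseries", "events", "snapshots"):
            assert pa[key].read_bytes() == pb[key].read_bytes()

    def test_config_echo_round_trips(self, tmp_path):
        cfg = load_fixture("ddri")
        cfg.to_yaml(tmp_path / "echo.yaml")
        back = RunConfig.from_yaml(tmp_path / "echo.yaml")
        assert back.to_dict() == cfg.to_dict()

    def test_written_timeseries_round_trip(self, tmp_path):
        cfg = load_fixture("untreated")
        cfg.horizon_days = 3.0
        result = run(cfg)
        paths = write_outputs(result, tmp_path)
        back = pd.read_csv(paths["timeseries"])
        assert back.shape == result.timeseries.shape
        np.testing.assert_allclose(back.n_cancer, result.timeseries.n_cancer)

    def test_snapshot_agrees_with_census(self, rng):
        cfg = load_fixture("untreated")
        cfg.horizon_days = 2.0
        cfg.output.snapshot_days = [1.0]
        result = run(cfg)
        snap = result.snapshots[0]
        n_cancer_snap = sum(a["kind"] == "cancer" for a in snap["agents"])
        ts = result.timeseries
        row = ts.iloc[(ts.time_h - snap["time_h"]).abs().argmin()]
        assert abs(n_cancer_snap - row.n_cancer) <= row.n_cancer * 0.1 + 3

    def test_sites_unique_in_snapshot(self):
        cfg = load_fixture("untreated")
        cfg.horizon_days = 2.0
        cfg.output.snapshot_days = [2.0]
        result = run(cfg)
        sites = [tuple(a["site"]) for a in result.snapshots[0]["agents"]]
        assert len(sites) == len(set(sites))


class TestPharmacologyPlumbing:
    def test_no_regimen_means_inert_drug_layers(self):
        cfg = RunConfig(horizon_days=2.0)
        ph = precompute_pharmacology(cfg)
        assert ph.occupancy.max() == 0.0
        assert ph.chemo_kill.max() == 0.0
        assert ph.ddri_effect.max() == 0.0

    def test_docetaxel_dose_enters_system_at_dose_time(self):
        cfg = RunConfig(horizon_days=4.0, regimens=[
            RegimenSpec("docetaxel", 0.132, "single", start_day=1.0)])
        ph = precompute_pharmacology(cfg)
        i = ph.index(24.0)
        assert ph.chemo_amount[i] == pytest.approx(0.132)
        assert ph.chemo_kill[i] > 0
        assert ph.chemo_amount[ph.index(12.0)] == 0.0
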
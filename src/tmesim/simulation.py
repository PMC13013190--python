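"""Hybrid simulation orchestrator.

Builds the initial tumour-immune state from a :class:`RunConfig` and
advances a time-driven hybrid loop with macro-step ``dt_h`` (default
0.5 h):

1. apply dose events due in the step (radiation fractions act on the
   state; drug boluses enter the precomputed PK trajectories);
2. advance the deterministic layers — compartmental PK (precomputed, since
   it does not depend on the stochastic state) and the oxygen PDE;
3. advance clocks: cancer phase/delay clocks, immune ageing and lifespan
   clearance, oxygen- and crowding-driven quiescence / reactivation /
   necrosis evaluated at the step boundary;
4. apply per-step treatment death draws (chemotherapy on G2/M cells and,
   configurably, immune cells; DDR inhibitor on S-phase cells) using
   oxygen-scaled local concentrations;
5. run exact-Gillespie events within the step with propensities frozen at
   the step start;
6. record census/rate/PK outputs at the configured cadence.

The run stops at the horizon, at cancer extinction, or when the total
agent count reaches the lethal-size ceiling (1e6 agents).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .agents import (EFFECTOR, G0, G1, G2, M, S, SUPPRESSOR, CancerCell,
                     ImmuneCell, advance_cycle, enter_quiescence,
                     quiescence_trigger, reactivate)
from .config import RunConfig
from .lattice import Lattice, Site
from .oxygen_field import (NECROTIC, OxygenField, advance_oxygen,
                           classify_oxygen)
from .pkpd import (DDRI, DOCETAXEL, PD1_ANTIBODY, RADIATION, DoseEvent,
                   build_schedule, chemo_death_probability, chemo_kill_rate,
                   ddr_effect, integrate_pk, local_concentration,
                   merge_schedules, occupancy_trajectory,
                   one_compartment_model, pd1_antibody_model,
                   mg_per_m2_to_mg)
from .radiotherapy import (RadiationHistory, apply_fraction,
                           rt_infiltration_boost)
from .state import EventLog, SimulationState
from .stochastic_engine import compute_propensities, run_gillespie_window

NECROSIS_DEATH = "necrosis_death"
IMMUNE_LIFESPAN_DEATH = "immune_lifespan_death"
CHEMO_CANCER_DEATH = "chemo_cancer_death"
CHEMO_IMMUNE_DEATH = "chemo_immune_death"
DDRI_CANCER_DEATH = "ddri_cancer_death"

STOP_HORIZON = "horizon"
STOP_EXTINCTION = "extinction"
STOP_LETHAL = "lethal_size"


@dataclass
class Pharmacology:
    """Precomputed deterministic drug layers on the macro-step grid."""

    grid: np.ndarray                       # hours
    occupancy: np.ndarray                  # PD1 receptor occupancy in [0, 1]
    chemo_amount: np.ndarray               # docetaxel amount in system (g)
    chemo_kill: np.ndarray                 # K(t), per h
    ddri_conc: np.ndarray                  # DDRi central amount (mg)
    ddri_effect: np.ndarray                # Emax effect, per h
    pd1_trajectories: dict[str, np.ndarray] = field(default_factory=dict)
    chemo_start_h: float | None = None
    radiation_doses: list[DoseEvent] = field(default_factory=list)

    def index(self, t: float) -> int:
        return int(np.clip(np.searchsorted(self.grid, t + 1e-9) - 1,
                           0, len(self.grid) - 1))


@dataclass
class RunResult:
    config: RunConfig
    timeseries: pd.DataFrame
    snapshots: list[dict[str, Any]]
    event_log: EventLog
    final_state: SimulationState
    stop_reason: str
    pharmacology: Pharmacology
    radiation_history: RadiationHistory


# -- initialisation --------------------------------------------------------

def _packed_sphere_sites(lattice: Lattice, n: int) -> list[Site]:
    """The n sites closest to the lattice centre (densest packing)."""
    nx, ny, nz = lattice.extents
    centre = np.array([(nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2])
    coords = np.array(np.meshgrid(range(nx), range(ny), range(nz),
                                  indexing="ij")).reshape(3, -1).T
    d2 = ((coords - centre) ** 2).sum(axis=1)
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], d2))
    return [tuple(coords[i]) for i in order[:n]]


def _initial_phase(config: RunConfig, rng: np.random.Generator) -> tuple[str, float]:
    cyc = config.cycle
    if config.initial_phases == "all_g1":
        return G1, 0.0
    u = rng.uniform(0.0, cyc.total_h)
    for phase in (G1, S, G2, M):
        dur = cyc.duration(phase)
        if u < dur:
            return phase, float(u)
        u -= dur
    return M, cyc.m_h * 0.999


def initialize(config: RunConfig, rng: np.random.Generator) -> SimulationState:
    """Seed the initial state: a compact PDL1-negative tumour nodule at the
    lattice centre plus immune cells per the 1:100 seeding ratio, with the
    oxygen field at the fully oxygenated initial condition (1 everywhere).
    """
    lattice = Lattice(config.lattice_extents)
    capacity = np.prod(config.lattice_extents)
    if config.initial_cancer + config.initial_immune > capacity:
        raise ValueError("initial agents exceed lattice capacity")
    oxygen = OxygenField(config.lattice_extents, boundary_value=1.0)
    state = SimulationState(
        lattice=lattice, oxygen=oxygen,
        immune_lifespan=config.immune.lifespan_h,
        immune_max_divisions=config.immune.max_divisions,
        immune_time_to_division=config.immune.time_to_division_h,
    )
    for site in _packed_sphere_sites(lattice, config.initial_cancer):
        phase, clock = _initial_phase(config, rng)
        state.add_cancer(CancerCell(site=site, phase=phase, phase_clock=clock))
    for _ in range(config.initial_immune):
        site = lattice.random_free_site(rng)
        if site is None:
            raise ValueError("no free site for immune seeding")
        role = (EFFECTOR if rng.uniform() < config.immune.effector_fraction
                else SUPPRESSOR)
        state.add_immune(ImmuneCell(
            site=site, role=role, lifespan=config.immune.lifespan_h,
            max_divisions=config.immune.max_divisions,
            time_to_division=config.immune.time_to_division_h))
    return state


# -- deterministic pharmacology --------------------------------------------

def precompute_pharmacology(config: RunConfig) -> Pharmacology:
    """Integrate every drug PK model over the whole horizon up front.

    The compartmental ODEs do not depend on the agent state, so their
    trajectories (and the derived receptor occupancy, chemotherapy kill
    rate and DDRi effect) are evaluated once on the macro-step grid.
    """
    horizon_h = config.horizon_days * 24.0
    grid = np.arange(0.0, horizon_h + config.dt_h, config.dt_h)
    schedules = [build_schedule(r) for r in config.regimens]
    doses = merge_schedules(schedules)

    occupancy = np.zeros_like(grid)
    pd1_traj: dict[str, np.ndarray] = {}
    pd1_doses = [DoseEvent(d.time, d.modality, d.amount * config.pd1.body_weight_kg)
                 for d in doses if d.modality == PD1_ANTIBODY]
    if pd1_doses:
        spec = pd1_antibody_model(config.pd1)
        pd1_traj = integrate_pk(spec, pd1_doses, grid)
        occupancy = occupancy_trajectory(spec, pd1_traj)

    chemo_amount = np.zeros_like(grid)
    chemo_kill = np.zeros_like(grid)
    chemo_start = None
    chemo_doses = [d for d in doses if d.modality == DOCETAXEL]
    if chemo_doses:
        chemo_start = chemo_doses[0].time
        traj = integrate_pk(one_compartment_model(config.chemo.elimination),
                            chemo_doses, grid)
        chemo_amount = traj["central"]
        since = np.clip(grid - chemo_start, 0.0, None)
        chemo_kill = np.array([
            chemo_kill_rate(float(t), float(a), config.chemo)
            for t, a in zip(since, chemo_amount)])

    ddri_conc = np.zeros_like(grid)
    ddri_eff = np.zeros_like(grid)
    ddri_doses = [DoseEvent(d.time, d.modality,
                            mg_per_m2_to_mg(d.amount, config.ddr.bsa_m2))
                  for d in doses if d.modality == DDRI]
    if ddri_doses:
        traj = integrate_pk(one_compartment_model(config.ddr.elimination),
                            ddri_doses, grid)
        ddri_conc = traj["central"]
        ddri_eff = np.array([ddr_effect(float(c), config.ddr) for c in ddri_conc])

    radiation = [d for d in doses if d.modality == RADIATION]
    return Pharmacology(grid=grid, occupancy=occupancy,
                        chemo_amount=chemo_amount, chemo_kill=chemo_kill,
                        ddri_conc=ddri_conc, ddri_effect=ddri_eff,
                        pd1_trajectories=pd1_traj, chemo_start_h=chemo_start,
                        radiation_doses=radiation)


# -- census ----------------------------------------------------------------

def census(state: SimulationState) -> dict[str, Any]:
    """Exact integer counts per category at the current time."""
    phases = state.phase_census()
    rec = {
        "time_h": state.time,
        "time_d": state.time / 24.0,
        "n_cancer": state.n_cancer,
        "n_pdl1_pos": state.n_pdl1_positive,
        "n_effector_active": state.n_effectors_active,
        "n_effector_exhausted": state.n_effectors_exhausted,
        "n_suppressor": state.n_suppressors,
        "cum_kills_effector": state.cum_kills_effector,
        "cum_kills_rt": state.cum_kills_rt,
        "cum_kills_chemo": state.cum_kills_chemo,
        "cum_kills_ddri": state.cum_kills_ddri,
        "cum_deaths_natural": state.cum_deaths_natural,
        "cum_deaths_necrosis": state.cum_deaths_necrosis,
        "cum_exhaustions": state.cum_exhaustions,
        "oxygen_min": float(state.oxygen.c.min()),
        "oxygen_mean": float(state.oxygen.c.mean()),
        "receptor_occupancy": state.receptor_occupancy,
        "rt_infiltration_boost": state.rt_infiltration_boost,
    }
    for ph, n in phases.items():
        rec[f"n_{ph}"] = n
    return rec


def take_snapshot(state: SimulationState) -> dict[str, Any]:
    agents = []
    for i, c in state.cancer.items():
        agents.append({"id": i, "kind": "cancer", "site": list(c.site),
                       "phase": c.phase, "pdl1": c.pdl1_positive})
    for i, c in state.immune.items():
        agents.append({"id": i, "kind": "immune", "site": list(c.site),
                       "role": c.role, "exhausted": c.exhausted})
    return {"time_h": state.time, "agents": agents,
            "oxygen_min": float(state.oxygen.c.min()),
            "oxygen_mean": float(state.oxygen.c.mean())}


# -- macro-step helpers ----------------------------------------------------

_NEIGHBOUR_KERNEL = np.ones((3, 3, 3), dtype=np.uint8)
_nb_total_cache: dict[tuple[int, int, int], np.ndarray] = {}


def _free_neighbour_counts(state: SimulationState) -> np.ndarray:
    """Per-site count of free neighbouring sites, vectorised.

    Evaluated once per macro-step from the occupancy mask frozen at the
    step boundary (quiescence/crowding decisions use step-start occupancy).
    """
    from scipy.ndimage import convolve

    ext = state.lattice.extents
    if ext not in _nb_total_cache:
        _nb_total_cache[ext] = convolve(np.ones(ext, dtype=np.uint8),
                                        _NEIGHBOUR_KERNEL,
                                        mode="constant", cval=0) - 1
    occ = state.lattice.occupancy_mask.astype(np.uint8)
    nb_occupied = convolve(occ, _NEIGHBOUR_KERNEL, mode="constant", cval=0) - occ
    return _nb_total_cache[ext] - nb_occupied


def _advance_clocks(state: SimulationState, config: RunConfig) -> None:
    """Oxygen/crowding transitions at the step boundary, then clocks."""
    dt = config.dt_h
    n_free_map = _free_neighbour_counts(state)
    # cancer: necrosis, quiescence entry/exit, cycle advancement
    for cid in list(state.cancer):
        cell = state.cancer[cid]
        o = state.oxygen.level(cell.site)
        if classify_oxygen(o, config.oxygen) == NECROTIC:
            state.remove_cancer(cid)
            state.cum_deaths_necrosis += 1
            state.event_log.append(state.time, NECROSIS_DEATH, cell=cid,
                                   phase=cell.phase, site=cell.site)
            continue
        trigger = quiescence_trigger(o, int(n_free_map[cell.site]),
                                     config.oxygen.quiescence_threshold)
        if cell.phase == G0:
            if not trigger:
                reactivate(cell)
                if not cell.division_ready:
                    advance_cycle(cell, dt, config.cycle)
        else:
            if trigger:
                enter_quiescence(cell)
            elif not cell.division_ready:
                advance_cycle(cell, dt, config.cycle)
        state.sync_ready(cid)
    # immune: ageing and lifespan clearance
    for iid in list(state.immune):
        imm = state.immune[iid]
        imm.age += dt
        imm.since_division += dt
        if imm.age >= imm.lifespan:
            state.remove_immune(iid)
            state.event_log.append(state.time, IMMUNE_LIFESPAN_DEATH, cell=iid,
                                   role=imm.role, exhausted=imm.exhausted)


def _apply_chemo_draws(state: SimulationState, config: RunConfig,
                       kill_rate: float, rng: np.random.Generator) -> None:
    """One chemotherapy application: G2/M cancer cells and (optionally)
    immune cells draw death with p = K_local / K_max."""
    if kill_rate <= 0:
        return
    k_max = config.chemo.k_max
    for cid in list(state.cancer):
        cell = state.cancer[cid]
        if cell.phase not in (G2, M):
            continue
        o = state.oxygen.level(cell.site)
        k_local = local_concentration(kill_rate, o, config.drug_oxygen_scaling)
        p = chemo_death_probability(min(k_local, k_max), k_max)
        if rng.uniform() < p:
            state.remove_cancer(cid)
            state.cum_kills_chemo += 1
            state.event_log.append(state.time, CHEMO_CANCER_DEATH, cell=cid,
                                   phase=cell.phase)
    if config.chemo.affects_immune:
        for iid in list(state.immune):
            imm = state.immune[iid]
            o = state.oxygen.level(imm.site)
            k_local = local_concentration(kill_rate, o, config.drug_oxygen_scaling)
            p = chemo_death_probability(min(k_local, k_max), k_max)
            if rng.uniform() < p:
                state.remove_immune(iid)
                state.event_log.append(state.time, CHEMO_IMMUNE_DEATH,
                                       cell=iid, role=imm.role)


def _apply_ddri_draws(state: SimulationState, config: RunConfig,
                      conc: float, rng: np.random.Generator) -> None:
    """Per-step DDRi death draws on S-phase cancer cells; the Emax effect
    acts as a death rate, p = 1 - exp(-E_local * dt)."""
    if conc <= 0:
        return
    dt = config.dt_h
    for cid in list(state.cancer):
        cell = state.cancer[cid]
        if cell.phase != S:
            continue
        o = state.oxygen.level(cell.site)
        c_local = local_concentration(conc, o, config.drug_oxygen_scaling)
        eff = ddr_effect(c_local, config.ddr)
        p = 1.0 - np.exp(-eff * dt)
        if rng.uniform() < p:
            state.remove_cancer(cid)
            state.cum_kills_ddri += 1
            state.event_log.append(state.time, DDRI_CANCER_DEATH, cell=cid,
                                   phase=cell.phase)


# -- main loop -------------------------------------------------------------

def run(config: RunConfig) -> RunResult:
    """Execute one full simulation and collect all outputs."""
    rng = np.random.default_rng(config.seed)
    state = initialize(config, rng)
    pharm = precompute_pharmacology(config)
    history = RadiationHistory()
    horizon_h = config.horizon_days * 24.0
    dt = config.dt_h

    records: list[dict[str, Any]] = []
    snapshots: list[dict[str, Any]] = []
    snapshot_times = sorted(d * 24.0 for d in config.output.snapshot_days)
    next_snapshot = 0
    next_census = 0.0
    next_chemo_apply: float | None = None
    rad_queue = list(pharm.radiation_doses)
    stop_reason = STOP_HORIZON

    def record_now() -> None:
        rec = census(state)
        props = compute_propensities(state, config.rates)
        for name, val in props.as_dict().items():
            rec[f"prop_{name}"] = val
        i = pharm.index(state.time)
        rec["pd1_occupancy"] = float(pharm.occupancy[i])
        rec["chemo_amount_g"] = float(pharm.chemo_amount[i])
        rec["chemo_kill_rate"] = float(pharm.chemo_kill[i])
        rec["ddri_conc_mg"] = float(pharm.ddri_conc[i])
        rec["ddri_effect"] = float(pharm.ddri_effect[i])
        records.append(rec)

    state.receptor_occupancy = float(pharm.occupancy[0])
    record_now()
    next_census += config.output.census_interval_h

    while state.time < horizon_h - 1e-9:
        t0 = state.time
        i0 = pharm.index(t0)
        state.receptor_occupancy = float(pharm.occupancy[i0])
        state.rt_infiltration_boost = rt_infiltration_boost(t0, history,
                                                            config.radio)

        # 1) dose events due in [t0, t0+dt): radiation acts on the state
        while rad_queue and rad_queue[0].time < t0 + dt - 1e-9:
            frac = rad_queue.pop(0)
            apply_fraction(state, frac.amount, rng, config.radio, history)
        if next_chemo_apply is None and pharm.chemo_start_h is not None:
            next_chemo_apply = pharm.chemo_start_h

        # 2) oxygen PDE
        cycling = [c.site for c in state.cancer.values() if c.phase != G0]
        quiescent = [c.site for c in state.cancer.values() if c.phase == G0]
        advance_oxygen(state.oxygen, cycling, quiescent, config.oxygen, dt)

        # 3) clocks and threshold-driven transitions
        _advance_clocks(state, config)

        # 4) treatment death draws
        if next_chemo_apply is not None and t0 + 1e-9 >= next_chemo_apply:
            _apply_chemo_draws(state, config, float(pharm.chemo_kill[i0]), rng)
            next_chemo_apply += config.chemo.apply_interval_h
        _apply_ddri_draws(state, config, float(pharm.ddri_conc[i0]), rng)

        # 5) stochastic events within the step
        run_gillespie_window(state, config.rates, dt, rng)

        # 6) outputs and stop conditions
        if state.time + 1e-9 >= next_census:
            record_now()
            next_census += config.output.census_interval_h
        while (next_snapshot < len(snapshot_times)
               and state.time + 1e-9 >= snapshot_times[next_snapshot]):
            snapshots.append(take_snapshot(state))
            next_snapshot += 1
        if state.n_cancer == 0:
            stop_reason = STOP_EXTINCTION
            break
        if state.n_agents >= config.lethal_agent_count:
            stop_reason = STOP_LETHAL
            break

    if not records or records[-1]["time_h"] < state.time - 1e-9:
        record_now()
    ts = pd.DataFrame(records)
    return RunResult(config=config, timeseries=ts, snapshots=snapshots,
                     event_log=state.event_log, final_state=state,
                     stop_reason=stop_reason, pharmacology=pharm,
                     radiation_history=history)


# -- output files ----------------------------------------------------------

def write_outputs(result: RunResult, outdir: str | Path) -> dict[str, Path]:
    """Write time series and event log as CSV, snapshots as JSON, and a
    config echo (resolved defaults + seed) for bit-exact reproduction."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "timeseries": out / "timeseries.csv",
        "events": out / "events.csv",
        "snapshots": out / "snapshots.json",
        "config": out / "config.yaml",
        "manifest": out / "manifest.json",
    }
    result.timeseries.to_csv(paths["timeseries"], index=False)
    result.event_log.to_dataframe().to_csv(paths["events"], index=False)
    paths["snapshots"].write_text(json.dumps(result.snapshots))
    result.config.to_yaml(paths["config"])
    manifest = {
        "tmesim_version": __version__,
        "seed": result.config.seed,
        "stop_reason": result.stop_reason,
        "n_events": len(result.event_log),
        "final_time_h": float(result.final_state.time),
        "final_n_cancer": result.final_state.n_cancer,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths
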
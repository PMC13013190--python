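"""Gillespie event engine for the tumour-immune agent-based model.

Event propensities are base rates multiplied by the population quantities
they depend on: cancer division and natural death scale with the number of
cancer cells, PDL1 expression rises with cumulative cancer-cell
eliminations, effector kill scales with the number of active effectors,
effector infiltration grows with cancer burden / effector presence /
immune-mediated kills, suppressor infiltration follows immune-mediated
kills, and effector exhaustion grows with suppressor and PDL1+ counts but
is suppressed by PD1-antibody receptor occupancy.

Waiting times are exponential in the summed propensity and the event type
is drawn proportionally to its propensity (exact SSA).  Contact events
(kill, exhaustion) carry spatial preconditions: a uniformly random
eligible pair is selected and the event is a logged no-op when no pair is
eligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .agents import (EFFECTOR, SUPPRESSOR, ImmuneCell,
                     biased_move, exhaust, make_cancer_daughter,
                     make_immune_daughter, place_daughter,
                     reset_after_division)
from .state import SimulationState

# Event types
CANCER_DIVISION = "cancer_division"
CANCER_NATURAL_DEATH = "cancer_natural_death"
PDL1_EXPRESSION = "pdl1_expression"
EFFECTOR_KILL = "effector_kill"
EFFECTOR_INFILTRATION = "effector_infiltration"
SUPPRESSOR_INFILTRATION = "suppressor_infiltration"
IMMUNE_DIVISION = "immune_division"
IMMUNE_MOVE = "immune_move"
EFFECTOR_EXHAUSTION = "effector_exhaustion"

EVENT_TYPES = (
    CANCER_DIVISION, CANCER_NATURAL_DEATH, PDL1_EXPRESSION, EFFECTOR_KILL,
    EFFECTOR_INFILTRATION, SUPPRESSOR_INFILTRATION, IMMUNE_DIVISION,
    IMMUNE_MOVE, EFFECTOR_EXHAUSTION,
)


class DispatchError(KeyError):
    """Unknown event type passed to :func:`execute_event`."""


@dataclass
class RateParams:
    """Per-hour base rates and dependency coefficients.

    The paper-level statements "increases with" / "depends on" default to
    linear forms with one coefficient per dependency; the exhaustion
    contribution from PDL1+ contact is multiplied by (1 - receptor
    occupancy) so that full checkpoint blockade suppresses it.
    """

    division: float = 0.021           # per cancer cell
    cancer_death: float = 0.02        # per cancer cell
    pdl1_base: float = 2e-6           # per PDL1- cancer cell
    pdl1_per_kill: float = 3e-5       # extra, per cumulative eliminated cell
    effector_kill: float = 0.005      # per active effector
    infiltration_effector: float = 8e-5   # x (N_cancer + w_e N_eff + w_k kills)
    infil_weight_effector: float = 0.5
    infil_weight_kills: float = 0.5
    infiltration_suppressor: float = 4e-4  # per cumulative effector kill
    immune_division: float = 5e-3     # per division-eligible immune cell
    immune_move: float = 0.5          # per active immune cell
    exhaustion: float = 3e-3          # x (c_sup N_sup + c_pdl1 (1-RO) N_pdl1+)
    exh_weight_suppressor: float = 1.0
    exh_weight_pdl1: float = 1.0
    chemotaxis_bias: float = 1.0      # biased-move weight parameter

    def __post_init__(self) -> None:
        for name in ("division", "cancer_death", "pdl1_base", "pdl1_per_kill",
                     "effector_kill", "infiltration_effector",
                     "infiltration_suppressor", "immune_division",
                     "immune_move", "exhaustion"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be nonnegative")


@dataclass
class PropensityVector:
    entries: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.entries.items():
            if v < 0:
                raise ValueError(f"negative propensity for {k}: {v}")

    @property
    def total(self) -> float:
        return float(sum(self.entries.values()))

    def as_dict(self) -> dict[str, float]:
        return dict(self.entries)


def compute_propensities(state: SimulationState, params: RateParams) -> PropensityVector:
    """Assemble the propensity vector from the current population state.

    Recomputed from scratch at every call; an empty state yields all zeros
    (extinction is absorbing).
    """
    n_cancer = state.n_cancer
    n_pdl1_neg = n_cancer - state.n_pdl1_positive
    if n_cancer < 0 or n_pdl1_neg < 0:
        raise ValueError("inconsistent state: negative counts")
    ro = state.receptor_occupancy
    entries = {
        CANCER_DIVISION: params.division * n_cancer,
        CANCER_NATURAL_DEATH: params.cancer_death * n_cancer,
        PDL1_EXPRESSION: (params.pdl1_base
                          + params.pdl1_per_kill * state.cum_kills_total) * n_pdl1_neg,
        EFFECTOR_KILL: params.effector_kill * state.n_effectors_active,
        EFFECTOR_INFILTRATION: (
            params.infiltration_effector
            * (n_cancer
               + params.infil_weight_effector * state.n_effectors_active
               + params.infil_weight_kills * state.cum_kills_effector)
            + state.rt_infiltration_boost),
        SUPPRESSOR_INFILTRATION: params.infiltration_suppressor * state.cum_kills_effector,
        IMMUNE_DIVISION: params.immune_division * state.n_immune_division_eligible,
        IMMUNE_MOVE: params.immune_move * state.n_immune_active,
        EFFECTOR_EXHAUSTION: params.exhaustion * (
            params.exh_weight_suppressor * state.n_suppressors
            + params.exh_weight_pdl1 * max(0.0, 1.0 - ro) * state.n_pdl1_positive),
    }
    return PropensityVector(entries)


def sample_event(
    p: PropensityVector, rng: np.random.Generator
) -> tuple[str | None, float]:
    """Draw (event type, waiting time) from the propensity vector.

    Waiting time ~ Exponential(total); the event type k is chosen with
    probability p_k / total.  A zero total signals "no stochastic event":
    returns (None, inf) and the caller advances to the next deterministic
    event.
    """
    total = p.total
    if total <= 0.0:
        return None, np.inf
    wait = float(rng.exponential(1.0 / total))
    u = rng.uniform(0.0, total)
    acc = 0.0
    for name, val in p.entries.items():
        acc += val
        if u < acc:
            return name, wait
    return name, wait  # numerical edge: return the last nonzero entry


# -- event execution -------------------------------------------------------

def _pick(seq: list, rng: np.random.Generator):
    return seq[int(rng.integers(len(seq)))]


def execute_event(state: SimulationState, event: str, rng: np.random.Generator,
                  params: RateParams) -> SimulationState:
    """Dispatch one sampled event to the agent operations (in place).

    Events whose spatial precondition fails (no eligible agent/pair, no
    free site) are logged as vacuous no-ops.
    """
    t = state.time
    log = state.event_log

    if event == CANCER_DIVISION:
        if not state.ready_cancer:
            log.append(t, event, vacuous=True)
            return state
        cid = _pick(sorted(state.ready_cancer), rng)
        mother = state.cancer[cid]
        site = place_daughter(mother.site, state.lattice, rng)
        if site is None:
            log.append(t, event, vacuous=True, mother=cid)
            return state
        daughter = make_cancer_daughter(mother, site)
        reset_after_division(mother)
        state.sync_ready(cid)
        did = state.add_cancer(daughter)
        log.append(t, event, mother=cid, daughter=did, site=site)

    elif event == CANCER_NATURAL_DEATH:
        if not state.cancer:
            log.append(t, event, vacuous=True)
            return state
        cid = _pick(list(state.cancer), rng)
        cell = state.remove_cancer(cid)
        state.cum_deaths_natural += 1
        log.append(t, event, cell=cid, site=cell.site, phase=cell.phase)

    elif event == PDL1_EXPRESSION:
        negatives = [i for i, c in state.cancer.items() if not c.pdl1_positive]
        if not negatives:
            log.append(t, event, vacuous=True)
            return state
        cid = _pick(negatives, rng)
        state.cancer[cid].pdl1_positive = True
        log.append(t, event, cell=cid)

    elif event == EFFECTOR_KILL:
        pairs = []
        for iid, imm in state.immune.items():
            if imm.role != EFFECTOR or imm.exhausted:
                continue
            for nb in state.lattice.neighbors(imm.site):
                occ = state.lattice.occupant(nb)
                if occ is not None and occ in state.cancer:
                    pairs.append((iid, occ))
        if not pairs:
            log.append(t, event, vacuous=True)
            return state
        iid, cid = _pick(pairs, rng)
        cell = state.remove_cancer(cid)
        state.cum_kills_effector += 1
        log.append(t, event, effector=iid, cancer=cid, site=cell.site,
                   phase=cell.phase)

    elif event in (EFFECTOR_INFILTRATION, SUPPRESSOR_INFILTRATION):
        site = state.lattice.random_free_site(rng)
        if site is None:
            log.append(t, event, vacuous=True)
            return state
        role = EFFECTOR if event == EFFECTOR_INFILTRATION else SUPPRESSOR
        cell = ImmuneCell(site=site, role=role,
                          lifespan=state.immune_lifespan,
                          max_divisions=state.immune_max_divisions,
                          time_to_division=state.immune_time_to_division)
        iid = state.add_immune(cell)
        log.append(t, event, cell=iid, site=site)

    elif event == IMMUNE_DIVISION:
        eligible = [(i, c) for i, c in state.immune.items() if c.division_eligible]
        if not eligible:
            log.append(t, event, vacuous=True)
            return state
        iid, mother = _pick(eligible, rng)
        site = place_daughter(mother.site, state.lattice, rng)
        if site is None:
            log.append(t, event, vacuous=True, mother=iid)
            return state
        mother.division_count += 1
        mother.since_division = 0.0
        daughter = make_immune_daughter(mother, site)
        did = state.add_immune(daughter)
        log.append(t, event, mother=iid, daughter=did, site=site)

    elif event == IMMUNE_MOVE:
        movers = [(i, c) for i, c in state.immune.items() if c.active]
        if not movers:
            log.append(t, event, vacuous=True)
            return state
        iid, cell = _pick(movers, rng)
        targets = (state.cancer_sites_array() if cell.role == EFFECTOR
                   else state.effector_sites_array())
        dst = biased_move(cell, state.lattice, targets,
                          params.chemotaxis_bias, rng)
        if dst is None:
            log.append(t, event, vacuous=True, cell=iid)
            return state
        state.lattice.move(cell.site, dst)
        cell.site = dst
        log.append(t, event, cell=iid, site=dst)

    elif event == EFFECTOR_EXHAUSTION:
        eligible = []
        for iid, imm in state.immune.items():
            if imm.role != EFFECTOR or imm.exhausted:
                continue
            for nb in state.lattice.neighbors(imm.site):
                occ = state.lattice.occupant(nb)
                if occ is None:
                    continue
                if occ in state.cancer and state.cancer[occ].pdl1_positive:
                    eligible.append(iid)
                    break
                if occ in state.immune and state.immune[occ].role == SUPPRESSOR:
                    eligible.append(iid)
                    break
        if not eligible:
            log.append(t, event, vacuous=True)
            return state
        iid = _pick(eligible, rng)
        exhaust(state.immune[iid])
        state.cum_exhaustions += 1
        log.append(t, event, effector=iid)

    else:
        raise DispatchError(f"unknown event type {event!r}")

    return state


def run_gillespie_window(
    state: SimulationState,
    params: RateParams,
    dt: float,
    rng: np.random.Generator,
) -> int:
    """Run exact SSA within one macro-step of length ``dt`` hours.

    Propensities are frozen at the window start (time-driven hybrid
    coupling); the state time is advanced to the window end.  Returns the
    number of events executed.
    """
    p = compute_propensities(state, params)
    t_end = state.time + dt
    n_events = 0
    elapsed = 0.0
    while True:
        event, wait = sample_event(p, rng)
        if event is None or elapsed + wait > dt:
            break
        elapsed += wait
        state.time += wait
        execute_event(state, event, rng, params)
        n_events += 1
    state.time = t_end
    return n_events


# -- small analytic harnesses (independent oracles use these directly) -----

def simulate_birth_death(
    birth: float,
    death: float,
    n0: int,
    t_max: float,
    rng: np.random.Generator,
    n_max: int | None = None,
) -> int:
    """Exact SSA for a linear birth-death process; returns N(t_max).

    Used to validate the sampling machinery against the Yule-process mean
    N0 exp(b t) and the extinction probability (d/b)^N0.  ``n_max`` stops
    a supercritical run early (the residual extinction probability
    (d/b)^n_max is negligible by then).
    """
    n = int(n0)
    t = 0.0
    while n > 0 and (n_max is None or n < n_max):
        p = PropensityVector({"birth": birth * n, "death": death * n})
        event, wait = sample_event(p, rng)
        if event is None or t + wait > t_max:
            break
        t += wait
        n += 1 if event == "birth" else -1
    return n
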
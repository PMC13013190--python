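"""Agent state machines: cancer-cell cycle and quiescence, immune life cycle.

Cancer cells progress through a clocked cell cycle (G1 -> S -> G2 -> M);
completing M makes a cell *division-ready* — the actual division event is
drawn by the stochastic engine.  Hypoxia or crowding sends a cell into
reversible quiescence (G0) that stores the exact cycle position.  Immune
cells are effectors (kill cancer cells, can be exhausted) or suppressors
(exhaust effectors); both age, move, and divide a bounded number of times.

All times are hours; rates elsewhere are per hour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import Lattice, Site, distance_to_nearest

G1, S, G2, M, G0 = "G1", "S", "G2", "M", "G0"
CYCLE_ORDER = (G1, S, G2, M)

EFFECTOR, SUPPRESSOR = "effector", "suppressor"


class StateError(RuntimeError):
    """An agent operation was applied in an invalid state."""


@dataclass
class CellCycleParams:
    """Phase durations in hours (defaults G1=11, S=8, G2=4, M=1)."""

    g1_h: float = 11.0
    s_h: float = 8.0
    g2_h: float = 4.0
    m_h: float = 1.0

    def __post_init__(self) -> None:
        if min(self.g1_h, self.s_h, self.g2_h, self.m_h) <= 0:
            raise ValueError("all phase durations must be positive")

    def duration(self, phase: str) -> float:
        return {G1: self.g1_h, S: self.s_h, G2: self.g2_h, M: self.m_h}[phase]

    @property
    def total_h(self) -> float:
        return self.g1_h + self.s_h + self.g2_h + self.m_h


@dataclass
class TumourScaling:
    """Agent-to-cell scaling: one agent stands for ``cells_per_agent`` cells.

    With the defaults, a 0.1 cm^3 tumour (~1e8 cells at 1e9 cells/cm^3) is
    100 agents and the lethal 1000 cm^3 tumour is 1e6 agents.
    """

    cells_per_agent: float = 1e6
    cell_density_per_cm3: float = 1e9

    def agents_for_volume_cm3(self, volume_cm3: float) -> int:
        return int(round(volume_cm3 * self.cell_density_per_cm3 / self.cells_per_agent))


@dataclass
class CancerCell:
    site: Site
    phase: str = G1
    phase_clock: float = 0.0
    pdl1_positive: bool = False
    pending_delay: float = 0.0
    stored_phase: str | None = None  # set iff phase == G0
    stored_clock: float = 0.0
    division_ready: bool = False
    alive: bool = True


@dataclass
class ImmuneCell:
    site: Site
    role: str = EFFECTOR
    age: float = 0.0
    lifespan: float = 240.0
    division_count: int = 0
    max_divisions: int = 4
    time_to_division: float = 24.0
    since_division: float = 0.0
    exhausted: bool = False
    alive: bool = True

    @property
    def active(self) -> bool:
        """Exhausted effectors are inactive: no move, kill, or division."""
        return self.alive and not self.exhausted

    @property
    def division_eligible(self) -> bool:
        return (self.active and self.since_division >= self.time_to_division
                and self.division_count < self.max_divisions)


# -- cancer cell cycle -----------------------------------------------------

def advance_cycle(cell: CancerCell, dt: float, params: CellCycleParams) -> CancerCell:
    """Advance a cycling cell's phase clock by ``dt`` hours (in place).

    Any pending radiation-induced delay is consumed before the remaining
    phase duration, i.e. delay prolongs residence in the current phase.
    Completing M flags the cell division-ready; it then waits (still in M)
    for a division event.
    """
    if not cell.alive:
        raise StateError("cannot advance a dead cell")
    if cell.phase == G0:
        raise StateError("quiescent cells do not cycle; reactivate first")
    if dt <= 0:
        raise ValueError("dt must be positive")
    remaining = dt
    while remaining > 1e-12 and not cell.division_ready:
        if cell.pending_delay > 0:
            used = min(cell.pending_delay, remaining)
            cell.pending_delay -= used
            remaining -= used
            continue
        dur = params.duration(cell.phase)
        step = min(dur - cell.phase_clock, remaining)
        cell.phase_clock += step
        remaining -= step
        if cell.phase_clock >= dur - 1e-12:
            if cell.phase == M:
                cell.division_ready = True
            else:
                cell.phase = CYCLE_ORDER[CYCLE_ORDER.index(cell.phase) + 1]
                cell.phase_clock = 0.0
    return cell


def reset_after_division(cell: CancerCell) -> None:
    """Restart the cycle at G1 with clock 0 (applied to mother and daughter)."""
    cell.phase = G1
    cell.phase_clock = 0.0
    cell.division_ready = False


def enter_quiescence(cell: CancerCell) -> CancerCell:
    """Store the exact cycle position and switch to G0 (in place)."""
    if cell.phase == G0:
        raise StateError("cell is already quiescent")
    cell.stored_phase = cell.phase
    cell.stored_clock = cell.phase_clock
    cell.phase = G0
    cell.phase_clock = 0.0
    return cell


def reactivate(cell: CancerCell) -> CancerCell:
    """Return to the stored cycle stage exactly (in place)."""
    if cell.phase != G0:
        raise StateError("only quiescent (G0) cells can be reactivated")
    assert cell.stored_phase is not None
    cell.phase = cell.stored_phase
    cell.phase_clock = cell.stored_clock
    cell.stored_phase = None
    cell.stored_clock = 0.0
    return cell


def quiescence_trigger(oxygen: float, n_free: int, quiescence_threshold: float) -> bool:
    """True when a cell should enter (or stay in) G0.

    Triggered by hypoxia (oxygen below the quiescence threshold) or by
    crowding (no free neighbouring site).
    """
    if not 0.0 <= oxygen <= 1.0:
        raise ValueError(f"oxygen level must be in [0, 1], got {oxygen}")
    return oxygen < quiescence_threshold or n_free == 0


# -- division placement ----------------------------------------------------

def place_daughter(mother_site: Site, lattice: Lattice, rng: np.random.Generator) -> Site | None:
    """Uniformly random free neighbour of the mother, or None if surrounded.

    The caller occupies the returned site; a fully surrounded mother is a
    valid no-division outcome, not an error.
    """
    free = lattice.free_neighbors(mother_site)
    if not free:
        return None
    return free[int(rng.integers(len(free)))]


def make_cancer_daughter(mother: CancerCell, site: Site) -> CancerCell:
    """New cancer cell at ``site``; PDL1 status is inherited from the mother."""
    return CancerCell(site=site, phase=G1, phase_clock=0.0,
                      pdl1_positive=mother.pdl1_positive)


def make_immune_daughter(mother: ImmuneCell, site: Site) -> ImmuneCell:
    """New immune cell at ``site``.

    The daughter inherits the (post-division) division count of the mother
    and starts age and time-to-division clocks at zero.
    """
    return ImmuneCell(site=site, role=mother.role, age=0.0,
                      lifespan=mother.lifespan,
                      division_count=mother.division_count,
                      max_divisions=mother.max_divisions,
                      time_to_division=mother.time_to_division,
                      since_division=0.0)


# -- immune behaviour ------------------------------------------------------

def exhaust(effector: ImmuneCell) -> ImmuneCell:
    """Mark an effector exhausted: inactive but still occupying its site."""
    if effector.role != EFFECTOR:
        raise StateError("only effector cells can be exhausted")
    if effector.exhausted:
        raise StateError("effector is already exhausted")
    effector.exhausted = True
    return effector


def biased_move(
    cell: ImmuneCell,
    lattice: Lattice,
    targets: np.ndarray | set[Site],
    bias: float,
    rng: np.random.Generator,
) -> Site | None:
    """Sample a destination among free neighbours, biased toward targets.

    Weight of a candidate site is exp(-bias * d) where d is the distance to
    the nearest target; bias = 0 gives an unbiased uniform walk.  Returns
    the chosen site (the caller performs the lattice move) or None when no
    free neighbour exists (the move event is then a no-op).
    """
    if not cell.active:
        raise StateError("exhausted or dead cells cannot move")
    free = lattice.free_neighbors(cell.site)
    if not free:
        return None
    tarr = targets if isinstance(targets, np.ndarray) else np.asarray(list(targets))
    if bias == 0.0 or tarr.size == 0:
        return free[int(rng.integers(len(free)))]
    d = np.array([distance_to_nearest(s, tarr) for s in free])
    logw = -bias * d
    w = np.exp(logw - logw.max())  # stabilised
    w /= w.sum()
    return free[int(rng.choice(len(free), p=w))]
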
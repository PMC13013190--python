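"""Shared simulation state container and the event log.

``SimulationState`` bundles everything the hybrid loop touches: the
lattice occupancy, the agent registries, the oxygen field, running
counters that feed propensities (cumulative kills by cause), the current
pharmacology couplings (receptor occupancy, radiotherapy infiltration
boost) and the event log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .agents import CancerCell, ImmuneCell, EFFECTOR, SUPPRESSOR, G0
from .lattice import Lattice
from .oxygen_field import OxygenField


class EventLog:
    """Append-only, time-ordered record of every executed event."""

    def __init__(self) -> None:
        self.records: list[dict[str, Any]] = []
        self._last_time = -np.inf

    def append(self, time: float, event: str, **detail: Any) -> None:
        if time < self._last_time - 1e-9:
            raise ValueError("event times must be nondecreasing")
        self._last_time = max(self._last_time, time)
        self.records.append({"time": time, "event": event, **detail})

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        if not self.records:
            return pd.DataFrame(columns=["time", "event"])
        return pd.DataFrame(self.records)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r["event"]] = out.get(r["event"], 0) + 1
        return out


@dataclass
class SimulationState:
    lattice: Lattice
    oxygen: OxygenField
    time: float = 0.0
    cancer: dict[int, CancerCell] = field(default_factory=dict)
    immune: dict[int, ImmuneCell] = field(default_factory=dict)
    next_id: int = 0
    # running counters feeding propensities
    cum_kills_effector: int = 0
    cum_kills_chemo: int = 0
    cum_kills_rt: int = 0
    cum_kills_ddri: int = 0
    cum_deaths_natural: int = 0
    cum_deaths_necrosis: int = 0
    cum_exhaustions: int = 0
    # pharmacology couplings, refreshed each macro-step by the orchestrator
    receptor_occupancy: float = 0.0
    rt_infiltration_boost: float = 0.0
    # template attributes for newly infiltrating immune cells
    immune_lifespan: float = 240.0
    immune_max_divisions: int = 4
    immune_time_to_division: float = 24.0
    # index of division-ready cancer cells (phase M, cycle complete),
    # kept in sync by the orchestrator and engine; see sync_ready()
    ready_cancer: set[int] = field(default_factory=set)
    event_log: EventLog = field(default_factory=EventLog)

    # -- registration ------------------------------------------------------

    def new_id(self) -> int:
        i = self.next_id
        self.next_id += 1
        return i

    def add_cancer(self, cell: CancerCell) -> int:
        i = self.new_id()
        self.lattice.place(cell.site, i)
        self.cancer[i] = cell
        self.sync_ready(i)
        return i

    def sync_ready(self, cid: int) -> None:
        """Update the division-ready index for one cancer cell."""
        cell = self.cancer.get(cid)
        if cell is not None and cell.division_ready and cell.phase != G0:
            self.ready_cancer.add(cid)
        else:
            self.ready_cancer.discard(cid)

    def rebuild_ready_index(self) -> set[int]:
        """The division-ready set recomputed from scratch (for checks)."""
        return {i for i, c in self.cancer.items()
                if c.division_ready and c.phase != G0}

    def add_immune(self, cell: ImmuneCell) -> int:
        i = self.new_id()
        self.lattice.place(cell.site, i)
        self.immune[i] = cell
        return i

    def remove_cancer(self, cid: int) -> CancerCell:
        cell = self.cancer.pop(cid)
        cell.alive = False
        self.lattice.remove(cell.site)
        self.ready_cancer.discard(cid)
        return cell

    def remove_immune(self, iid: int) -> ImmuneCell:
        cell = self.immune.pop(iid)
        cell.alive = False
        self.lattice.remove(cell.site)
        return cell

    # -- counts ------------------------------------------------------------

    @property
    def n_cancer(self) -> int:
        return len(self.cancer)

    @property
    def n_immune(self) -> int:
        return len(self.immune)

    @property
    def n_agents(self) -> int:
        return len(self.cancer) + len(self.immune)

    @property
    def n_pdl1_positive(self) -> int:
        return sum(1 for c in self.cancer.values() if c.pdl1_positive)

    @property
    def n_effectors_active(self) -> int:
        return sum(1 for c in self.immune.values()
                   if c.role == EFFECTOR and not c.exhausted)

    @property
    def n_effectors_exhausted(self) -> int:
        return sum(1 for c in self.immune.values()
                   if c.role == EFFECTOR and c.exhausted)

    @property
    def n_suppressors(self) -> int:
        return sum(1 for c in self.immune.values() if c.role == SUPPRESSOR)

    @property
    def n_immune_active(self) -> int:
        return sum(1 for c in self.immune.values() if c.active)

    @property
    def n_immune_division_eligible(self) -> int:
        return sum(1 for c in self.immune.values() if c.division_eligible)

    @property
    def cum_kills_total(self) -> int:
        """Cancer cells eliminated by effectors, chemotherapy, or radiation."""
        return self.cum_kills_effector + self.cum_kills_chemo + self.cum_kills_rt

    def cancer_sites_array(self) -> np.ndarray:
        """(n, 3) array of cancer-cell sites (chemotaxis targets)."""
        if not self.cancer:
            return np.empty((0, 3), dtype=int)
        return np.array([c.site for c in self.cancer.values()], dtype=int)

    def effector_sites_array(self) -> np.ndarray:
        """(n, 3) array of active-effector sites (suppressor targets)."""
        sites = [c.site for c in self.immune.values()
                 if c.role == EFFECTOR and not c.exhausted]
        if not sites:
            return np.empty((0, 3), dtype=int)
        return np.array(sites, dtype=int)

    def phase_census(self) -> dict[str, int]:
        census = {"G1": 0, "S": 0, "G2": 0, "M": 0, "G0": 0}
        for c in self.cancer.values():
            census[c.phase] += 1
        return census
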
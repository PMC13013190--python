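"""Run configuration: dataclass schema, YAML round trip, shipped fixtures.

A :class:`RunConfig` gathers every module parameter block plus the regimen
list, horizon, macro-step and seed.  Configs are plain YAML with the same
nesting as the dataclasses; unspecified entries take the documented
defaults.  ``load_fixture`` loads the scenario configs shipped with the
package (untreated growth and each treatment regimen at reduced scale).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .agents import CellCycleParams, TumourScaling
from .oxygen_field import OxygenParams
from .pkpd import ChemoParams, DdrParams, Pd1Params, RegimenSpec
from .radiotherapy import RadioParams
from .stochastic_engine import RateParams

CONFIG_SCHEMA_VERSION = 1


@dataclass
class ImmuneParams:
    """Immune agent life-cycle constants (placeholder defaults, hours)."""

    lifespan_h: float = 240.0
    time_to_division_h: float = 24.0
    max_divisions: int = 4
    effector_fraction: float = 1.0   # share of seeded immune cells that are effectors

    def __post_init__(self) -> None:
        if self.lifespan_h <= 0 or self.time_to_division_h <= 0:
            raise ValueError("immune clocks must be positive")
        if not 0.0 <= self.effector_fraction <= 1.0:
            raise ValueError("effector fraction must be in [0, 1]")


@dataclass
class OutputOptions:
    census_interval_h: float = 24.0
    snapshot_days: list[float] = field(default_factory=list)


@dataclass
class RunConfig:
    """Complete configuration of one simulation run."""

    lattice_extents: tuple[int, int, int] = (24, 24, 24)
    initial_cancer: int = 100
    immune_ratio: float = 0.01       # immune : cancer seeding ratio (1:100)
    initial_phases: str = "uniform"  # "uniform" cycle position or "all_g1"
    horizon_days: float = 60.0
    dt_h: float = 0.5                # macro-step of the hybrid loop
    seed: int = 0
    lethal_agent_count: int = 1_000_000
    scaling: TumourScaling = field(default_factory=TumourScaling)
    cycle: CellCycleParams = field(default_factory=CellCycleParams)
    immune: ImmuneParams = field(default_factory=ImmuneParams)
    rates: RateParams = field(default_factory=RateParams)
    oxygen: OxygenParams = field(default_factory=OxygenParams)
    radio: RadioParams = field(default_factory=RadioParams)
    chemo: ChemoParams = field(default_factory=ChemoParams)
    ddr: DdrParams = field(default_factory=DdrParams)
    pd1: Pd1Params = field(default_factory=Pd1Params)
    regimens: list[RegimenSpec] = field(default_factory=list)
    output: OutputOptions = field(default_factory=OutputOptions)
    drug_oxygen_scaling: str = "linear"

    def __post_init__(self) -> None:
        if self.horizon_days <= 0 or self.dt_h <= 0:
            raise ValueError("horizon and macro-step must be positive")
        if self.initial_cancer < 0 or self.immune_ratio < 0:
            raise ValueError("initial counts must be nonnegative")

    @property
    def initial_immune(self) -> int:
        return int(round(self.initial_cancer * self.immune_ratio))

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["lattice_extents"] = list(self.lattice_extents)
        d["schema_version"] = CONFIG_SCHEMA_VERSION
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data)
        data.pop("schema_version", None)
        nested = {
            "scaling": TumourScaling, "cycle": CellCycleParams,
            "immune": ImmuneParams, "rates": RateParams,
            "oxygen": OxygenParams, "radio": RadioParams,
            "chemo": ChemoParams, "ddr": DdrParams, "pd1": Pd1Params,
            "output": OutputOptions,
        }
        kwargs: dict[str, Any] = {}
        for key, value in data.items():
            if key in nested and isinstance(value, dict):
                kwargs[key] = nested[key](**value)
            elif key == "regimens":
                kwargs[key] = [RegimenSpec(**r) if isinstance(r, dict) else r
                               for r in value]
            elif key == "lattice_extents":
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def fixture_names() -> list[str]:
    """Names of the scenario configs shipped with the package."""
    pkg = resources.files("tmesim") / "configs"
    return sorted(p.name.removesuffix(".yaml") for p in pkg.iterdir()
                  if p.name.endswith(".yaml"))


def load_fixture(name: str) -> RunConfig:
    """Load a shipped scenario config by name (see :func:`fixture_names`)."""
    pkg = resources.files("tmesim") / "configs" / f"{name}.yaml"
    with resources.as_file(pkg) as path:
        return RunConfig.from_yaml(path)
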
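"""Reaction-diffusion oxygen field on the lattice.

Oxygen (relative concentration in [0, 1]) diffuses from the periphery of
the grid — the boundary faces are held at a fixed value, emulating supply
from surrounding vascularised tissue — and is consumed at cancer-cell
sites.  Actively cycling cells consume at rate ``k_o``; quiescent cells at
the reduced rate ``q_c * k_o``.  Threshold levels on the local oxygen
concentration drive proliferation / quiescence / necrosis decisions.

The PDE  dc/dt = D lap(c) - k_o chi_cycling - q_c k_o chi_quiescent  is
discretised with a 7-point face-neighbour Laplacian on a unit grid and
explicit Euler in time (stability guard dt <= 1/(6 D)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .lattice import Site


class ConfigurationError(ValueError):
    """Invalid oxygen-field configuration (thresholds or time step)."""


PROLIFERATIVE, QUIESCENT_LEVEL, NECROTIC = "proliferative", "quiescent", "necrotic"


@dataclass
class OxygenParams:
    """Diffusion/consumption constants and behavioural thresholds.

    All defaults are assumed values (relative units, per hour on a unit
    lattice spacing) intended to keep a desk-scale tumour well oxygenated
    with a mild core depression; they are meant to be replaced when
    calibrating to measured gradients.
    """

    diffusion: float = 2.0          # D, lattice^2 / h
    consumption: float = 0.3        # k_o, per h per cycling-cell site
    quiescent_factor: float = 0.1   # q_c in [0, 1]
    quiescence_threshold: float = 0.5
    necrosis_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.diffusion <= 0:
            raise ConfigurationError("diffusion coefficient must be positive")
        if self.consumption < 0:
            raise ConfigurationError("consumption rate must be nonnegative")
        if not 0.0 <= self.quiescent_factor <= 1.0:
            raise ConfigurationError("quiescent factor must be in [0, 1]")
        if not self.necrosis_threshold < self.quiescence_threshold:
            raise ConfigurationError(
                "necrosis threshold must be below the quiescence threshold")

    @property
    def max_stable_dt(self) -> float:
        return 1.0 / (6.0 * self.diffusion)


class OxygenField:
    """Per-site relative oxygen concentration with a fixed boundary.

    By default every face of the grid is held at ``boundary_value``
    (oxygen enters from the periphery).  Alternatively a set of vessel
    sites can be supplied as the fixed-concentration source set, a hook
    for modelling blood vessels at specific grid points.
    """

    def __init__(
        self,
        extents: Iterable[int],
        boundary_value: float = 1.0,
        initial_value: float | None = None,
        vessel_sites: Iterable[Site] | None = None,
    ):
        self.extents = tuple(int(e) for e in extents)
        if not 0.0 <= boundary_value <= 1.0:
            raise ConfigurationError("boundary value must be in [0, 1]")
        self.boundary_value = float(boundary_value)
        init = boundary_value if initial_value is None else float(initial_value)
        self.c = np.full(self.extents, init, dtype=float)
        self.vessel_sites = tuple(vessel_sites) if vessel_sites is not None else None
        self._impose_boundary()

    def _impose_boundary(self) -> None:
        if self.vessel_sites is None:
            for ax in range(3):
                sl0 = [slice(None)] * 3
                sl1 = [slice(None)] * 3
                sl0[ax] = 0
                sl1[ax] = -1
                self.c[tuple(sl0)] = self.boundary_value
                self.c[tuple(sl1)] = self.boundary_value
        else:
            for s in self.vessel_sites:
                self.c[s] = self.boundary_value

    def level(self, site: Site) -> float:
        return float(self.c[site])

    def copy(self) -> "OxygenField":
        new = OxygenField.__new__(OxygenField)
        new.extents = self.extents
        new.boundary_value = self.boundary_value
        new.c = self.c.copy()
        new.vessel_sites = self.vessel_sites
        return new


def _laplacian(c: np.ndarray) -> np.ndarray:
    """7-point Laplacian on the interior; boundary entries are unused."""
    lap = np.zeros_like(c)
    lap[1:-1, 1:-1, 1:-1] = (
        c[2:, 1:-1, 1:-1] + c[:-2, 1:-1, 1:-1]
        + c[1:-1, 2:, 1:-1] + c[1:-1, :-2, 1:-1]
        + c[1:-1, 1:-1, 2:] + c[1:-1, 1:-1, :-2]
        - 6.0 * c[1:-1, 1:-1, 1:-1]
    )
    return lap


def step_oxygen(
    field: OxygenField,
    cycling_sites: Iterable[Site],
    quiescent_sites: Iterable[Site],
    params: OxygenParams,
    dt: float,
) -> OxygenField:
    """One explicit finite-difference step of the oxygen PDE (in place).

    Raises :class:`ConfigurationError` before stepping when ``dt`` violates
    the explicit-scheme stability bound dt <= 1/(6 D).  Values are clipped
    at 0 and the boundary condition is re-imposed after the step.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    if dt > params.max_stable_dt + 1e-12:
        raise ConfigurationError(
            f"dt={dt} exceeds stability bound {params.max_stable_dt:.4g} "
            f"for D={params.diffusion}")
    sink = np.zeros_like(field.c)
    for s in cycling_sites:
        sink[s] += params.consumption
    for s in quiescent_sites:
        sink[s] += params.quiescent_factor * params.consumption
    field.c += dt * (params.diffusion * _laplacian(field.c) - sink)
    np.clip(field.c, 0.0, 1.0, out=field.c)  # relative units live in [0, 1]
    field._impose_boundary()
    return field


def advance_oxygen(
    field: OxygenField,
    cycling_sites: Iterable[Site],
    quiescent_sites: Iterable[Site],
    params: OxygenParams,
    dt_total: float,
    dt_sub: float | None = None,
) -> OxygenField:
    """Advance by ``dt_total`` using stability-respecting substeps."""
    if dt_sub is None:
        dt_sub = 0.9 * params.max_stable_dt
    cyc = list(cycling_sites)
    qui = list(quiescent_sites)
    # a uniform field with no consumers is a fixed point of the scheme
    if (params.consumption == 0.0 or (not cyc and not qui)) \
            and np.all(field.c == field.boundary_value):
        return field
    n = max(1, int(np.ceil(dt_total / dt_sub)))
    h = dt_total / n
    for _ in range(n):
        step_oxygen(field, cyc, qui, params, h)
    return field


def classify_oxygen(level: float, params: OxygenParams) -> str:
    """Map a local oxygen level to proliferative / quiescent / necrotic.

    Half-open convention: necrotic iff level < necrosis threshold;
    quiescent iff necrosis <= level < quiescence threshold; proliferative
    otherwise (a level exactly at the quiescence threshold proliferates).
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"oxygen level must be in [0, 1], got {level}")
    if level < params.necrosis_threshold:
        return NECROTIC
    if level < params.quiescence_threshold:
        return QUIESCENT_LEVEL
    return PROLIFERATIVE
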
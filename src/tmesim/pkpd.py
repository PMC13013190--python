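"""Deterministic pharmacology: schedules, compartmental PK, and PD effects.

Four modalities are supported:

* **PD1 antibody** (pembrolizumab-like, 2 mg/kg Q3W): a linear
  compartmental model (central, peripheral, tumour vasculature, endosomal,
  intestinal) plus a second-order drug-receptor binding term producing a
  drug-PD1 complex; the receptor occupancy (complex / total receptor)
  scales down the effector-exhaustion propensity.
* **Radiotherapy** dose events (handled by :mod:`tmesim.radiotherapy`).
* **Docetaxel chemotherapy** (0.132 g Q3W): a K/PD model in which the kill
  rate K(t) = eps * A(t) * exp(-lambda t) follows the amount in the system
  A(t) and declines exponentially with the resistance parameter lambda;
  the per-application death probability is K / K_max.
* **DDR inhibitor** (210 mg/m^2 weekly): compartmental PK with a
  saturating Emax concentration-effect model, killing S-phase cells.

Because no blood vessels are modelled, the local drug concentration at a
lattice site is the systemic concentration scaled by a nondecreasing
function of the local relative oxygen level (default: multiplied by it),
so the poorly-perfused core sees less drug than the edge.

All compartment parameters shipped here are placeholder defaults with
literature-scale magnitudes; they are plain config entries meant to be
replaced by published model constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp


class ScheduleError(ValueError):
    """Unknown or inconsistent regimen specification."""


PD1_ANTIBODY, DOCETAXEL, DDRI, RADIATION = ("pd1_antibody", "docetaxel",
                                            "ddri", "radiation")

HOURS_PER_DAY = 24.0
HOURS_PER_WEEK = 168.0


@dataclass(frozen=True)
class DoseEvent:
    """A single administration: time (h), modality, and amount.

    Amount units are modality-specific: mg for the antibody and DDRi
    (after BSA conversion), g for docetaxel, Gy for radiation.
    """

    time: float
    modality: str
    amount: float

    def __post_init__(self) -> None:
        if self.time < 0 or self.amount < 0:
            raise ValueError("dose time and amount must be nonnegative")


@dataclass
class RegimenSpec:
    """A dosing pattern compiled to sorted :class:`DoseEvent` lists.

    Patterns:
      * ``"q3w"`` / ``"q2w"`` / ``"q1w"`` / ``"weekly"`` — every n weeks,
        ``n_doses`` administrations;
      * ``"5_per_week"`` — fractions on days 0-4 of each of
        ``duration_weeks`` consecutive weeks (e.g. 2.5 Gy x 5 d/wk x 6 wk
        = 30 fractions).
    """

    modality: str
    amount: float
    pattern: str
    start_day: float = 0.0
    n_doses: int | None = None
    duration_weeks: int | None = None


def mg_per_m2_to_mg(dose_mg_per_m2: float, bsa_m2: float = 1.75) -> float:
    """Convert body-surface-area dosing to an absolute amount in mg."""
    return dose_mg_per_m2 * bsa_m2


def build_schedule(regimen: RegimenSpec) -> list[DoseEvent]:
    """Compile a regimen into a time-sorted list of dose events."""
    start_h = regimen.start_day * HOURS_PER_DAY
    pat = regimen.pattern.lower()
    times: list[float] = []
    if pat in ("q1w", "weekly", "qw"):
        interval, n = HOURS_PER_WEEK, regimen.n_doses
    elif pat == "q2w":
        interval, n = 2 * HOURS_PER_WEEK, regimen.n_doses
    elif pat == "q3w":
        interval, n = 3 * HOURS_PER_WEEK, regimen.n_doses
    elif pat == "single":
        interval, n = 0.0, 1
    elif pat == "5_per_week":
        if regimen.duration_weeks is None:
            raise ScheduleError("5_per_week pattern requires duration_weeks")
        for week in range(regimen.duration_weeks):
            for day in range(5):
                times.append(start_h + (7 * week + day) * HOURS_PER_DAY)
        return [DoseEvent(t, regimen.modality, regimen.amount) for t in sorted(times)]
    else:
        raise ScheduleError(f"unknown pattern {regimen.pattern!r}")
    if n is None:
        raise ScheduleError(f"pattern {pat!r} requires n_doses")
    times = [start_h + i * interval for i in range(n)]
    return [DoseEvent(t, regimen.modality, regimen.amount) for t in times]


def merge_schedules(schedules: Sequence[list[DoseEvent]]) -> list[DoseEvent]:
    out = [d for s in schedules for d in s]
    return sorted(out, key=lambda d: (d.time, d.modality))


# -- compartmental PK ------------------------------------------------------

@dataclass
class BindingSpec:
    """Second-order association of central drug with a fixed receptor pool.

    d(complex)/dt = kon * C_source * (R_total - complex) - koff * complex
    """

    source: str
    complex_name: str
    r_total: float
    kon: float    # per amount-unit per hour
    koff: float   # per hour

    def __post_init__(self) -> None:
        if self.r_total <= 0:
            raise ValueError("total receptor must be positive")
        if self.kon < 0 or self.koff < 0:
            raise ValueError("binding rate constants must be nonnegative")


@dataclass
class PKModelSpec:
    """Named compartments with linear transfer/elimination, optional binding.

    ``transfers`` maps (src, dst) -> first-order rate constant (per hour);
    ``eliminations`` maps compartment -> first-order loss rate.  Boluses
    are added to ``dosing_compartment`` at dose-event times.
    """

    compartments: list[str]
    transfers: dict[tuple[str, str], float] = field(default_factory=dict)
    eliminations: dict[str, float] = field(default_factory=dict)
    dosing_compartment: str = "central"
    binding: BindingSpec | None = None

    def __post_init__(self) -> None:
        if self.dosing_compartment not in self.compartments:
            raise ValueError("dosing compartment must be a named compartment")
        for (a, b), k in self.transfers.items():
            if k < 0:
                raise ValueError(f"negative transfer rate {a}->{b}")
            if a not in self.compartments or b not in self.compartments:
                raise ValueError(f"transfer {a}->{b} names unknown compartment")
        for c, k in self.eliminations.items():
            if k < 0:
                raise ValueError(f"negative elimination rate for {c}")
            if c not in self.compartments:
                raise ValueError(f"elimination names unknown compartment {c}")
        if self.binding is not None and self.binding.source not in self.compartments:
            raise ValueError("binding source must be a named compartment")

    @property
    def state_names(self) -> list[str]:
        names = list(self.compartments)
        if self.binding is not None:
            names.append(self.binding.complex_name)
        return names


def _rhs(spec: PKModelSpec) -> Callable[[float, np.ndarray], np.ndarray]:
    n = len(spec.compartments)
    idx = {c: i for i, c in enumerate(spec.compartments)}
    A = np.zeros((n, n))
    for (a, b), k in spec.transfers.items():
        A[idx[a], idx[a]] -= k
        A[idx[b], idx[a]] += k
    for c, k in spec.eliminations.items():
        A[idx[c], idx[c]] -= k
    bind = spec.binding
    src = idx[bind.source] if bind is not None else -1

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = A @ y[:n]
        if bind is not None:
            cplx = y[n]
            flux = bind.kon * y[src] * (bind.r_total - cplx) - bind.koff * cplx
            dy = np.append(dy, flux)
            dy[src] -= flux
        return dy

    return rhs


def integrate_pk(
    spec: PKModelSpec,
    doses: list[DoseEvent],
    grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> dict[str, np.ndarray]:
    """Solve the compartmental ODEs over ``grid`` (hours) with bolus dosing.

    Returns one trajectory per state name (compartments plus the complex,
    if any), each evaluated on ``grid``.  Doses outside the grid span are
    ignored; a dose exactly at a grid point contributes from that point on.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing with >= 2 points")
    doses = sorted((d for d in doses if d.time <= grid[-1]), key=lambda d: d.time)
    rhs = _rhs(spec)
    n_states = len(spec.state_names)
    dose_idx = spec.compartments.index(spec.dosing_compartment)

    y = np.zeros(n_states)
    out = np.zeros((n_states, len(grid)))
    t_cur = grid[0]
    k = 0

    def apply_due_boluses(t: float) -> None:
        # a dose exactly at a grid point contributes from that point on
        nonlocal k
        while k < len(doses) and doses[k].time <= t + 1e-9:
            y[dose_idx] += doses[k].amount
            k += 1
        j = np.searchsorted(grid, t - 1e-9)
        if j < len(grid) and abs(grid[j] - t) <= 1e-9:
            out[:, j] = y

    def integrate_to(t_next: float) -> None:
        nonlocal y, t_cur
        if t_next <= t_cur + 1e-12:
            return
        mask = (grid > t_cur + 1e-9) & (grid < t_next - 1e-9)
        t_eval = np.append(grid[mask], t_next)  # always evaluate the endpoint
        sol = solve_ivp(rhs, (t_cur, t_next), y, method="LSODA",
                        t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"PK integration failed: {sol.message}")
        out[:, np.where(mask)[0]] = sol.y[:, :-1]
        y = sol.y[:, -1].copy()
        t_cur = t_next
        j = np.searchsorted(grid, t_next - 1e-9)
        if j < len(grid) and abs(grid[j] - t_next) <= 1e-9:
            out[:, j] = y

    apply_due_boluses(t_cur)
    out[:, 0] = y
    while k < len(doses):
        t_dose = doses[k].time
        integrate_to(t_dose)
        apply_due_boluses(t_dose)
    integrate_to(grid[-1])

    traj = {name: np.clip(out[i], 0.0, None)
            for i, name in enumerate(spec.state_names)}
    return traj


def receptor_occupancy(complex_amount: float, r_total: float) -> float:
    """Fraction of receptors bound; clamped to [0, 1]."""
    if r_total <= 0:
        raise ValueError("total receptor must be positive")
    return float(np.clip(complex_amount / r_total, 0.0, 1.0))


def occupancy_trajectory(spec: PKModelSpec, traj: dict[str, np.ndarray]) -> np.ndarray:
    if spec.binding is None:
        raise ValueError("model has no receptor-binding term")
    cplx = traj[spec.binding.complex_name]
    return np.clip(cplx / spec.binding.r_total, 0.0, 1.0)


# -- chemotherapy K/PD -----------------------------------------------------

@dataclass
class ChemoParams:
    """Docetaxel K/PD constants (per hour; amounts in g)."""

    efficacy: float = 2.0        # eps, per h per g in system
    resistance: float = 6e-4     # lambda, per h (exponential kill-rate decline)
    k_max: float = 0.5           # reference maximum kill rate, per h
    elimination: float = 0.08    # one-compartment PK elimination, per h
    affects_immune: bool = True
    apply_interval_h: float = 24.0

    def __post_init__(self) -> None:
        if min(self.efficacy, self.resistance, self.elimination) < 0 or self.k_max <= 0:
            raise ValueError("chemo parameters must be nonnegative with k_max > 0")


def chemo_kill_rate(t: float, amount: float, params: ChemoParams) -> float:
    """K(t) = eps * amount * exp(-lambda t); t is hours since treatment start.

    The exponential factor models emerging resistance: at fixed amount the
    kill rate declines with rate ``params.resistance``.
    """
    if t < 0:
        raise ValueError("time since treatment start must be nonnegative")
    if amount == 0:
        return 0.0
    return params.efficacy * amount * float(np.exp(-params.resistance * t))


def chemo_death_probability(k: float, k_max: float) -> float:
    """Death probability per application: K / K_max, clipped at 1."""
    if k < 0 or k_max <= 0:
        raise ValueError("kill rates must be nonnegative with k_max > 0")
    if k > k_max:
        warnings.warn("kill rate exceeds K_max; death probability clipped to 1",
                      RuntimeWarning, stacklevel=2)
        return 1.0
    return k / k_max


# -- DDR inhibitor ---------------------------------------------------------

@dataclass
class DdrParams:
    """Emax effect constants for the DNA-damage-response inhibitor.

    ``emax`` is interpreted as a maximal death rate (per hour) applied to
    S-phase cancer cells; ``ec50`` is in mg (amount in the central
    compartment).
    """

    emax: float = 0.02           # per hour
    ec50: float = 50.0           # mg
    elimination: float = 0.08    # one-compartment PK elimination, per h
    bsa_m2: float = 1.75

    def __post_init__(self) -> None:
        if self.emax < 0 or self.ec50 <= 0 or self.elimination < 0:
            raise ValueError("require emax >= 0, ec50 > 0, elimination >= 0")


def ddr_effect(conc: float, params: DdrParams) -> float:
    """Saturating Emax effect: Emax * C / (EC50 + C), in [0, Emax)."""
    if conc < 0:
        raise ValueError("concentration must be nonnegative")
    return params.emax * conc / (params.ec50 + conc)


# -- oxygen-gradient drug scaling ------------------------------------------

def local_concentration(
    systemic: float,
    oxygen: float,
    scaling: str | Callable[[float], float] = "linear",
) -> float:
    """Scale the systemic concentration by local oxygenation.

    Drug reaches a site in proportion to a nondecreasing function of the
    local relative oxygen level (default: the level itself), so the
    hypoxic core sees a lower concentration than the tumour edge.
    """
    if not 0.0 <= oxygen <= 1.0:
        raise ValueError(f"oxygen level must be in [0, 1], got {oxygen}")
    if callable(scaling):
        f = scaling(oxygen)
    elif scaling == "linear":
        f = oxygen
    elif scaling == "none":
        f = 1.0
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return systemic * f


# -- shipped placeholder model builders ------------------------------------

@dataclass
class Pd1Params:
    """PD1-antibody PK/binding placeholder constants (amounts in mg)."""

    dose_mg_per_kg: float = 2.0
    body_weight_kg: float = 70.0
    k_elim_central: float = 0.0015         # per h (long antibody half-life)
    k_central_peripheral: float = 0.01
    k_peripheral_central: float = 0.008
    k_central_tumour_vasculature: float = 0.004
    k_tumour_vasculature_central: float = 0.01
    k_central_endosomal: float = 0.002
    k_endosomal_central: float = 0.001
    k_central_intestinal: float = 0.001
    k_intestinal_elim: float = 0.005
    r_total: float = 1.0                    # normalised receptor pool
    kon: float = 0.01                       # per mg per h
    koff: float = 0.01                      # per h

    @property
    def dose_mg(self) -> float:
        return self.dose_mg_per_kg * self.body_weight_kg


def pd1_antibody_model(params: Pd1Params | None = None) -> PKModelSpec:
    """Compartmental antibody model with the drug-PD1 complex.

    Compartments: central, peripheral, tumour vasculature, endosomal and
    intestinal spaces; central drug binds the PD1 receptor pool to form
    the drug-PD1 complex whose occupancy feeds the exhaustion rate.
    """
    p = params or Pd1Params()
    return PKModelSpec(
        compartments=["central", "peripheral", "tumour_vasculature",
                      "endosomal", "intestinal"],
        transfers={
            ("central", "peripheral"): p.k_central_peripheral,
            ("peripheral", "central"): p.k_peripheral_central,
            ("central", "tumour_vasculature"): p.k_central_tumour_vasculature,
            ("tumour_vasculature", "central"): p.k_tumour_vasculature_central,
            ("central", "endosomal"): p.k_central_endosomal,
            ("endosomal", "central"): p.k_endosomal_central,
            ("central", "intestinal"): p.k_central_intestinal,
        },
        eliminations={"central": p.k_elim_central,
                      "intestinal": p.k_intestinal_elim},
        dosing_compartment="central",
        binding=BindingSpec(source="central", complex_name="drug_pd1_complex",
                            r_total=p.r_total, kon=p.kon, koff=p.koff),
    )


def one_compartment_model(k_elim: float) -> PKModelSpec:
    """Single central compartment with first-order elimination."""
    return PKModelSpec(compartments=["central"],
                       eliminations={"central": k_elim},
                       dosing_compartment="central")
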
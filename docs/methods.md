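# Methods

`tmesim` simulates a tumour microenvironment (TME) as a multiscale hybrid
model: a stochastic agent-based model of cancer and immune cells on a 3D
lattice, coupled to a deterministic oxygen reaction–diffusion field and
deterministic pharmacology (ODE compartment models and closed-form
kinetic–pharmacodynamic rates) for four treatment modalities.  This note
records the model, its assumptions, the default parameters and why they
were chosen, the numerical scheme, and what the shipped scenarios do and
do not demonstrate.

## Agents and scaling

One agent represents 10⁶ biological cells at an assumed density of 10⁹
cells/cm³, so a 0.1 cm³ tumour is 100 agents, a 1 cm³ tumour is 1000, and
the lethal 1000 cm³ burden is 10⁶ agents (the run's hard stop).  Agents
occupy single sites of a bounded 3D grid (one agent per site, Moore
neighbourhood of up to 26 sites, non-periodic clipped boundaries).  Three
agent types exist:

* **Cancer cells** carry a clocked cell cycle (G1 11 h → S 8 h → G2 4 h →
  M 1 h), a PDL1 expression flag, a pending radiation-induced cycle delay,
  and a reversible quiescent state (G0) that stores the exact cycle
  position.  Completing M makes a cell *division-ready*; the division
  itself is an event of the stochastic engine (below), so the realised
  division rate is the smaller of the cycle flux and the engine's demand.
  Hypoxia (local oxygen below a threshold) or crowding (no free
  neighbouring site) sends a cell to G0; when the condition clears it
  resumes exactly where it stopped.  Oxygen below the necrosis threshold
  kills the cell.
* **Immune effector cells** chemotax toward cancer cells, kill adjacent
  cancer cells, divide a bounded number of times, age out at their
  lifespan, and can be *exhausted* by contact with a PDL1⁺ cancer cell or
  a suppressor cell; an exhausted effector no longer moves, kills or
  divides but occupies its site until its lifespan ends.
* **Immune suppressor cells** chemotax toward effectors and provide the
  suppressor arm of the exhaustion event.

## Stochastic engine

Events are drawn with the exact Gillespie algorithm from propensities that
are base rates multiplied by the stated population quantities:

| event | propensity |
|---|---|
| cancer division | r_div · N_cancer (executed on a random division-ready cell) |
| cancer natural death | r_death · N_cancer |
| PDL1 expression | (r_pdl1 + c_kill · kills_total) · N_PDL1⁻ |
| effector kill | r_kill · N_active_effectors (needs adjacency) |
| effector infiltration | k_e · (N_cancer + w_e N_eff + w_k kills_eff) + RT boost |
| suppressor infiltration | k_s · kills_eff |
| immune division | r_idiv · N_division_eligible |
| immune move | r_move · N_active_immune |
| effector exhaustion | r_exh · (N_sup + (1 − RO) · N_PDL1⁺) (needs adjacency) |

`kills_total` counts cancer cells eliminated by effectors, chemotherapy
and radiation since the start (adaptive immune resistance); `RO` is the
PD1-antibody receptor occupancy, so full blockade removes the
PDL1-contact route to exhaustion.  Contact events select a uniformly
random eligible pair and are logged no-ops when none exists.  "Increases
with"-type dependencies are linear with one coefficient each; all forms
are plain config entries.

**Hybrid coupling.**  Deterministic layers (oxygen PDE, drug PK, clocks,
scheduled doses) advance on a fixed macro-step Δt (default 0.5 h); the SSA
runs inside each macro-step with propensities frozen at the step start
(time-driven hybrid).  Threshold-driven transitions (quiescence,
reactivation, necrosis) are evaluated at macro-step boundaries.

## Oxygen field

Relative oxygen c ∈ [0, 1] obeys ∂c/∂t = D∇²c − k_o·χ_cycling −
q_c·k_o·χ_quiescent with the grid faces held at 1 (supply from the
periphery; a vessel-site boundary set is available as a hook).  The
scheme is the 7-point Laplacian with explicit Euler substeps guarded by
dt ≤ 1/(6D).  Defaults (assumed, in relative units per hour on unit
spacing): D = 2, k_o = 0.3, q_c = 0.1, quiescence threshold 0.5, necrosis
threshold 0.05.  These produce a mild hypoxic core in a packed nodule of
a few hundred agents — enough to exercise the quiescence/necrosis logic
and the oxygen scaling of drugs and radiosensitivity — without collapsing
the population.  Threshold comparisons are half-open: a level exactly at
the quiescence threshold proliferates.

## Treatments

Schedules are compiled from regimen specs (QnW, weekly, 5-days-per-week ×
n weeks) into dose events.  Because the drug ODEs do not depend on the
agent state, all PK trajectories are integrated once (LSODA, bolus dosing)
on the macro-step grid before the hybrid loop; radiation fractions act on
the state in-loop.

* **PD1 antibody** (2 mg/kg Q3W, 70 kg): linear compartments named
  central / peripheral / tumour-vasculature / endosomal / intestinal plus
  a second-order binding term to a normalised PD1 receptor pool.
  Occupancy = complex / total receptor multiplies the exhaustion
  propensity by (1 − RO).  The shipped constants are placeholders with an
  antibody-like half-life (~19 d); at the default regimen occupancy
  plateaus above 95%, the intended near-total blockade.
* **Radiotherapy** (2.5 Gy fractions): per-cell survival
  S = exp(−s_phase (α·d_eff + β·d_eff²)) with d_eff = OMF(oxygen)·dose.
  Phase sensitivities s_S = s_G2 = s_M = 1 > s_G1 = s_G0 = 0.5; immune
  cells use the S/G2/M class.  The oxygen modification factor is the
  saturating form OMF(o) = [(o + k_m/OER)/(o + k_m)]·[(1 + k_m)/(1 +
  k_m/OER)] (OER = 3, k_m = 0.05), normalised to 1 at full oxygenation
  with floor ≈ 1/OER.  Defaults α = 0.035 /Gy, β = 0.0035 /Gy² give
  ≈ 0.90 survival per 2.5 Gy oxic fraction, i.e. ≈ 96% kill over a
  30-fraction course before regrowth and immune effects.  Surviving G1/G2
  cells draw a cycle delay uniform on [1, 9] h (accumulating across
  fractions), the lattice signature of p53/p21 arrest.  Radiation kills
  feed a deterministic effector-infiltration boost amplitude · cum_kills ·
  Σ_f kernel(t − t_f), zero within a 48 h lag after each fraction (initial
  immune suppression) then decaying over 120 h — a stand-in with the
  qualitative properties of published delayed post-RT infiltration
  responses.
* **Docetaxel** (0.132 g Q3W; the printed dose for BSA 1.75 m² at
  75 mg/m², which is 131.25 mg — the printed value is used): K/PD kill
  rate K(t) = ε·A(t)·e^(−λt) with A(t) the amount in a one-compartment
  system (elimination 0.08 /h), ε = 2 /h/g, resistance λ = 6·10⁻⁴ /h
  (kill rate halves in ~48 d).  Death probability per application is
  K_local/K_max (K_max = 0.5 /h), applied at a fixed daily cadence —
  tying the probability to a fixed application interval rather than the
  macro-step keeps the dose–response independent of Δt.  Only G2/M cancer
  cells (and, by default, immune cells) are eligible; G0 cells are
  insensitive.
* **DDR inhibitor** (210 mg/m² weekly, BSA-converted): one-compartment PK
  (elimination 0.08 /h) with Emax effect E = Emax·C/(EC50 + C)
  (Emax = 0.02 /h, EC50 = 50 mg) treated as a death rate on S-phase
  cancer cells, applied per macro-step as p = 1 − e^(−E·Δt).

Local drug concentration at a site is the systemic value multiplied by
the local relative oxygen level (configurable), so the tumour core sees
less drug than the edge.

## Default rates and why

The event rates are not published; the defaults were chosen once to
realise the qualitative regime the scenarios describe, at desk scale:

* division demand 0.021 /h against natural death 0.02 /h — a
  slightly supercritical population (net ≈ 0.001 /h, ~29-day doubling)
  whose M-phase census is visibly inflated by division-ready cells
  waiting for the division event, as a demand-limited cycle implies;
* effector kill 0.005 /h per effector, infiltration 8·10⁻⁵ × burden,
  suppressor infiltration 4·10⁻⁴ × kills, exhaustion 3·10⁻³ with PDL1
  feedback 3·10⁻⁵ per kill — an immune response strong enough to kill
  and thereby trigger adaptive PDL1 expression, but reliably overtaken
  by exhaustion so the untreated tumour escapes (the untreated scenario's
  defining behaviour);
* immune lifespan 240 h, time-to-division 24 h, max 4 divisions,
  chemotaxis bias 1 (exponential-distance weighting, unbiased at 0).

## Shipped scenarios

Eight fixture configs reproduce the regimen *structure* of the studied
scenarios at reduced scale (24³ lattice, 100–400 initial agents, 49–60
day horizons, treatment start days pulled forward accordingly): untreated
growth; PD1 antibody 2 mg/kg Q3W; radiotherapy 2.5 Gy × 5 d/wk; docetaxel
0.132 g Q3W; DDRi 210 mg/m² weekly; and PD1+RT, DDRi+RT, chemo+RT
combinations.  They are study conditions, not calibrated patients: the
passing checks demonstrate the mechanisms (escape via immunosuppression,
post-RT census redistribution and G0 emptying, weekly S-phase
oscillation under DDRi, burst kills with resistance decay under
chemotherapy), not clinical numbers.

What the scenarios do **not** emulate: vasculature (oxygen and drug enter
from the periphery only), immune subtypes beyond effector/suppressor,
T-cell priming and trafficking, cytokine fields, off-lattice mechanics,
inter-patient variability.  Quantitative figure-level outcomes
(extinction days, exact percentage reductions) depend on unpublished
parameter tables and are out of scope.

## Numerical and design choices

* Determinism: one seeded generator per run; dict iteration is insertion
  ordered, index sets are drawn from sorted order, so a fixed seed
  reproduces every output byte-for-byte.
* Neighbour ordering is lexicographic by offset; eligible-pair selection
  for contact events is uniform.
* The division-ready and crowding computations are vectorised
  (occupancy-mask convolution) but semantically identical to per-cell
  scans; a rebuild-from-scratch check is part of the test suite.
* Necrotic cells are removed immediately (no persistent debris occupying
  the site); cumulative kill counters do not decay.
* Initial phases are uniform over cycle position (configurable to
  synchronised all-G1); initial geometry is densest-sphere packing around
  the lattice centre (configurable to random scatter).
* The chemo clip K > K_max → p = 1 emits a warning rather than an error.

## Known limitations

Near-criticality makes individual trajectories noisy: at the default
rates a small fraction of seeds shows transient decline of the untreated
tumour before exhaustion rescues it; replicate means are stable.  The
paper-scale census pattern in which the S phase nearly empties during
fractionated radiotherapy is stronger than uniform 1–9 h delays can
produce; the implementation reproduces the redistribution direction
(G2:S ratio rising, G0 emptying) rather than its full magnitude.
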
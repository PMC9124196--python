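# Methods

`dcisim` is a multiscale, lattice-free agent-based model of early ductal
carcinoma in situ (DCIS) growing inside a rigid segment of mammary duct,
coupled to quasi-steady reaction–diffusion fields for oxygen, estrogen,
amphiregulin (AREG) and fibroblast growth factor (FGF), together with the
perturbation-analysis machinery (Latin hypercube sampling, multivariate
regression, dose–response fits) used to interrogate it. This note documents
the model, its assumptions, the tunable parameters, the numerical choices,
and the design decisions taken where the design was genuinely open.

## The model

**Domain.** A cylinder of length `duct_length` and lumen radius
`duct_inner_diameter / 2`, axis along x with the origin at the duct
midpoint. The duct wall (myoepithelial/luminal epithelial bilayer) is a
rigid boundary, not a population of mechanical agents; intraluminal growth
only. The lesion is initiated at t = 0 by `n_tic` (default 5)
tumor-initiating stem cells placed adjacently on the +y interior wall at
x = 0.

**Cells.** Each agent is a sphere (mature radius 5 µm; newborns start at
half volume and grow linearly in volume over their cycle). The lineage
hierarchy is stem → progenitor → terminally differentiated, crossed with a
status overlay {active, quiescent, hypoxic, necrotic, calcified}:

* *Stem* cells divide without limit. Each division yields a stem daughter
  with probability ω_SC = 0.12, otherwise a progenitor daughter assigned
  ER+ with probability ω_SC,± = 0.5 (else ER−). The mother remains stem.
* *Progenitors* divide up to P_max = 18 generations; each division yields a
  progenitor daughter with probability ω_P = 0.75 (else a terminally
  differentiated daughter), inheriting the mother's ER status. Progenitor
  daughters of progenitor mothers inherit the mother's incremented
  generation count — without inheritance a progenitor lineage would be
  immortal and growth arrest could never occur. A mature progenitor at the
  cap terminally differentiates.
* *Dedifferentiation*: an actively cycling progenitor that is not dividing
  on the current step reverts to the stem phenotype with per-step
  probability `1 − (1 − Ω_DD)^(dt/τ)`, so the per-cell-cycle probability is
  Ω_DD regardless of the cell's own cycle time. Quiescent, hypoxic,
  differentiated and stem cells are ineligible. Reverted cells regain
  unlimited renewal (generation count cleared).
* *Cycle time*: each newborn (and each mother, on division) draws a cycle
  time from a lognormal with arithmetic mean τ_P = 20 h and SD
  `tau_sigma` = 2 h, floored at 16 h. The 2 h spread (10 % CV) is a
  structural choice — enough to break the artificial mitotic synchrony of
  equal cycle times while keeping the mean interpretable.
* *Proliferation gating*: a mature cell divides only if (i) its local
  volume occupancy is below θ_Q = 0.70 (otherwise it is quiescent, cycle
  clock paused, reversible), (ii) its signalling gate is satisfied — ER+
  cells need local estrogen ≥ θ_E = 0.85, ER− cells need local FGF ≥
  θ_FGF = 0.70, and stem cells follow the estrogen gate by default
  (`stem_er_gated`; they reside in the signalling-rich wall niche), and
  (iii) progenitors are below the division cap.
* *Apoptosis*: every live cell faces a per-step Bernoulli death with
  ω_Apop = 0.705 % per 30-minute step (`apoptosis_scope="all"`; a
  `"non_cycling"` scope restricting death to quiescent/hypoxic/
  differentiated compartments is available as a config switch). Dead cells
  are removed immediately.
* *Hypoxia*: a live cell whose local O2 falls below `hypoxia_threshold`
  becomes hypoxic; 12 h of continuous hypoxia → necrosis (irreversible);
  24 h after necrosis → calcification (permanent). Necrotic and calcified
  bodies persist as inert mechanical obstacles and are excluded from live
  counts; recovery before necrosis resets the clock.

**Schedule.** Fixed order per 30-minute step: (1) deposit agent rates and
solve the four fields; (2) hypoxia/necrosis/calcification then quiescence
updates from the freshly sampled local conditions; (3) apoptosis draws;
(4) cycle advance, growth, terminal differentiation at the cap, and mitosis
with daughter placement; (5) dedifferentiation draws for non-dividing
active progenitors; (6) mechanical relaxation; (7) counters, transition
log, per-step metrics record. State transitions complete within the step.
Agents are processed in stable id order; daughters join the schedule next
step.

**Mechanics.** Overdamped pairwise linear repulsion on overlap with no
long-range adhesion: each sweep moves both members of an overlapping pair
apart along the center line by `relax_factor/2 ×` overlap each (equal and
opposite for equal radii), followed by projection back inside the duct;
sweeps repeat until the worst overlap is ≤ 0.25 µm or 40 sweeps. Candidate
pairs come from a k-d tree with a 2 µm skin and are rebuilt when
accumulated motion could invalidate them. Daughters are placed one mother
radius away in a random direction, reflected inward at the wall. The force
law is deliberately the simplest one producing confluent packings and is
isolated so a Hertz/JKR law could substitute.

**Molecular fields.** Each species obeys a quasi-steady balance
`D∇²c − k·c + S = 0` on a 10 µm voxel grid masked to the lumen, solved
every step (diffusion equilibrates in seconds–minutes at these scales, far
below the 30-minute step). Oxygen and estrogen enter at the duct wall
(Dirichlet, normalized value 1; no-flux axial ends); per-cell uptake is
first order in the local concentration (λ_C × κ_O2 for every live tumor
cell; λ_E × κ_E2 for ER+ cells), which preserves positivity and the
discrete maximum principle. AREG is secreted by estrogen-stimulated ER+
cells (local E2 ≥ θ_E) at rate λ_AREG × q_AREG and cleared first order;
FGF is produced in the wall voxel shell proportionally to local AREG
(`k_relay`; the stromal relay), consumed by ER− cells (λ_FGF × κ_FGF) and
cleared first order, with no-flux boundaries. The 7-point finite-difference
operator is assembled once per geometry; each solve is a Jacobi-
preconditioned conjugate-gradient iteration warm-started from the previous
solution (relative residual 1e−5).

**Local density.** Occupancy is cell volume binned to voxels, box-averaged
over a 50 µm cubic window with a matching average of the lumen indicator
(so wall-adjacent neighbourhoods are normalized by the lumen volume they
actually contain), and scaled by a confluent-packing reference of 0.64
(random close packing). θ_Q's 0.5–0.9 range therefore spans attainable
densities, with 1.0 ≈ fully jammed.

## Parameters

Biological parameters (baseline [perturbation range]): τ_P 20 h
[16.5–23.5, uniform]; ω_P 75 % [50–100 %]; ω_SC 12 % [12 ± 6 %,
lognormal]; ω_SC,± 50 % [36–64 %]; ω_Apop 0.705 %/step [0.10–1.31 %];
P_max 18 cycles [11–25]; θ_Q 70 % [50–90 %]; Ω_DD 0.4 %/cycle
[0.1–0.7 %, 0 disables]; λ_C 4.5× [3–6×]; λ_E 1.0 [0.9–1.1]; λ_FGF 0.72
[0.648–0.792]; λ_AREG 0.086 [0.0774–0.096]; θ_E 0.85 [± 0.2, lognormal];
θ_FGF 0.70 [± 0.15, lognormal]. "Lognormal mean ± spread" is interpreted
as arithmetic mean and arithmetic SD (the exact convention is not
recoverable from the source table; a geometric-convention switch is
provided). ω_Apop is applied directly as a per-step Bernoulli probability;
one step = one 30-minute recording interval.

Structural constants the published description does not fix were
calibrated once — in the spirit of the model's own development procedure
(free constants tuned until reported behaviours are reproduced, then
frozen) — and are configurable:

* diffusivities D_O2 = 2000, D_E2 = 1000, D_AREG = D_FGF = 100 µm²/s;
* κ_O2 = 300 µm³/s per cell: with λ_C = 4.5 and a confluent lesion this
  yields an O2 decay length of ≈ 40 µm, i.e. a hypoxic core in a 100 µm
  lumen, matching the reported centrally calcified morphology;
* κ_E2 = 30 µm³/s (mild estrogen gradients; the wall supply dominates);
* q_AREG = 800, k_relay = 0.2 s⁻¹, κ_FGF = 30, clearance k_decay =
  0.0025 s⁻¹: chosen so the paracrine loop opens once the lesion holds a
  few tens of ER+ cells — both receptor lineages then participate in
  growth from the first week, and their division budgets are spent on the
  same schedule;
* hypoxia threshold 0.30 (normalized), necrosis after 12 h of sustained
  hypoxia, calcification 24 h after necrosis.

## Scale profiles

The published experiments ran a 1 mm × 200 µm duct for 96 wall-clock hours
per run; the bundled studies use a desk-scale profile chosen so the full
three-study design completes on a laptop: duct 400 µm long, 80 µm lumen,
10 µm voxels, 35 simulated days, analysis window t ≥ 15 d. Two choices
keep the scaled-down physics faithful: the per-cell O2 uptake is raised by
the squared radius ratio (κ_O2 → 1875), preserving the dimensionless
uptake/diffusion balance and hence the radial O2 profile and hypoxic core;
and the duct is long enough that the lesion does not hit the axial walls
inside the analysis window at the highest dedifferentiation rates. The
`full` profile carries the published geometry. The bundled studies run at
these sizes: the local sweep as 8 doses × 3 replicates to day 35; the
no-dedifferentiation arrest study as 20 seeds with early stop at arrest;
the reduced-set perturbation study as 20 Latin-hypercube draws to day 25.

What the desk profile preserves: growth-arrest-without-dedifferentiation
(including the ≈ 26-day mean arrest time), rescue by the dedifferentiation
pathway, the increasing/saturating dose–response of advance rate, hypoxic
calcification of the core, stem-fraction dilution. What it does not: the
absolute population sizes (hundreds to a few thousand cells instead of
tens of thousands), so per-event granularity is coarser — a single
dedifferentiation event sustains a desk-scale leading edge for longer,
relative to the front's size, than at full scale — and fraction-based
statistics carry more replicate noise.

## Studies and analyses

* `no_dediff_global` — LHS over the 13 globally perturbed parameters with
  Ω_DD = 0; outputs truncated at arrest. Arrest is *terminal* cessation of
  progression, detected by three prioritized rules: extinction of the live
  population; an incompetence onset after which both leading-edge bands
  (25 µm at each axial extremum) stay ≥ 90 % free of stem cells and
  under-cap progenitors for at least 5 days with extent growth below
  1 µm/day (the flicker tolerance exists because a melting post-arrest
  shell keeps exposing interior cells at the shrinking extremes; the
  growth guard because a 25 µm tip band can transiently hold only
  differentiated cells while competent cells just behind still drive
  advance); or a furthest-reach extent that never again grows by one cell
  diameter. A transient stall that later recovers — expected at low Ω_DD,
  where rescue events are Poisson-rare at desk scale — is not arrest; the
  5-day persistence serves the same purpose.
* `dediff_global` — LHS over the reduced most-influential set (ω_P, ω_SC,
  P_max, θ_Q, Ω_DD, λ_C, θ_E, θ_FGF; cycle time excluded), pathway on, no
  truncation.
* `dediff_local` — only Ω_DD is swept (0.01–1.0 % per cycle, finer at the
  low end: 0.01, 0.025, 0.05, 0.1, 0.25, 0.5, 0.75, 1.0 %), triplicate,
  35 days, everything else at baseline. Advance rate is the least-squares
  slope of the *furthest-reach* extent (running maximum of the summed
  two-direction axial extent — invasion is irreversible, and the
  instantaneous max−min span shrinks when a post-arrest mass regresses by
  apoptosis) over t ≥ 15 d; the stem-density rate is the least-squares
  slope of stem percent over the same window.

Regression is ordinary least squares of each output on all perturbed
parameters simultaneously, two-sided t tests, p < 0.05 significant with
deliberately no multiplicity correction (a fidelity choice), and
standardized effects |β·SD(x)/SD(y)| for Pareto ranking. The local sweep
is summarized by (i) a Michaelis–Menten fit, advance = V_max·Ω/(K_M + Ω)
with Ω on the fraction-per-cycle scale (multi-start nonlinear least
squares), and (ii) a through-origin linear fit of the daily stem-percent
change against Ω in percent per cycle (slope = Σxy/Σx², R² about zero).
The mixed scales follow the conventions in which the two reference values
are quoted (K_M ≈ 0.0262 as a per-cycle probability; slope ≈ 0.189
%-points/day per %/cycle).

## Numerical choices

dt = 30 simulated minutes (= the recording cadence). Field solves are
warm-started CG at rtol 1e−5 with an absolute floor of 1e−12 for
near-empty right-hand sides. Mechanics: relax factor 0.7, overlap
tolerance 0.25 µm, at most 40 sweeps per step (residual overlap carries to
the next step; per-step volume increments are small, so the packing stays
quasi-relaxed); coincident centers separate along a fixed axis.
Degenerate inputs: empty populations produce a solved-but-sourceless
field set and NaN fraction metrics; a dead run ends early. All randomness
flows through named PCG64 child streams of one root seed (cycle times,
phenotype draws, dedifferentiation, apoptosis, placement, LHS), so
trajectories are bit-reproducible and toggling one pathway does not
perturb the draws of another.

## Known limitations

* The desk-scale stem-cell economy equilibrates early: with death applied
  per 30-minute step, the standing stem pool at Ω_DD = 1 %/cycle levels
  out near 2 % of the live population before the t ≥ 15 d analysis window
  opens, so the fitted daily stem-percent change is several-fold smaller
  than the published full-scale slope even though the stem-fraction
  *levels* (≈ 0.5–2.5 % across the biological Ω_DD range, < 1 % at arrest
  without dedifferentiation) sit in the reported ranges. The through-origin
  fit on the desk profile therefore mostly quantifies replicate noise.
* Dedifferentiation events are granular at desk scale: at 0.1 %/cycle a
  ~10³-cell lesion sees of order one event every other day, so a single
  event near an edge rescues a narrow front disproportionately (flattening
  the low-dose response and biasing the fitted K_M downward), while runs
  whose events happen not to arrive before day 35 terminally stall —
  behaviour the full-scale geometry averages away.
* The Michaelis–Menten V_max is an extrapolation beyond the swept range
  and inherits the desk profile's coarser per-event granularity at the top
  of the curve.
* The wall is rigid: no duct deformation, basement-membrane invasion, or
  myoepithelial mechanics; no cell polarity; no explicit cell-cycle
  phases; differentiated cells never revert; dedifferentiation is purely
  stochastic (no hypoxia coupling).
* The force law and the stromal FGF relay are the simplest forms meeting
  their qualitative contracts; their coefficients are calibrated
  stand-ins, not measurements.
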
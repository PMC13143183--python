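# Methods

## Compartmental models

The full model is a six-dimensional ODE system in (L, M, F_U, F_I,
F_F, S), all continuous densities, time in days:

    L'   = ω(1 − L/K) F_F − (μL + ν) L
    M'   = νp L − μM M
    F_U' = ν(1−p) L + τF F_F + τI F_I − (μF + χ) F_U
    F_I' = χ · ηS/(M+ηS) · F_U − (τI + μF) F_I
    F_F' = χ · M/(M+ηS) · F_U − (τF + μF) F_F
    S'   = −μS S + σ

Assumptions: the population is well mixed; males are never limiting
(a female who mates picks a sterilized partner with probability
ηS/(M+ηS), where η discounts sterilized-male competitiveness);
larval competition is a logistic-like throttle (1 − L/K) on
oviposition only; all demographic transitions are Markovian with
constant rates; σ is constant in time.

Because χ (≈10 day⁻¹) exceeds every other rate by two to three orders
of magnitude, F_U is a fast variable that stays near zero. The reduced
model eliminates it, routing new females ν(1−p)L and re-available
females (τF F_F, τI F_I) directly into F_I or F_F through the same
mating fractions. The package treats the reduction as a numerical
claim, not a theorem: `compare_full_reduced` measures the sup-norm
relative discrepancy between the two models (full model started with
F_U = 0) and the test suite checks it falls roughly tenfold for each
tenfold increase in χ (0.020 → 0.0021 → 0.00021 at χ = 10, 100, 1000
for the standard high-infestation run).

### Equilibria and the eradication threshold

S decouples and settles at S* = σ/μS. Infestation equilibria solve the
quadratic ζ(L*) = σ (see README for the closed forms of ζ, R0, γ and
σ̄). The solver uses the closed-form roots, not a generic root-finder,
and reconstructs the remaining compartments by back-substitution:
M* = νpL*/μM, S* = σ/μS, F_F* from the stationary L-equation, F_I*
from the stationary F_I-equation. Roots are labelled low/high relative
to the parabola vertex K/2·(1−1/R0); a double root at σ = σ̄ (detected
with relative tolerance 1e−12 on the discriminant) is reported as a
single "marginal" infestation equilibrium.

Stability is classified numerically: a central finite-difference
Jacobian of the reduced vector field (relative step 1e−6 per
component, absolute floor 1e−6 for zero components) and the sign of
the largest eigenvalue real part, with an absolute tolerance of
1e−9 day⁻¹; |max Re λ| inside the tolerance is reported as "marginal"
rather than silently binned.

### Numerical choices

* Integrator: LSODA (adaptive, switches to BDF when stiff — the χ term
  makes the full model moderately stiff), rtol = atol = 1e−8.
  Tolerance-level undershoot below zero is clipped to 0 in returned
  trajectories.
* Mating fractions at M + ηS = 0 are defined as 0 (no males, no
  mating); this removes a spurious 0/0 without changing the dynamics
  anywhere else.
* Eradication is *reported* when L < 1 (a continuous density below one
  organism); the criterion never feeds back into the dynamics. Note
  that just above σ̄ the saddle-node ghost makes convergence slow: at
  σ = 450,000 in the First setting (σ̄ ≈ 421,000) larvae only fall
  below 1 after ≈ 4,000 days.
* Default high-infestation initial condition: (L, M, F_I, F_F) =
  (30,000, 100,000, 0, 100,000) with S(0) = σ/μS; low infestation:
  (100, 300, 0, 300).

## Agent-based model

Daily time step, well mixed. Scheduler order within a day: releases →
sterilized-male survival → wild-male survival → larval survival,
maturation and sex split → female step (survival, refractory
countdown, mating, oviposition) → data collection.

Every continuous rate r becomes a daily probability q = 1 − exp(−r),
so sojourn times are geometric with the same mean as the ODE's
exponential durations. Consequences worth noting: τ = 0 means the
refractory period never ends (the First ODE setting), and the ABM's
replicate mean tracks the reduced ODE — the suite verifies a maximum
relative error under 15% over 100 days on the larval series (measured
≈ 0.7% with 50 replicates, no releases, large initial population).

Representation: wild males, sterilized males and larvae carry no
state beyond survival (and, for larvae, a memoryless maturation draw),
so they are integer pools updated with binomial draws — statistically
identical to per-agent Bernoulli trials. Females are true individuals;
the population engine stores them as parallel arrays of sufficient
statistics for the six sperm-use rules (refractory days remaining,
counts of fertile and sterile records, first- and last-record origin).
The scalar per-agent API (`SpermStore`, `FemaleAgent`,
`sperm_selection`, `mate_event`) implements the identical rules one
agent at a time and is what the unit tests exercise directly.

Oviposition: every inseminated female lays Poisson(ω) eggs per day; an
egg becomes a larva only if (i) the sperm-use rule selects fertile
sperm for it and (ii) it passes the density filter. All of a day's
viable eggs are admitted with the start-of-day probability
max(0, 1 − L/K) and then capped at K − L, so larvae can never exceed
K; within-day density feedback is otherwise ignored (one day's
admissions are small relative to K at the default parameters). Eggs
blocked by density or fertilized by sterile sperm simply create no
larva — sterile-oviposition fruit damage is out of scope.

Other reconstructed details (the per-agent protocol of the original
study is not fully specified in its main text; these choices keep the
ABM consistent with the ODE):

* Matings per female are uncapped by default (configurable cap).
* Sperm does not deplete; one record per mating, records never
  reordered; the Mixed rule weighs records equally.
* Releases default to a batch of σ males every day from day 0
  (period and start configurable).
* Fertilized females in high-infestation initial conditions carry one
  fertile record and a freshly drawn geometric refractory duration
  (memoryless, hence distributionally identical to a mid-refractory
  state).
* Randomness: one master seed; replicate r uses the seed sequence
  (master, r), so sweeps are reproducible and the no-release baseline
  can be paired with each scenario replicate.

## Experiments layer

The headline metric is the percentage reduction of the trapezoidal
area under the daily larval series against the paired no-release (WR)
baseline, 100·(AUC_WR − AUC_scenario)/AUC_WR, summarised over
replicates as mean ± 1.96·sd/√n. Pairing (scenario and WR share the
replicate seed) reduces variance but also resolves small systematic
differences between scenarios that unpaired designs would wash out.
Default grid: σ ∈ {10, 15, 20, 30, 40, 50, 60}·10³ males/day,
100 days, 100 replicates (tests and the acceptance script use 30–40
to stay within desk-scale run times).

## What the synthetic world does and does not establish

The generator *is* the stated world: Table-2-style rates for
*D. suzukii*, K = 36,000 larvae per tunnel, daily releases, 100-day
seasons. It emulates demographic stochasticity, polyandry and
sperm-use bias; it does not emulate spatial structure, weather or
seasonality, age-dependent fecundity, sperm depletion, fixed
developmental delays, or damage from sterile oviposition. A green test
therefore establishes internal consistency (closed forms vs
simulation, ABM vs ODE limit, qualitative bifurcation and transient
structure) — not field-level prediction.

Known limitation: with memoryless maturation, juveniles begin
reaching adulthood the day after they are laid, so at low release
rates (σ ≈ 10,000/day, far below σ̄) wild males rebound quickly and
the 100-day AUC reductions are substantially smaller than those of
simulators that impose a fixed development time. Replacing geometric
maturation with a fixed ~13-day emergence delay raises the Last-rule
reduction at σ = 10,000 from ≈ 35% to ≈ 61% — the price is losing the
exact correspondence with the ODE. This package keeps the memoryless
model for that correspondence; treat the low-σ ABM endpoints as
conservative.
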
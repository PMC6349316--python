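# Methods

## The static snapshot

A food web is represented as functional groups (producers, consumers, one or
more detritus pools) joined by a diet-composition matrix `DC[i, j]` (share of
prey *i* in predator *j*'s diet; a per-predator import share covers feeding
outside the system) and fishing fleets with baseline catches. At steady state
each living group obeys the mass balance

    B_i · PB_i · EE_i = Σ_j B_j · QB_j · DC[i, j] + Y_i + E_i + BA_i

with biomass `B` (t km⁻²), production rate `PB` (yr⁻¹), consumption rate `QB`
(yr⁻¹), catch `Y`, net migration `E` (emigration positive), biomass
accumulation `BA`, and ecotrophic efficiency `EE ∈ [0, 1]`. Exactly one of
{B, PB, EE} may be unknown per group (a fully determined group is verified
instead, which makes balancing idempotent). Unknown biomasses can be mutually
coupled through predation; they are solved as one linear system, with a
singular system reported as an error rather than regularized. PB and EE then
follow in closed form. The consumer energy budget Q = P + R + U must leave
respiration `R = Q − P − U·Q` non-negative, i.e. `U + PB/QB < 1`.

Detritus is an explicit pool: inflows are unassimilated consumption `U·Q` of
all consumers, non-predation deaths `B·PB·(1−EE)` of all living groups, and
fishery discards; the outflow is detritivore consumption. The residual is
booked as export when positive and as a constant external import when
negative, so the snapshot conserves mass either way. Discards (the unlanded
catch fraction) route to detritus.

Units are fixed at t km⁻² and yr⁻¹ throughout; there is no conversion layer.

## Dynamics

Biomass trajectories follow, per group,

    dB_i/dt = g_i · Σ Q(prey→i) − Σ Q(i→pred) − (M0_i + F_i(t) + e_i) · B_i

with net growth efficiency `g = PB/QB`, other-mortality `M0 = PB·(1−EE)`,
fishing mortality `F` linear in fleet effort, and constant migration rate
`e = E/B0`. Consumption uses a foraging-arena functional response

    Q = Q0 · (B_prey/B_prey0) · K·p / (K − 1 + p),   p = B_pred/B_pred0,

where `Q0 = B_pred0 · QB_pred · DC` reproduces the snapshot flows at the base
state. The vulnerability `K ≥ 1` controls top-down potential: at `K = 1`
consumption is exactly independent of predator biomass (pure bottom-up
control — a predator that grows dilutes its own per-capita intake), and for
`K > 1` predation mortality rises with predator abundance but saturates at
`K` times its baseline. This multiplicative saturating form was chosen
because it reproduces the three behaviours that define the vulnerability
semantics — identity at the base state, invariance at K = 1, and a K-fold
mortality cap — while staying algebraically simple; it is not the exact
functional form used inside EwE, which differs away from the base state and
the limits. Imported diet scales linearly with predator biomass.

Producers replace the consumption-gain term with saturating production
`P = m(t) · PB0 · B0 · s·x/(1 + (s−1)x)`, `x = B/B0`, where `m(t)` is the
producer forcing multiplier and the saturation factor `s` (default 2, must
exceed 1) caps production at `s/(s−1)` times baseline. The detritus pool
integrates its ledger flows instantaneously (no lag), with export as a
linear rate anchored at the snapshot.

Because all rates are anchored at the balanced snapshot, the snapshot is an
exact fixed point of the dynamics at baseline effort when `BA = 0`; this is
asserted to machine precision before any scenario work.

Integration is fixed-step RK4 at 12 steps per year — a deliberate choice for
bit-reproducibility over adaptive stepping — with a biomass floor of
`1e-10·B0`. Halving the step changes 200-year equilibria by well under 0.1%
for the webs generated here; the generator's producer turnover ranges
(PB ≤ 25 yr⁻¹) keep the system comfortably inside the stability region of
that step. Groups with a forced biomass trajectory are hard-reset to the
forced value at every step (they still consume prey and suffer recorded
catch); forcing functions are constants or breakpoint series with linear
interpolation.

Two-pool stage structure replaces full multi-stanza age structure: a
fraction `r` of the adult pool's production (at the baseline production rate
per unit adult biomass, so the inflow is linear in adult biomass) recruits
into the juvenile pool, and juveniles graduate back at rate `γ·B_juv`. Any
net base-state transfer is booked through the migration terms and the two
efficiencies are re-solved, so the static balance and the dynamic fixed
point survive the linkage; the synthetic generator picks `γ = r·PB_a·B_a/B_j`
so the base transfers cancel exactly.

## msMSY search and scenarios

The multispecies-MSY search scales all scope fleets by one common factor
(the relative-stability constraint; non-scope fleets stay at baseline
effort), runs each factor for 200 years, and summarizes the next-to-last
simulated year (the annual mean of year 199 of 200) — by then the webs here
have long equilibrated, which a convergence screen verifies: a run whose
final two annual-mean biomasses differ by more than 1% for any scope species
is flagged and excluded from the argmax. The grid is `{step, 2·step, …}` up
to a maximum (default 5.0, a value that comfortably brackets the yield
maxima of the generated webs); the argmax is a grid member (no
interpolation) and ties resolve to the smallest factor as the precautionary
choice. Two objectives are tracked: combined scope-species catch in tonnes
(msMSYt) and combined landings revenue (msMSY€), the latter valuing each
stock's landed catch at its per-tonne price.

Scenarios are applied before scanning: a producer multiplier (the reduced
primary-production scenario uses 0.7 for the whole horizon), forced-biomass
multipliers on baseline biomass (seals 5.76; porpoises 2.09 with continued
southward drift, 1.46 without), and per-predator vulnerability overrides
(the mammal scenarios raise the seal K from its bottom-up baseline of 1 to
2 — without this the biomass forcing could not raise seal consumption at
all). Forced groups are excluded from the objectives; in these webs no scope
fleet catches them anyway. Scenario-versus-baseline tables report the
relative effort factor, absolute F per species, and SSB/catch/revenue as
percentages of the baseline values at the baseline msMSY, where SSB of a
stage-linked species is its adult-pool biomass and single-pool species
report total biomass.

## Synthetic webs

The generator emulates the trophic skeleton of a temperate shelf sea:
phytoplankton → zooplankton/benthos → brown shrimp → fish → marine mammals,
with detritus closing the loop, cod (juvenile + adult pools) as the key
shrimp predator, seals and porpoises preying on cod, and fleets DEM (cod),
BT (plaice + sole), SHR (shrimp) plus a non-scope gillnet fleet whose small
mammal bycatch keeps the top predators' efficiencies inside the generator's
[0.05, 0.95] band. Plaice is priced at exactly 16% of sole; baseline
vulnerabilities are 1 on the mammal columns and 2 elsewhere.

Construction is demand-driven rather than draw-and-check: apex biomasses
are drawn log-uniformly, and every lower group's biomass is then set so its
efficiency lands on a drawn target, which makes each web balance by
construction; a retry loop (same RNG stream, at most 100 attempts) covers
the rare draw that still violates a bound. Rate ranges live in a config
dict, not in code: PB declines with trophic level (phytoplankton 15–25 yr⁻¹
down to mammals 0.06–0.1 yr⁻¹), QB is 3–4× PB for poikilotherms and 10–20×
PB for the warm-blooded mammals, and diets are template weights with
multiplicative jitter bounded so the structural guarantees (shrimp is cod's
top prey; flatfish are benthos-dominated) survive any draw. Identical seeds
give bit-identical CSV output.

What these webs do *not* emulate: real parameter magnitudes (absolute
biomasses come out self-consistent but small compared to survey-scaled
shelf-sea models), age structure beyond two pools, seasonal forcing,
spatial dynamics, and any hindcast fit to observed time series.
Passing tests therefore demonstrate the correctness of the balance algebra,
the dynamic fixed point, the response-function contracts and the qualitative
scenario mechanisms (bottom-up depletion under reduced primary production;
seal predation on cod releasing shrimp) — not quantitative agreement with
any real ecosystem's numbers.

## Numerical conventions and limitations

* Balance residual tolerance: 1e-9 relative per group, checked against an
  independent term-by-term evaluation in the tests.
* Diet columns must sum to 1 (with import) within 1e-9; EE is accepted in
  [0, 1] with a 1e-12 slack for round-off, then clipped.
* `DC[i, j]` and `Q[i, j]` always mean prey *i* → predator *j*; every
  formula in the package is written in this single convention.
* The argmax tie tolerance is relative 1e-12 — exact ties in practice.
* Degenerate inputs fail loudly: zero production with unknown EE, singular
  coupled-biomass systems, K < 1, s ≤ 1, non-finite integration states
  (reported with time and group) are all errors, never silently patched.
* Migration is supported only as a constant rate; there are no migration
  time series, no Monte-Carlo uncertainty, and no spatial component.
* Problem sizes used by the shipped studies: 12-group webs (plus optional
  fillers), 200-year runs at 12 steps per year, effort grids of 0.1–0.5
  steps up to factor 5 — small enough that a full four-scenario study runs
  in well under a minute on one core.
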
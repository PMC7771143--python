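# Model and methods

## Overview

`evosize` is a physiologically size-structured food-web model (a
size-spectrum model in the mizer family) coupled to stochastic turnover of
maturation-size phenotypes.  A community of S species shares one set of
physiological parameters and differs only in asymptotic mass M, maximum
recruitment flux R_max, and the evolving trait η — the fraction of M at
which half of net energy is routed to reproduction.  Each species is a
collection of lineages ("phenotypes") that differ only in η, reproduce
clonally, and compete through the shared food web.  Selection on maturation
size then emerges from size-dependent predation, competition for a shared
resource, and (optionally) size-selective fishing.

## Ecological component

Each phenotype's abundance density N(m) (individuals m⁻³ g⁻¹) obeys the
McKendrick–von Foerster transport equation

    ∂N/∂t + ∂(g N)/∂m = −μ N,

with food-dependent growth g(m) and total mortality μ(m).

**Feeding.**  A predator of mass m prefers prey of mass m/β through a
log-normal kernel φ = exp(−ln²(m/(β m_p))/(2σ²)).  Encounter is
E(m) = γ m^q ∫(N_R + Σ_j θ_ij N_j) φ m_p dm_p, summing the background
resource (always fully available) and all fish phenotypes weighted by the
species interaction matrix θ (all entries 0.5 with predation on — the
diagonal sets cannibalism — or 0, in which case fish feed only on the
resource).  Intake saturates as a Holling type II response,
f = E/(E + h m^n).  The search coefficient γ = 538 makes f = 0.5 emerge for
feeding on an ungrazed resource (this identity is exact with the default
parameters and is asserted in the tests).

**Energy budget.**  Assimilated intake α f h m^n pays standard metabolism
k_s m^p; the surplus is split by the allocation function
ψ(m) = [1 + (m/m*)^(−u)]^(−1) (m/M)^(1−n) between reproduction (ψ) and
somatic growth (1−ψ).  A negative budget does not shrink individuals: growth
is floored at zero and the deficit is charged as starvation mortality
μ_st = deficit/(ξ m), ξ being the mobilisable fraction of body mass.

**Reproduction.**  Spawn output R_p = ε/(2 m₀) ∫ N (surplus) ψ dm (eggs per
volume per year; the ½ assumes half the spawners are female).  Recruitment is
Beverton–Holt with one ceiling per species: all phenotypes' spawn outputs are
pooled, R_s = R_max ΣR_p/(ΣR_p + R_max), and recruits are redistributed in
proportion to each phenotype's spawn output, so density dependence does not
disproportionately penalise abundant lineages.  Recruits enter the egg bin
(m₀ = 0.001 g) as a flux boundary condition.

**Mortality.**  Five components: emergent predation
μ_p(m_p) = Σ_j ∫ φ (1−f_j) γ m^q θ N_j dm (satiated predators kill nothing);
senescence μ_se = se_min + (se_max − se_min) e^(−M/m) above the maturation
mass (a survival cost of reproduction, rising toward se_max near M);
starvation (above); background μ_b = μ0 M^(n−1) (larger species live
longer); and knife-edge fishing, F per year at and above 0.25·M.  The
selectivity mass stays at its initial value for the whole run — it does not
track evolved maturation sizes.

**Resource.**  The background spectrum (10⁻¹⁰ g to m_cut = 1 g) follows
semi-chemostat dynamics, regenerating toward the carrying capacity κ m^(−λ)
(λ = 2 − n + q) at rate r₀ m^(p−1) while being grazed by all fish.

## Evolutionary component

At each time step each species independently has probability χ = 0.001 of
budding a new phenotype off a uniformly chosen parent lineage.  The child's
trait is η(1+δ) with δ drawn from a Normal(0, 0.10) truncated at ±20%
(so ±2 sd spans the admissible range; both knobs are configurable), redrawn
until the child maturation mass lies in (m₀, M].  The child receives 5% of
the parent's density, taken proportionally from every size bin, so
introductions conserve biomass and spectrum shape exactly.  (An alternative
seeding mode that injects the 5% biomass as an egg-size pulse is available
but off by default: the proportional slice preserves the parent's
demographic structure and avoids an artificial larval pulse.)  Lineages
whose total abundance falls below Ω = 10⁻³⁰ m⁻³ are removed.  Because χ is a
per-step probability, the evolutionary tempo scales with dt; dt = 0.1 yr is
part of the model definition here.

Species-level trait summaries weight each phenotype's η by its biomass
(numbers-weighting is available as an option); the biomass weighting matches
how trait trajectories are usually reported for this model family.

## Fitness

The fitness of a phenotype at time t₀ is a modified lifetime reproductive
output ("eggs per recruit"): a cohort entering at the egg mass is advanced
for t_max = 50 years along its growth characteristic dm/dt = g(m, t) through
the rate fields the forward simulation actually produced (the cohort does
not feed back on the community).  Survivorship decays as exp(−∫μ dt); the
cohort's own spawn output is passed through the species' Beverton–Holt map
and the resulting recruitment flux is integrated over the horizon and
divided by the cohort's initial numbers (its egg-bin numbers at t₀).
Values are comparable across phenotypes within a species, not across species
(different R_max).  Rate fields are recorded at a configurable thinning
(default: every step within the requested window); mass interpolation is
linear in log mass.

## Numerics

- Fish grid: 100 log-spaced bins, 0.001 g – 10⁵ g.  Resource grid: 160
  log-spaced bins, 10⁻¹⁰ – 1 g.  Trapezoid weights double as quadrature
  weights and transport cell widths; integrating a constant is exact.
  Encounter/predation/spawn integrals agree with a 10×-resolution
  brute-force oracle to ~0.1–0.3% for equilibrium-like spectra (<1% for
  strongly curved test spectra on the 100-bin grid).
- Transport: first-order semi-implicit upwind scheme, unconditionally
  positive; recruitment enters as the egg-bin flux (g·N at m₀ equals the
  recruitment flux).  Densities above each phenotype's asymptotic mass are
  truncated to zero (individuals do not exceed M; outflow through the M
  boundary acts as mortality at asymptotic size).
- Resource: exact per-bin exponential update of the semi-chemostat equation
  with the predation field held constant over the step — reproduces the
  closed-form solution to machine precision for constant grazing.
- Time step dt = 0.1 yr.  Halving dt and refining the grids changes century-
  scale biomass trajectories consistently with first-order convergence
  (asserted in the tests).
- The RNG draw order is fixed (species in index order, one uniform each,
  then mutation draws), so a seed fully determines a replicate.  With χ = 0
  the model is deterministic and bit-reproducible.

## Experiment design

The reference design: 3,000 unfished years of burn-in to accumulate
phenotype diversity, a full-state checkpoint (community, resource, RNG,
configuration digest; HDF5, exact round trip), then paired 3,000-year
continuations with and without fishing (F = 0.8, knife-edge at 0.25·M) from
the identical state.  Replicate r uses seed base_seed + r.  By default a
fork resumes the saved RNG stream, so the F = 0 fork is the exact
continuation of the burn-in and paired forks share one mutation history;
passing `reseed` derives independent child streams
(`SeedSequence(reseed, spawn_key=(fork_index,))`) instead.  Sweeps cover
F ∈ {0.1, …, 1.0} and the sensitivity knobs (initial η, mutation sd, χ,
initial phenotype fraction, σ, β).

The test suite exercises the full 3,000-year burn-in at 3 replicates per
predation scenario and checks fished forks of 300–600 years; a reduced
3-species preset (50 fish bins) serves the fast unit tests.  The full
10-replicate, 6,000-year factorial design is available through the CLI and
`ScenarioSpec` but is an overnight computation.

## Parameter defaults

| symbol | value | units | meaning |
|---|---|---|---|
| α | 0.6 | – | assimilation efficiency |
| h | 85 | g^(1−n)/yr | maximum intake coefficient |
| n, p | 0.75 | – | intake / metabolism exponents |
| k_s | 4 | g^(1−p)/yr | metabolism coefficient |
| γ | 538 | g^(−q) m³/yr | search volume coefficient |
| q | 0.8 | – | search exponent |
| β, σ | 100, 1 | – | preferred predator:prey ratio, kernel width |
| u | 7 | – | maturation transition steepness |
| ε | 1 | – | offspring production efficiency |
| m₀ | 0.001 | g | offspring mass |
| μ0 | 2 | g^(1−n)/yr | background mortality coefficient |
| se_min, se_max | 0.1, 1 | 1/yr | senescence bounds |
| ξ | 0.1 | – | energy-reserve fraction |
| κ, λ, r₀, m_cut | 0.05, 2.05, 4, 1 | — | resource spectrum |
| χ, Ω | 0.001, 10⁻³⁰ | — | introduction probability, extinction threshold |
| F | 0.8 | 1/yr | default fishing mortality |

The 9-species community has asymptotic sizes log-spaced from 10 g to 100 kg,
initial η = 0.25 and R_max declining from 0.49208 to 0.00034.

## Design choices where the definition was open

- **Senescence exponent.**  The senescence term is implemented as
  se_min + (se_max − se_min)·e^(−M/m) for m > m*: monotonically increasing
  with size, bounded by se_max, and consistent with a survival cost of
  reproduction.  The coefficient is treated as a plain rate (1/yr); an
  allometric m^(n−1) scaling was evaluated and rejected (it weakens the
  cost so much that large-adult pile-up worsens food limitation at the top
  of the web).
- **Starvation prefactor.**  μ_st = deficit/(ξ m) — the energy-reserve
  formulation; the alternative constant coefficient st_r is retained in the
  configuration for sensitivity work.
- **Egg mass.**  0.001 g (the value also used for the smallest size at
  which all species begin life); a 0.1 mg variant changes no reported
  quantity measurably.
- **Fork RNG pairing** (above) and **biomass-weighted trait means** (above).

## What the model world does and does not contain

The community is deliberately idealised: one shared physiology, evenly
log-spaced asymptotic sizes, a single knife-edge fishery, no space,
temperature, sex structure, or interbreeding between phenotypes (each
lineage breeds true, so selection differentials are not comparable to
quantitative-genetic estimates).  Tests passing on this world show that the
coupled dynamics, the recruitment pooling, and the selection responses are
implemented correctly — not that real stocks will evolve at the simulated
tempo, which is set by χ, the 5% seeding fraction and the ±20% mutation
kernel.

## Known limitations

- With predation disabled (θ = 0) the resource cutoff at m_cut = 1 g caps
  resource-only feeding: through the β = 100 kernel the feeding level drops
  below the critical level f_c = k_s/(α h) ≈ 0.078 near m ≈ 380 g, so no
  individual can grow (or spawn) much beyond ~0.4 kg.  Species whose
  maturation mass exceeds that ceiling (the four largest, m* ≥ 790 g at
  η = 0.25) cannot complete their life cycle on the resource alone and go
  extinct within a few hundred years of a no-predation run.  The
  no-predation scenario is therefore informative only for the small species
  unless the resource cutoff is raised in the configuration.
- In the fully fed equilibrium, recruitment is saturated (R ≈ R_max for all
  species), adults of the largest species accumulate between the fishing
  selectivity size and m*, and their grazing depresses mid-size prey; the
  largest predators therefore sit at feeding levels just above f_c (~0.09).
  Emergent feeding levels over 1 g–M span ≈ 0.09–0.42 in a century-long
  deterministic run.
- Evolutionary tempo is dt-dependent by construction (χ per step).
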
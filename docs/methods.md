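# Methods

`mucosim` simulates multispecies bacterial communities growing in a
mucosa-like niche: a 2-D box with nutrients diffusing in from the top
face, a rigid substratum at the bottom, periodic side boundaries, and a
fixed ceiling height above which biomass is eroded away by the ambient
flow.  Bacteria are discrete circular agents coupled to a grid-based
steady-state description of the dissolved chemistry.  This note records
the model, its assumptions, the parameters that matter, and the numerical
choices, in enough detail to reproduce or modify any result the package
computes.

## Model overview

**Agents.**  Each bacterium has a species, a continuous 2-D position and
an individual mass; one mass unit corresponds to a cell of 1 um
diameter.  Cell radius follows the area-proportional law r = 0.5 sqrt(m)
(a circle's area scales with its mass), so packing density is consistent
as cells grow; a volume-proportional alternative (r = 0.5 m^(1/3)) is
config-selectable.  Cells are *planktonic* (swimming, during the brief
colonization phase) or *frozen* (immobilized in the packed community);
freezing is irreversible.

**Two time phases.**  Colonization runs on 1-s steps: swimmers are
injected at uniform random positions, move a persistent random walk
(10 um/s, heading jitter uniform in +-45 deg per second), reflect off the
top boundary, wrap in x, and freeze at first substratum contact.  The
phase ends when exactly `seed_count` (default 50) cells have attached;
because the injected population size needed for that is not a model
quantity, swimmers are injected in batches until the target is met,
making the attached count deterministic while positions and species
stay random.  Remaining swimmers are discarded.  Growth then proceeds on
15-min steps until every species' biomass is flat (below 1% relative
range over a trailing 50-h window, with a 0.5 mass-unit absolute floor
for absent species) or `max_time_h` is reached.

**Chemistry.**  Every substrate S obeys the pseudo-steady-state balance
div(D grad S) + R(S) = 0 on a square-block grid (10 um blocks), with a
Dirichlet value at the top face (1 for bulk nutrients, 0 for byproducts,
normalized units), zero flux at the substratum, and periodic sides.  The
reaction term sums Monod uptake over the species in each block,

    consumption_i = sum_k mu_max(i,k) * S_i/(S_i+Ks(i,k)) * x_k / Y(i,k),

i.e. producing one unit of biomass costs 1/Y units of substrate — the
standard Monod convention, under which the yield strategist is the
species that converts nutrient to biomass more efficiently.  (A config
flag `literal_yield_form` multiplies by Y instead, for comparison with
the opposite convention.)  Byproduct production is a fraction gamma of
the donor's consumption of the precursor, with gamma = 1 - Y by default
so that biomass plus byproduct exactly account for the substrate
consumed.  The unit bridge between the agent and grid worlds is 1
concentration unit == 1 mass unit per um^2; block biomass densities are
agent masses binned by cell center divided by block area.

**Growth and division.**  Each frozen cell grows by the exponential
Euler update m <- m * exp[(sum_i mu_max_i S_i/(S_i+Ks_i) - m_maint) dt]
using its block's concentrations frozen at the start of the step — exact
for constant S and always positive.  A cell divides when its mass
reaches its personal threshold, drawn at birth from N(2, 0.2) truncated
at two standard deviations (so [1.6, 2.4]); the split is exactly 50/50
and the daughter lands tangentially in a uniformly random direction.
Newborn and initially injected masses are drawn from N(1, 0.1) with the
same +-2 SD cut.

**Mechanics.**  Overlap between two cells is (r_a + r_b) minus the
center distance (minimum image across the periodic x).  The shoving rule
assigns each overlapping pair displacements of half the overlap along
the line of centers; `shove_step` applies one simultaneous sweep of this
rule.  For relaxation of a whole community, simultaneous sweeps
propagate expansion only one cell layer per sweep, which measurably
cannot hold a confined growing bed at physical density within any
affordable budget; `relax` therefore applies the same pairwise rule in
sequential (Gauss-Seidel) order inside a compiled kernel, with the
candidate-pair list cached between sweeps by a k-d tree query with a
distance margin.  In addition, each growth step first lifts cells by the
displacement that volume balance dictates in a laterally confined,
incompressible packed bed: within each grid column, the upward shift at
height y equals the biomass produced below y this step divided by
(column width x hexagonal close-packing density, 1.155 mass/um^2).  This
growth advection carries the systematic expansion; shoving remains the
authority on pairwise non-overlap and handles all local rearrangement
(division placements, lateral spreading, fronts).  With both in place
the bed holds at 1.10-1.15 mass/um^2 with residual overlaps of a few
hundredths of a micron.  Cells whose centers end a step strictly above
the niche height h = 60 um are removed; the removed mass is ledgered per
species so biomass is exactly accounted: B(t+dt) = B(t) + growth -
removal (division and shoving conserve mass to the bit).

**Order within a growth step**: apply due injections; bin biomass; solve
the fields; grow (and advect); divide; relax; enforce the cap; record.

**Determinism.**  A single seeded generator drives every random draw in
a fixed order, so a (config, seed) pair reproduces a trajectory bitwise.
Replicates use seeds seed, seed+1, ...

## Interaction topologies and kinetic strategies

Two-species communities are wired as: competition (one shared bulk
nutrient), neutralism (one bulk nutrient each), commensalism (the
provider eats a bulk nutrient and excretes the byproduct that is the
beneficiary's only food), and mutualism (each eats its own bulk nutrient
plus the partner's byproduct).  Species follow a growth-yield trade-off
with mu_max * Y held constant: the baseline N (bulk mu 0.3/h, Y 0.15),
the rate strategist G (0.6/h, 0.15) and the yield strategist E (0.3/h,
0.30); byproduct kinetics are ten-fold faster with the same yields.
Three-species invasion panels use a doubled baseline (N 0.6/h) with fast
(1.2/h) or efficient (Y 0.3) invaders, residents seeded 50:50 and five
newcomer cells injected at half the niche height at 300 h.  Panels a-e
wire the invader competitively (against a provider's bulk nutrient, both
neutral nutrients, the shared byproduct, or a mutualist's resources);
panels f-j wire it cooperatively (commensal beneficiary, neutral with
its own nutrient, or mutualistic partner of one resident); each builder
documents its exact wiring.

## Parameters and defaults

| parameter | default | units | why |
|---|---|---|---|
| domain | 500 x 500 | um | niche plus diffusion boundary layer |
| grid dx | 10 | um | chemistry resolution |
| height cap h | 60 | um | mucosal community thickness |
| S_top (bulk) | 1.0 | conc. (normalized) | concentration scale |
| Ks | 0.1 | conc. | half-saturation well below supply |
| D | 2.5e3 | um^2/h | see below |
| maintenance m | 0.01 (catalog) | 1/h | see below |
| walk speed | 10 | um/s | flagellar swimming speed |
| colonization dt | 1 | s | resolves the walk |
| growth dt | 15 | min | chemistry quasi-static per step |
| seed count | 50 | cells | seeding layer |
| division threshold | N(2, 0.2), +-2 SD | mass | binary fission at ~2 units |
| relax budget | 10 rebuilds x 10 sweeps | — | holds packing with advection |
| steady state | 1% over 50 h, floor 0.5 | — | flat-biomass criterion |

**Diffusion coefficient.**  The substrates are normalized
pseudo-substances, so D is meaningful only relative to the community's
consumptive capacity.  D = 2.5e3 um^2/h puts the system in the strongly
diffusion-limited regime this model is about: the active growth layer is
a band of roughly sqrt(D Y Ks / (mu x)) ~ 7 um at the community surface,
communities mature (fill the 60-um niche and plateau) over 100-200 h —
the timescale on which the studied communities develop, with newcomers
arriving at 300 h into a just-matured biofilm — and the interior is
nutrient-starved, giving the stratified structures and surface-dominated
turnover the model is designed to exhibit.  An order of magnitude more
diffusive and the niche saturates within tens of hours with a thick
active layer whose interior turnover expels any mid-height newcomer; an
order of magnitude less and the niche cannot fill at all.

**Maintenance.**  The growth law subtracts a maintenance rate m.  The
catalog scenarios set m = 0.01/h for every species (at most 3% of any
mu_max).  Its role is qualitative, not quantitative: with m = 0 exactly,
the Monod tail gives every starved interior cell a small positive growth
rate, the packed interior becomes a slow upward conveyor, and any
species without substratum anchorage — in particular newcomers injected
at mid-height — is inexorably carried to the cap and eroded, so no
delayed-introduction experiment can end in establishment.  A small
positive m zeroes net growth where nutrients are exhausted, freezing the
interior demographically while leaving the active layer essentially
untouched.  `SpeciesSpec.maintenance_m` itself defaults to 0 so the
growth law can be exercised in its pure form.

## What the built-in scenarios do and do not emulate

The generator reproduces the *structure* of the study system: interaction
topologies, rate/yield strategy cards, seeding, injection schedules, and
the niche geometry.  It does not emulate real gut physiology — no mucus
secretion or host feedback, no fluid shear profile (erosion is a sharp
height threshold), no cell death or lysis, no 3-D packing, and
single-substrate Monod metabolism instead of genome-scale networks.
Outcomes shown by the tests (who dominates which topology, establishment
or exclusion of newcomers) are statements about this model class, not
quantitative predictions for in-vivo communities.

## Numerical choices

* **Nonlinear field solve.**  Picard iteration with the uptake term
  linearized semi-implicitly: the Monod denominator is lagged one
  iterate, so uptake enters the matrix diagonal as a nonnegative
  coefficient and the operator stays an M-matrix (iterates cannot go
  negative).  Byproduct sources are lagged explicitly.  Convergence:
  relative change below 1e-6 (max 200 sweeps); the fields warm-start
  from the previous growth step.
* **Discretization.**  Standard 5-point finite-volume stencil; Dirichlet
  top face via a half-cell ghost (coefficient 2D/dx^2); no-flux bottom;
  periodic x.  At a face where the sink profile has a kink the flux
  stencil is first-order; tests verify the discrete closed form exactly
  and continuum convergence at the observed rate.
* **Division** checks once per step after growth; with growth-rate x dt
  at most ~0.3 per step, masses cannot overshoot the 2.4 threshold
  ceiling enough to need multiple splits per step.
* **Degenerate geometry.**  Coincident centers (distance < 1e-9) get a
  random separation direction from the step's generator before the
  relaxation kernel runs.  Daughters are clamped inside the substratum
  and domain bounds before relaxation.
* **Steady-state detection** ignores species below 0.5 mass units so an
  extinct or not-yet-injected species does not block termination, and is
  only consulted once all scheduled injections have occurred plus one
  full window.

## Problem sizes used by the tests and acceptance script

Full-width (500 um) runs are scientifically identical but proportionally
slower, so the shipped checks use narrower domains, chosen as the
package's standard verification conditions: the dominance-ordering runs
(competition/neutralism/commensalism/mutualism, rate vs yield
strategist) use a 60-um-wide domain for up to 300 h; the three-species
invasion check uses a 100-um domain to 700 h in the test suite and a
60-um domain in the acceptance script (injection at 300 h in both; the
invader share is read as the trailing-50-h mean fraction, averaged over
three replicate seeds); the height-cap ledger check uses 100 um for
110 h.  All heights, caps,
kinetics, seeding counts and time steps are the full study conditions.

## Known limitations

* The shoving relaxation is budgeted, not iterated to machine tolerance;
  residual overlaps of up to ~0.1-0.3 um can persist transiently at the
  active front (bed density stays within ~5% of close packing).
* The growth advection assumes purely vertical accommodation within a
  column; lateral redistribution is left to shoving, so columnar
  structure is mildly emphasized at the grid-column scale.
* Byproducts are produced from bulk consumption only; chains of
  byproduct-to-byproduct conversion must be wired explicitly.
* With `literal_yield_form` the yield interpretation inverts (high-Y
  species consume more), which contradicts the efficiency reading of the
  yield strategist; the flag exists for comparison, not for the standard
  scenarios.
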
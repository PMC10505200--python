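# Methods

This note documents the model equations, the parameter choices and their
rationale, what the simulated study conditions do and do not represent,
and the numerical decisions a maintainer would want to know.

## State and currencies

Each species is a single well-mixed population with a biomass in tons.
Plants and seabirds additionally occupy a fraction of one of two
independent unit-interval space budgets (the plant habitat layer and the
seabird nesting layer). The island (1.38 km²) has no explicit spatial
structure; "area" is bookkeeping for competition-for-space, with forest
cover capped at 95% of the island (coastal strips and rock are treated as
unplantable).

The conserved currency is a single collective nutrient, with nitrogen mass
fractions used for the contents of organisms and detritus. Nutrient enters
the system only as (a) seabird droppings and seabird biomass growth — both
fuelled by fish at sea, (b) nitrogen fixation by fixer plants, and (c) the
(small) biomass of arriving propagules. It leaves only by weathering of
detritus. Every other flow, including goat carcasses during eradication,
is an internal transfer. `total_system_nutrient` equals
`initial + cumulative_input − cumulative_weathered` to float rounding
(~1e-13 relative over a full scenario); the test suite enforces 1e-6.

Trophic conversion is nutrient-exact: a consumer that ingests mass `I` of
prey with nutrient fraction `nf_prey` assimilates `a·I·nf_prey` of
nutrient and converts it to its own biomass at its own nutrient fraction.
Biomass alone cannot be conserved across trophic levels with heterogeneous
nutrient contents; nutrient can, and is.

## Daily step

Fixed sub-step order: seabird input → interference → plant growth →
feeding (herbivores+goats, carnivores, rats) → plant competition → seabird
nest competition → detritus cycle (detritivore feeding, weathering,
ageing/decomposition) → extinction sweep. Nutrient must enter before
growth; feeding precedes competition so consumed biomass frees area the
same day.

**Plant growth.** Demand is `M·g·modifier·(1 − M/K)` with
`K = (A·(1+overdensity) + free)/sa`, where `sa` is the form-specific area
per ton and `overdensity = 0.5` lets biomass overshoot the area-supported
density. Without that headroom a space-limited plant could neither grow
nor encroach (encroached area is capped by biomass-supported area) and
succession would deadlock. The nutrient cost is drawn from the pool,
shared proportionally to demand when short; nitrogen fixers cover 80% of
their demand from the atmosphere. Under shortfall, biomass declines at
`0.1·(1−met)·Cs` per step — stress-tolerant (high-S, low-Cs) plants
resist. All plants shed litter at 0.5%/step.

**Feeding.** Demand is `M·m·demand_factor/a` (ingestion capacity 2.5×
maintenance, a Yodzis–Innes-style ingestion:metabolism ratio; with demand
equal to maintenance alone a fully fed consumer could never grow). Prey
are visited in descending preference (triangular kernel on the niche
interval; generalists rank by prey nutrient content) with Holling type III
potential per prey and truncation at demand. Egestion `(1−a)·I`, metabolic
loss `M·m`, and background mortality `M·0.002` feed the droppings and
carcass pools.

**Plant competition.** The trait-similarity threshold (0.2 on the C/100
axis) applies within a growth form; arboreous-over-herbaceous shading is
unconditional — a canopy shades the understory regardless of strategy
similarity, and without this a tree whose C score overlapped no grass
could never expand on a grass-covered island.

**Seabirds.** Colonies relax logistically (rate 0.05/step) toward the
nesting-capacity limit; droppings (3%/step of colony mass, nutrient
fraction 0.04) are the island's nutrient subsidy. Bigger species encroach
smaller ones' nesting area; displaced biomass enters the carcass pool.

**Detritus.** Each compartment is a queue of daily cohorts carrying
(mass, nutrient, age). Scavengers eat carcasses, litter feeders eat
litter, rats additionally scavenge carcasses. Per step each cohort loses
0.6% to weathering; at age 50 its nutrient returns to the belowground
pool and the (carbon) mass is dropped.

**Extinction.** A population below a single organism's mass is extinct.
The floor is category-scaled: 0.05 t for trees and goats, 1e-4 t for
grasses, 1e-3 t for seabirds, 1e-6 t for invertebrates. With a flat 1e-6
floor a milligram of a tree species could regrow an entire forest, which
makes species loss — and with it every non-restoration outcome — almost
unreachable.

## Evolution phase

One immigrant per 1000 steps, category uniform over {tree, grass,
herbivore, carnivore, scavenger, litter feeder, seabird}, at one tenth of
the founder biomass. One speciation opportunity per 100 steps, rotating
over grasses, trees, herbivores, carnivores (detritivores and seabirds,
fed from outside the plant production of the island, are excluded — their
richness would grow without bound). The daughter takes 5% of the
ancestor's biomass; each heritable trait mutates by a zero-mean Gaussian
with SD 10% of its value times the ancestor's evolutionary rate; CSR is
perturbed in two coordinates on the 100-point simplex with rejection;
nutrient content is inherited unchanged.

## Aliens, eradication, outcomes

Goats (1 t) are generalist herbivores with a space/water-limited herd
ceiling of 20 t. Their impact channels: grazing; destructive browsing of
woody vegetation (3× the ingested mass, to litter); suppression of woody
regeneration (growth modifier `1 − 0.1·M_goat`) and, more weakly, of the
herb layer (`1 − 0.04·M_goat`); woody biomass kill
`0.004·M_goat·Cs` per step — scaled by the tree's stress sensitivity, so
fragile low-S forests collapse while tough high-S forests resist (this is
the main replicate-to-replicate heterogeneity in disturbance outcome);
and interference with seabird nesting (capacity factor `1 − 0.05·M_goat`),
which throttles the nutrient subsidy while goats are present. The herd
ceiling keeps the maximum sustained goat production below the 0.4 t/step
removal rate, so eradication always terminates; without it the removal
programme reaches a stable harvested equilibrium and never ends.

Rats (0.1 t) are territory-limited (60 t) omnivores and scavengers that
also kill tree seedlings (`0.0003·M_rat` per step) — the main brake on
canopy recovery after goats are gone. White popinac is a ruderal,
nitrogen-fixing, fast-growing tree; Korean lawn grass a ruderal turf
grass; both enter at propagule size.

Eradication removes min(0.4 t, stock) per step from step 210,000; removed
mass enters the carcass pool, so the nutrient ledger is untouched.

A replicate is *restored* when its final state is at the 95% cap (a
transient touch followed by collapse does not count). Non-restored
replicates are classified, in order: all trees extinct; popinac ≥ 90% of
remaining forest; ≤ 3 tree species without popinac dominance; > 3 tree
species (herbivore-suppressed). "Reduced but forested" replicates are
those whose forest at eradication start lay strictly between 0 and the cap
with open ground increased since the invasion.

## Desk scaling

`Config.scaled(N)` divides the four phase lengths, the immigration
interval and the sampling cadences by N, and the speciation interval by
√N. Immigration events are the category-balanced diversity source, so
their count per phase is preserved; compressing speciation by the full
divisor would fire an event every step and leave the dynamics no time for
competitive exclusion between events, so speciation events scale back by
the square root (100 opportunities in a 1000-step evolution phase at
N=100). Per-step physiology — including the 0.4 t/step goat removal — is
never scaled. The supported study configuration is N=100: a 3,100-step
scenario, 30 replicates, about 7 s per replicate on one CPU; this is the
problem size the acceptance script and the phenomenology tests use.

## Parameters

The headline schedule (phase lengths, event intervals, the 10% mutation
SD, the 5% speciation split, the tenth-strength immigrants, the 0.4 t/step
removal, the 95% cap, 1.38 km²) is fixed by the study design. The
remaining rate constants are not published and were calibrated by random
and manual search (the procedure `runner.calibrate` implements) against
the observed 1991 vegetation ratio (forest 12.1%, grassland 64.5%,
denuded 23.9%), a goat stock of ~15 t, and the desk-scale phenomenology:
grassland-first succession closing at the cap before invasion in most
replicates, alien boom and bust, eradication completing, and restoration
being the slow exception. Key values: Holling `k=0.07`, `h=400` (global);
demand factor 2.5; invertebrate metabolism 0.5–2%/day, assimilation
0.3–0.8 by guild; tree specific area 1e-4 island fraction per ton (full
canopy ≈ 9,500 t), grass 1.4e-3; initial pool 30 t; decomposition lag 50
steps; weathering 0.6%/step.

Under these conditions a 20-seed desk ensemble gives: 75% of replicates
fully forested at the invasion checkpoint; roughly a third of
reduced-forest replicates restored, with mean restoration time ≈ 700
steps (seven times the scaled disturbance phase); restored replicates
nutrient-richer before eradication than unrestored ones; rat biomass
10–60× higher after goat removal than before. The acceptance script
recomputes these numbers; none are hard-coded.

## What the synthetic conditions do and do not show

The generator produces the study's own world: a single collective
nutrient, one-dimensional diet axes, linear interference, no seasonality,
weather, age structure or spatial pattern, and alien vertebrates bounded
by fixed ceilings rather than by behaviour. Passing tests therefore show
that the *mechanisms* — closed nutrient accounting, trait-based
succession, niche-web trophodynamics, eradication logistics, and the
founder-effect route to failed restoration — behave as designed at desk
scale; they do not validate the parameter values against the real island
beyond the calibration targets listed above, and quantitative outcomes at
full scale (310,000 steps, thousands of replicates) will differ in detail.

## Numerical notes

* Determinism: one `numpy` Generator per replicate, seeded
  `base_seed + i`; species iterate in id order; web preference ties break
  by id. Identical seeds give bit-identical trajectory CSVs.
* The interaction web is rebuilt only when species are added; removals
  zero the species' biomass and area so stale links are inert.
* Detritus cohorts merge by age, bounding each queue at the decomposition
  lag regardless of community size.
* Areas and biomasses are clamped at zero where float rounding could
  produce −1e-18-scale values; the conservation audit tolerates 1e-6
  relative while typically achieving 1e-13.
* Degenerate inputs: `mutation_sd_fraction=0` clones ancestors exactly;
  `weathering_fraction=0` makes the system fully closed; an empty prey
  list starves the consumer by its metabolism; an empty speciation
  rotation returns no candidate.
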
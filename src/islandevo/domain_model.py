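"""Core state types for the island ecosystem model.

The model tracks a single closed nutrient currency (nitrogen mass fractions
are used for the contents of organisms) cycling between a belowground pool,
three age-structured detritus compartments (droppings, carcasses, litter),
and the biomass of the living species.  Space enters as two independent
unit-interval budgets: the plant habitat layer and the seabird nesting
layer.  Biomass is measured in tons; areas are fractions of the island.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Optional, Union

import numpy as np

# Species categories.  Plants occupy the habitat layer, seabirds the nesting
# layer; goat and rat are the large-vertebrate aliens with special feeding
# rules.
PLANT_CATEGORIES = ("grass", "tree")
INVERTEBRATE_CATEGORIES = ("herbivore", "carnivore", "scavenger", "litter_feeder")
CATEGORIES = PLANT_CATEGORIES + INVERTEBRATE_CATEGORIES + ("seabird", "goat", "rat")

# Categories eligible for the speciation rotation, in rotation order.
SPECIATION_ROTATION = ("grass", "tree", "herbivore", "carnivore")

# Categories that can immigrate during the evolution phase.
IMMIGRANT_CATEGORIES = (
    "tree",
    "grass",
    "herbivore",
    "carnivore",
    "scavenger",
    "litter_feeder",
    "seabird",
)

CSR_TOL = 1e-9


@dataclass
class PlantTraits:
    """Grime CSR strategy block plus the derived physiological rates.

    ``csr`` is a 100-point budget over (competitive, stress-tolerant,
    ruderal).  ``stress_tolerance_index`` (Cs) is ``1 - S/100``: a low value
    means high stress tolerance and resistance to encroachment and to
    oligotrophic die-back.
    """

    form: str  # "herbaceous" | "arboreous"
    csr: tuple[float, float, float]
    basic_growth_rate: float  # fractional biomass growth per step
    height: float  # metres
    area_increase_rate: float  # E, fractional area expansion per step
    stress_tolerance_index: float  # Cs in [0, 1]
    nutrient_content: float  # nutrient mass fraction of biomass
    nitrogen_fixer: bool = False
    evolutionary_rate: float = 1.0


@dataclass
class AnimalTraits:
    feeding_type: str  # herbivore | carnivore | scavenger | litter_feeder | omnivore
    niche_value: float  # position n on the niche axis, in [0, 1]
    feeding_center: float  # c
    feeding_range: float  # r (interval width)
    metabolism_rate: float  # fractional biomass loss per step
    assimilation_rate: float  # fraction of intake assimilated, in (0, 1]
    nutrient_content: float
    evolutionary_rate: float = 1.0


@dataclass
class SeabirdTraits:
    body_size: float  # ordinal rank for nest competition
    nesting_area_per_biomass: float  # nesting-layer fraction per ton
    dropping_rate: float  # detritus tons per ton biomass per step
    carcass_rate: float  # mortality fraction per step
    trampling_coefficient: float  # plant-growth suppression per unit nesting area
    nutrient_content: float


Traits = Union[PlantTraits, AnimalTraits, SeabirdTraits]


@dataclass
class SpeciesState:
    """One population: every species is a single well-mixed population."""

    id: int
    category: str
    traits: Traits
    biomass: float  # tons
    area: float = 0.0  # habitat (plants) or nesting (seabirds) fraction
    origin: str = "founder"  # founder | immigrant | speciation | alien
    ancestor_id: Optional[int] = None
    birth_step: int = 0

    @property
    def is_plant(self) -> bool:
        return self.category in PLANT_CATEGORIES

    @property
    def is_seabird(self) -> bool:
        return self.category == "seabird"

    @property
    def diet_axis_position(self) -> float:
        """Where this species sits on its layer's one-dimensional diet axis.

        Plants are embedded by their competitive score C/100; animals by
        their niche value.
        """
        if self.is_plant:
            return self.traits.csr[0] / 100.0
        if isinstance(self.traits, AnimalTraits):
            return self.traits.niche_value
        raise ValueError(f"species {self.id} ({self.category}) has no diet-axis position")


@dataclass
class DetritusEntry:
    mass: float  # tons
    nutrient: float  # tons of nutrient contained in ``mass``
    age: int = 0


@dataclass
class Pools:
    """Belowground nutrient stock plus the three detritus queues."""

    nutrient: float = 0.0
    droppings: list[DetritusEntry] = field(default_factory=list)
    carcasses: list[DetritusEntry] = field(default_factory=list)
    litter: list[DetritusEntry] = field(default_factory=list)

    def compartments(self) -> dict[str, list[DetritusEntry]]:
        return {
            "droppings": self.droppings,
            "carcasses": self.carcasses,
            "litter": self.litter,
        }

    def add(self, compartment: str, mass: float, nutrient: float) -> None:
        if mass <= 0.0 and nutrient <= 0.0:
            return
        queue = self.compartments()[compartment]
        # Same-age additions merge into one cohort, so each queue holds at
        # most decomposition_lag entries regardless of community size.
        if queue and queue[-1].age == 0:
            queue[-1].mass += mass
            queue[-1].nutrient += nutrient
        else:
            queue.append(DetritusEntry(mass, nutrient, 0))

    def detritus_nutrient(self) -> float:
        return sum(e.nutrient for q in self.compartments().values() for e in q)

    def detritus_mass(self, compartment: Optional[str] = None) -> float:
        if compartment is not None:
            return sum(e.mass for e in self.compartments()[compartment])
        return sum(e.mass for q in self.compartments().values() for e in q)


@dataclass
class Config:
    """All global parameters.  Flat key/value; loadable from YAML.

    Phase lengths and event intervals follow the study design (100k-step
    evolution with immigration every 1000 steps and a speciation opportunity
    every 100 steps, 100k settling, 10k disturbance, 100k post-eradication).
    Rate constants are per time-step (one step = one day).
    """

    # Phase schedule (steps)
    evolve_steps: int = 100_000
    settle_steps: int = 100_000
    disturb_steps: int = 10_000
    post_steps: int = 100_000
    immigration_interval: int = 1000
    speciation_interval: int = 100
    sample_interval_coarse: int = 1000
    sample_interval_fine: int = 100

    # Evolution
    immigrant_biomass_fraction: float = 0.1
    speciation_biomass_fraction: float = 0.05
    mutation_sd_fraction: float = 0.10

    # Island geometry
    island_area_km2: float = 1.38
    forest_cap: float = 0.95

    # Trophic interaction constants (global Holling type III)
    holling_k: float = 0.07
    holling_h: float = 400.0
    demand_factor: float = 2.5

    # Nutrient cycle
    initial_pool_nutrient: float = 30.0
    decomposition_lag: int = 50
    weathering_fraction: float = 0.006
    nitrogen_fixation_fraction: float = 0.8

    # Plants
    specific_area_grass: float = 1.4e-3  # island fraction per ton
    specific_area_tree: float = 1.0e-4
    plant_litter_rate: float = 0.005
    plant_decline_rate: float = 0.1
    plant_overdensity: float = 0.5
    seed_area: float = 1.0e-3
    competition_overlap_threshold: float = 0.2
    grass_height_base: float = 0.5
    tree_height_base: float = 8.0
    grass_growth_min: float = 0.03
    grass_growth_max: float = 0.15
    tree_growth_min: float = 0.01
    tree_growth_max: float = 0.08
    grass_area_rate_base: float = 0.08
    tree_area_rate_base: float = 0.10
    nutrient_content_grass: float = 0.02
    nutrient_content_tree: float = 0.005

    # Invertebrates
    metabolism_min: float = 0.005
    metabolism_max: float = 0.02
    assimilation_herbivore: float = 0.45
    assimilation_carnivore: float = 0.80
    assimilation_scavenger: float = 0.30
    assimilation_litter_feeder: float = 0.30
    nutrient_content_animal: float = 0.025
    animal_carcass_rate: float = 0.002
    niche_beta: float = 2.3333333333333335  # Beta(1, beta); E[x] = 2 * connectance

    # Seabirds
    seabird_growth_rate: float = 0.05
    seabird_dropping_rate: float = 0.03
    seabird_carcass_rate: float = 0.001
    seabird_napb: float = 0.01
    seabird_trampling: float = 0.05
    seabird_encroach_rate: float = 0.01
    nutrient_content_seabird: float = 0.04

    # Aliens
    goat_intro_biomass: float = 1.0
    rat_intro_biomass: float = 0.1
    goat_removal_per_step: float = 0.4  # tons removed per step during eradication
    goat_metabolism: float = 0.025
    goat_assimilation: float = 0.7
    goat_nutrient_content: float = 0.0125
    goat_trample_plants: float = 0.1  # woody-regeneration suppression per ton of goat
    goat_trample_grass: float = 0.04  # herb-layer growth suppression per ton of goat  # growth suppression per ton of goat
    goat_destruction_factor: float = 3.0  # woody biomass destroyed (to litter) per unit browsed
    goat_carrying_capacity: float = 20.0  # tons; space/water-limited herd ceiling
    goat_trample_kill: float = 0.004  # plant biomass killed per step per ton of goat
    goat_nest_interference: float = 0.05  # nesting-capacity loss per ton of goat
    rat_carrying_capacity: float = 60.0  # tons; territory-limited ceiling
    rat_tree_kill: float = 0.0003  # seedling predation per step per ton of rat
    rat_metabolism: float = 0.015
    rat_assimilation: float = 0.6
    rat_nutrient_content: float = 0.025

    # Initial biomasses (tons); immigrants arrive at a tenth of these
    initial_biomass_grass: float = 1.0
    initial_biomass_tree: float = 20.0
    initial_biomass_animal: float = 0.1
    initial_biomass_seabird: float = 10.0

    # Numerics.  A population below the mass of a single organism is
    # extinct; the floor therefore scales with typical body/plant mass.
    extinction_threshold: float = 1.0e-6
    min_viable_tree: float = 0.05
    min_viable_grass: float = 1.0e-4
    min_viable_seabird: float = 1.0e-3
    min_viable_goat: float = 0.05

    # Calibration targets: observed 1991 vegetation ratio and goat stock
    target_forest: float = 0.121
    target_grassland: float = 0.645
    target_denuded: float = 0.234
    target_goat_biomass: float = 15.0

    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "evolve_steps",
            "settle_steps",
            "disturb_steps",
            "post_steps",
            "immigration_interval",
            "speciation_interval",
            "sample_interval_coarse",
            "sample_interval_fine",
        ):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"config field {name} must be a positive integer, got {v!r}")
        for name in (
            "immigrant_biomass_fraction",
            "speciation_biomass_fraction",
            "forest_cap",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"config field {name} must lie in (0, 1), got {v!r}")
        # Zero is a meaningful degenerate limit for these two.
        for name in ("mutation_sd_fraction", "weathering_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"config field {name} must lie in [0, 1), got {v!r}")

    # Phase boundaries -----------------------------------------------------
    @property
    def invasion_step(self) -> int:
        return self.evolve_steps + self.settle_steps

    @property
    def eradication_step(self) -> int:
        return self.invasion_step + self.disturb_steps

    @property
    def total_steps(self) -> int:
        return self.eradication_step + self.post_steps

    def scaled(self, divisor: int) -> "Config":
        """Return a desk-scale config: phase lengths, the immigration
        interval and sampling cadences divided by ``divisor`` (floored at
        1); the speciation interval divided by sqrt(divisor).

        Immigration events are the (category-balanced) diversity source, so
        their count per phase is preserved.  Speciation events are scaled
        back by the square root so that the dynamics retain enough steps
        between events for competitive exclusion to act; at divisor 100
        this gives 100 speciation opportunities in a 1000-step evolution
        phase.  Per-step physiology and the goat removal rate are never
        scaled.
        """
        if divisor < 1:
            raise ValueError("scale divisor must be >= 1")

        def d(v: int) -> int:
            return max(1, v // divisor)

        spec_interval = max(1, int(round(self.speciation_interval / math.sqrt(divisor))))
        return replace(
            self,
            evolve_steps=d(self.evolve_steps),
            settle_steps=d(self.settle_steps),
            disturb_steps=d(self.disturb_steps),
            post_steps=d(self.post_steps),
            immigration_interval=d(self.immigration_interval),
            speciation_interval=spec_interval,
            sample_interval_coarse=d(self.sample_interval_coarse),
            sample_interval_fine=d(self.sample_interval_fine),
        )


CONFIG_KEYS = tuple(f.name for f in fields(Config))


@dataclass
class IslandState:
    """Full simulation state of one replicate."""

    step: int
    species: list[SpeciesState]
    pools: Pools
    rng: np.random.Generator
    island_area: float = 1.38
    forest_cap: float = 0.95
    cumulative_input: float = 0.0
    cumulative_weathered: float = 0.0
    next_id: int = 0
    web_dirty: bool = True  # set whenever the community composition changes

    def new_id(self) -> int:
        i = self.next_id
        self.next_id += 1
        return i

    def add_species(self, sp: SpeciesState) -> None:
        self.species.append(sp)
        self.web_dirty = True

    def remove_species(self, ids: Iterable[int]) -> None:
        # Removal leaves stale ids in the cached web; consumers skip them
        # lazily, so no rebuild is needed (additions do set web_dirty).
        ids = set(ids)
        if ids:
            self.species = [s for s in self.species if s.id not in ids]

    def by_category(self, *categories: str) -> list[SpeciesState]:
        return [s for s in self.species if s.category in categories]

    def plants(self) -> list[SpeciesState]:
        return self.by_category(*PLANT_CATEGORIES)

    def seabirds(self) -> list[SpeciesState]:
        return self.by_category("seabird")

    def goat_biomass(self) -> float:
        return sum(s.biomass for s in self.by_category("goat"))

    def rat_biomass(self) -> float:
        return sum(s.biomass for s in self.by_category("rat"))


# ---------------------------------------------------------------------------
# Audits


def total_system_nutrient(state: IslandState) -> float:
    """Total nutrient in the closed system, in tons.

    Pool + detritus nutrient + nutrient bound in living biomass.  Over any
    run this obeys: final = initial + cumulative_input - cumulative_weathered
    (seabird subsidies and nitrogen fixation are the only imports, weathering
    the only export).
    """
    living = sum(s.biomass * s.traits.nutrient_content for s in state.species)
    return state.pools.nutrient + state.pools.detritus_nutrient() + living


def vegetation_ratio(state: IslandState) -> tuple[float, float, float]:
    """(forest, grassland, denuded) fractions of the plant-habitat layer."""
    forest = sum(s.area for s in state.species if s.category == "tree")
    grassland = sum(s.area for s in state.species if s.category == "grass")
    denuded = 1.0 - forest - grassland
    return forest, grassland, max(denuded, 0.0)


def validate_state(state: IslandState, config: Optional[Config] = None) -> list[str]:
    """Return a list of human-readable invariant violations (empty if valid)."""
    out: list[str] = []
    seen: set[int] = set()
    for s in state.species:
        if s.id in seen:
            out.append(f"duplicate species id {s.id}")
        seen.add(s.id)
        if s.biomass < 0:
            out.append(f"species {s.id}: negative biomass {s.biomass}")
        if not 0.0 <= s.area <= 1.0 + 1e-12:
            out.append(f"species {s.id}: area {s.area} outside [0, 1]")
        if s.area > 0 and not (s.is_plant or s.is_seabird):
            out.append(f"species {s.id} ({s.category}): non-plant/seabird with area")
        t = s.traits
        if isinstance(t, PlantTraits):
            if abs(sum(t.csr) - 100.0) > CSR_TOL:
                out.append(f"species {s.id}: CSR sum {sum(t.csr)} != 100")
            if min(t.csr) < -CSR_TOL:
                out.append(f"species {s.id}: negative CSR component")
            for name in ("basic_growth_rate", "area_increase_rate", "height", "nutrient_content"):
                if getattr(t, name) <= 0:
                    out.append(f"species {s.id}: plant trait {name} must be > 0")
            if not -CSR_TOL <= t.stress_tolerance_index <= 1.0 + CSR_TOL:
                out.append(f"species {s.id}: stress_tolerance_index outside [0, 1]")
        elif isinstance(t, AnimalTraits):
            half = t.feeding_range / 2.0
            if t.feeding_center - half < -1e-9 or t.feeding_center + half > 1.0 + 1e-9:
                out.append(f"species {s.id}: niche interval outside [0, 1]")
            if not 0.0 < t.assimilation_rate <= 1.0:
                out.append(f"species {s.id}: assimilation_rate outside (0, 1]")
            if t.metabolism_rate < 0:
                out.append(f"species {s.id}: negative metabolism_rate")
        elif isinstance(t, SeabirdTraits):
            if t.dropping_rate <= 0:
                out.append(f"species {s.id}: seabird dropping_rate must be > 0")
            for name in ("carcass_rate", "trampling_coefficient", "nesting_area_per_biomass"):
                if getattr(t, name) < 0:
                    out.append(f"species {s.id}: seabird trait {name} must be >= 0")

    plant_area = sum(s.area for s in state.species if s.is_plant)
    if plant_area > 1.0 + 1e-9:
        out.append(f"plant areas sum to {plant_area} > 1")
    forest = sum(s.area for s in state.species if s.category == "tree")
    if forest > state.forest_cap + 1e-9:
        out.append(f"forest fraction {forest} exceeds cap {state.forest_cap}")
    nest_area = sum(s.area for s in state.species if s.is_seabird)
    if nest_area > 1.0 + 1e-9:
        out.append(f"seabird nesting areas sum to {nest_area} > 1")

    if state.pools.nutrient < 0:
        out.append(f"negative pool nutrient {state.pools.nutrient}")
    lag = config.decomposition_lag if config is not None else None
    for name, queue in state.pools.compartments().items():
        for e in queue:
            if e.mass < 0 or e.nutrient < 0:
                out.append(f"negative detritus entry in {name}")
            if lag is not None and e.age >= lag:
                out.append(f"{name} entry age {e.age} >= decomposition lag {lag}")
    return out


# ---------------------------------------------------------------------------
# Trait sampling (founder/immigrant distributions)


def plant_traits_from_csr(
    form: str, csr: tuple[float, float, float], config: Config, nitrogen_fixer: bool = False
) -> PlantTraits:
    """Derive physiology from a CSR allocation.

    Competitive points buy height and some growth; ruderal points buy
    colonisation speed (area expansion) and growth; stress-tolerant points
    buy resistance (low Cs) at the cost of growth.
    """
    c, s, r = csr
    if form == "herbaceous":
        g_min, g_max = config.grass_growth_min, config.grass_growth_max
        h_base, e_base = config.grass_height_base, config.grass_area_rate_base
        nf = config.nutrient_content_grass
    elif form == "arboreous":
        g_min, g_max = config.tree_growth_min, config.tree_growth_max
        h_base, e_base = config.tree_height_base, config.tree_area_rate_base
        nf = config.nutrient_content_tree
    else:
        raise ValueError(f"unknown plant form {form!r}")
    growth = g_min + (g_max - g_min) * (0.6 * r + 0.4 * c) / 100.0
    height = h_base * (0.5 + c / 100.0)
    e_rate = e_base * (0.5 + r / 100.0)
    cs = 1.0 - s / 100.0
    return PlantTraits(
        form=form,
        csr=(float(c), float(s), float(r)),
        basic_growth_rate=growth,
        height=height,
        area_increase_rate=e_rate,
        stress_tolerance_index=cs,
        nutrient_content=nf,
        nitrogen_fixer=nitrogen_fixer,
    )


def sample_plant_traits(form: str, config: Config, rng: np.random.Generator) -> PlantTraits:
    csr = tuple(rng.dirichlet((1.0, 1.0, 1.0)) * 100.0)
    return plant_traits_from_csr(form, csr, config)


def sample_animal_traits(
    feeding_type: str, config: Config, rng: np.random.Generator
) -> AnimalTraits:
    """Draw an invertebrate trait block.  The feeding interval is assigned
    separately (niche_web.assign_niche) for the consuming guilds."""
    assim = {
        "herbivore": config.assimilation_herbivore,
        "carnivore": config.assimilation_carnivore,
        "scavenger": config.assimilation_scavenger,
        "litter_feeder": config.assimilation_litter_feeder,
    }[feeding_type]
    return AnimalTraits(
        feeding_type=feeding_type,
        niche_value=float(rng.uniform(0.0, 1.0)),
        feeding_center=0.0,
        feeding_range=0.0,
        metabolism_rate=float(rng.uniform(config.metabolism_min, config.metabolism_max)),
        assimilation_rate=assim,
        nutrient_content=config.nutrient_content_animal,
    )


def sample_seabird_traits(config: Config, rng: np.random.Generator) -> SeabirdTraits:
    u = rng.uniform
    return SeabirdTraits(
        body_size=float(u(0.5, 2.0)),
        nesting_area_per_biomass=float(u(0.5, 1.5)) * config.seabird_napb,
        dropping_rate=float(u(0.5, 1.5)) * config.seabird_dropping_rate,
        carcass_rate=float(u(0.5, 1.5)) * config.seabird_carcass_rate,
        trampling_coefficient=float(u(0.5, 1.5)) * config.seabird_trampling,
        nutrient_content=config.nutrient_content_seabird,
    )


def initial_biomass(category: str, config: Config) -> float:
    if category == "grass":
        return config.initial_biomass_grass
    if category == "tree":
        return config.initial_biomass_tree
    if category == "seabird":
        return config.initial_biomass_seabird
    return config.initial_biomass_animal
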
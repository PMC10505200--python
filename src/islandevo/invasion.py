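"""The four alien species, the invasion event, and goat eradication.

Goats are generalist herbivores that trample plants and interfere with
seabird nesting; rats are generalist omnivores and scavengers; white
popinac (*Leucaena leucocephala*) is a ruderal, nitrogen-fixing pioneer
tree; Korean lawn grass is a ruderal turf grass.  Eradication removes a
fixed goat biomass per step, retaining the carcasses in the system.
"""

from __future__ import annotations

from .domain_model import (
    AnimalTraits,
    Config,
    IslandState,
    SpeciesState,
    plant_traits_from_csr,
)
from .dynamics import claim_seed_area

POPINAC_CSR = (20.0, 10.0, 70.0)
LAWN_GRASS_CSR = (10.0, 30.0, 60.0)


def make_aliens(state: IslandState, config: Config) -> list[SpeciesState]:
    """Construct the four aliens (goat, rat, white popinac, Korean lawn
    grass) with ids drawn from the state's counter."""
    goat = SpeciesState(
        id=state.new_id(),
        category="goat",
        traits=AnimalTraits(
            feeding_type="herbivore",
            niche_value=0.0,
            feeding_center=0.0,
            feeding_range=0.0,  # generalist: prey set bypasses the interval
            metabolism_rate=config.goat_metabolism,
            assimilation_rate=config.goat_assimilation,
            nutrient_content=config.goat_nutrient_content,
        ),
        biomass=config.goat_intro_biomass,
        origin="alien",
        birth_step=state.step,
    )
    rat = SpeciesState(
        id=state.new_id(),
        category="rat",
        traits=AnimalTraits(
            feeding_type="omnivore",
            niche_value=0.0,
            feeding_center=0.0,
            feeding_range=0.0,
            metabolism_rate=config.rat_metabolism,
            assimilation_rate=config.rat_assimilation,
            nutrient_content=config.rat_nutrient_content,
        ),
        biomass=config.rat_intro_biomass,
        origin="alien",
        birth_step=state.step,
    )
    popinac_traits = plant_traits_from_csr(
        "arboreous", POPINAC_CSR, config, nitrogen_fixer=True
    )
    # Pioneer: top of the arboreous growth range.
    popinac_traits.basic_growth_rate = config.tree_growth_max
    popinac = SpeciesState(
        id=state.new_id(),
        category="tree",
        traits=popinac_traits,
        biomass=config.immigrant_biomass_fraction * config.initial_biomass_tree,
        origin="alien",
        birth_step=state.step,
    )
    lawn_grass = SpeciesState(
        id=state.new_id(),
        category="grass",
        traits=plant_traits_from_csr("herbaceous", LAWN_GRASS_CSR, config),
        biomass=config.immigrant_biomass_fraction * config.initial_biomass_grass,
        origin="alien",
        birth_step=state.step,
    )
    return [goat, rat, popinac, lawn_grass]


def invade(state: IslandState, config: Config) -> list[SpeciesState]:
    """Append the aliens to the community at the invasion boundary."""
    if any(s.origin == "alien" for s in state.species):
        raise RuntimeError("invasion refused: alien species already present")
    aliens = make_aliens(state, config)
    for sp in aliens:
        state.add_species(sp)
        claim_seed_area(state, sp, config)
        # Introduced biomass is an import into the closed nutrient cycle.
        state.cumulative_input += sp.biomass * sp.traits.nutrient_content
    return aliens


def eradicate_goats_step(state: IslandState, config: Config) -> float:
    """Remove up to ``goat_removal_per_step`` tons of goat biomass; the
    carcasses stay on the island, so the nutrient ledger is untouched.
    Returns the mass actually removed."""
    removal = config.goat_removal_per_step
    removed_total = 0.0
    for sp in state.by_category("goat"):
        if removal <= 0:
            break
        removed = min(removal, sp.biomass)
        sp.biomass -= removed
        removal -= removed
        removed_total += removed
        if removed > 0:
            state.pools.add("carcasses", removed, removed * sp.traits.nutrient_content)
    return removed_total
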
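"""Small hand-checkable island states for tests and examples."""

from __future__ import annotations

import numpy as np

from .domain_model import (
    AnimalTraits,
    Config,
    IslandState,
    Pools,
    SeabirdTraits,
    SpeciesState,
    plant_traits_from_csr,
)
from .runner import founder_state


def make_fixture(kind: str, config: Config | None = None, seed: int = 0) -> IslandState:
    """Return a ready-made state.

    ``founder``: the study's initial state (one grass, one seabird).
    ``midweb``: a nine-species community with hand-set traits whose niche
    intervals are chosen so every consumer has prey.
    ``pre_invasion_forest``: a deterministic fully forested island at the
    95% cap, for invasion/eradication tests.
    """
    config = config or Config()
    if kind == "founder":
        return founder_state(config, seed)
    if kind == "midweb":
        return _midweb(config, seed)
    if kind == "pre_invasion_forest":
        return _pre_invasion_forest(config, seed)
    raise ValueError(f"unknown fixture kind {kind!r}")


def _add(state: IslandState, category: str, traits, biomass: float, area: float = 0.0):
    sp = SpeciesState(
        id=state.new_id(), category=category, traits=traits, biomass=biomass, area=area
    )
    state.add_species(sp)
    return sp


def _seabird_traits(config: Config, body_size: float = 1.0) -> SeabirdTraits:
    return SeabirdTraits(
        body_size=body_size,
        nesting_area_per_biomass=config.seabird_napb,
        dropping_rate=config.seabird_dropping_rate,
        carcass_rate=config.seabird_carcass_rate,
        trampling_coefficient=config.seabird_trampling,
        nutrient_content=config.nutrient_content_seabird,
    )


def _animal(
    config: Config, feeding_type: str, center: float, width: float, niche: float
) -> AnimalTraits:
    assim = {
        "herbivore": config.assimilation_herbivore,
        "carnivore": config.assimilation_carnivore,
        "scavenger": config.assimilation_scavenger,
        "litter_feeder": config.assimilation_litter_feeder,
    }[feeding_type]
    return AnimalTraits(
        feeding_type=feeding_type,
        niche_value=niche,
        feeding_center=center,
        feeding_range=width,
        metabolism_rate=0.01,
        assimilation_rate=assim,
        nutrient_content=config.nutrient_content_animal,
    )


def _midweb(config: Config, seed: int) -> IslandState:
    state = IslandState(
        step=0,
        species=[],
        pools=Pools(nutrient=config.initial_pool_nutrient),
        rng=np.random.default_rng(seed),
        island_area=config.island_area_km2,
        forest_cap=config.forest_cap,
    )
    # Plants at diet-axis positions C/100 = 0.30, 0.40, 0.60.
    g1 = plant_traits_from_csr("herbaceous", (30.0, 20.0, 50.0), config)
    g2 = plant_traits_from_csr("herbaceous", (40.0, 40.0, 20.0), config)
    t1 = plant_traits_from_csr("arboreous", (60.0, 20.0, 20.0), config)
    _add(state, "grass", g1, 200.0, area=200.0 * config.specific_area_grass)
    _add(state, "grass", g2, 100.0, area=100.0 * config.specific_area_grass)
    _add(state, "tree", t1, 2000.0, area=2000.0 * config.specific_area_tree)
    # Herbivores covering the plant positions; niche values 0.3 and 0.5.
    _add(state, "herbivore", _animal(config, "herbivore", 0.35, 0.2, 0.3), 5.0)
    _add(state, "herbivore", _animal(config, "herbivore", 0.55, 0.3, 0.5), 3.0)
    # Carnivore whose interval covers both herbivore niche values.
    _add(state, "carnivore", _animal(config, "carnivore", 0.4, 0.5, 0.8), 1.0)
    _add(state, "scavenger", _animal(config, "scavenger", 0.0, 0.0, 0.2), 0.5)
    _add(state, "litter_feeder", _animal(config, "litter_feeder", 0.0, 0.0, 0.6), 0.5)
    sb = _add(state, "seabird", _seabird_traits(config), 10.0)
    sb.area = min(1.0, sb.biomass * sb.traits.nesting_area_per_biomass)
    return state


def _pre_invasion_forest(config: Config, seed: int) -> IslandState:
    state = IslandState(
        step=config.invasion_step,
        species=[],
        pools=Pools(nutrient=50.0),
        rng=np.random.default_rng(seed),
        island_area=config.island_area_km2,
        forest_cap=config.forest_cap,
    )
    tree = plant_traits_from_csr("arboreous", (50.0, 30.0, 20.0), config)
    biomass = config.forest_cap / config.specific_area_tree
    _add(state, "tree", tree, biomass, area=config.forest_cap)
    grass = plant_traits_from_csr("herbaceous", (30.0, 30.0, 40.0), config)
    _add(state, "grass", grass, 10.0, area=10.0 * config.specific_area_grass)
    _add(state, "herbivore", _animal(config, "herbivore", 0.45, 0.3, 0.4), 4.0)
    sb = _add(state, "seabird", _seabird_traits(config), 20.0)
    sb.area = min(1.0, sb.biomass * sb.traits.nesting_area_per_biomass)
    return state
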
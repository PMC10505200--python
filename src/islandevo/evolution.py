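"""Immigration and speciation during the 100,000-step evolution phase.

Every ``immigration_interval`` steps a brand-new species (one of seven
categories, drawn uniformly) arrives at one tenth of the founder biomass.
Every ``speciation_interval`` steps one species is given the opportunity to
speciate; the opportunity rotates over herbaceous plants, arboreous plants,
herbivores and carnivores (detritivores and seabirds never speciate -- fed
from outside the island's plant production, their diversity would grow
without bound).  The offspring takes 5% of the ancestor's biomass, and every
mutable trait is perturbed by a zero-mean Gaussian whose standard deviation
is ~10% of the trait value, scaled by the ancestor's evolutionary rate.
"""

from __future__ import annotations

import copy
from typing import Optional

import numpy as np

from .domain_model import (
    AnimalTraits,
    Config,
    IMMIGRANT_CATEGORIES,
    IslandState,
    PlantTraits,
    SPECIATION_ROTATION,
    SeabirdTraits,
    SpeciesState,
    initial_biomass,
    plant_traits_from_csr,
    sample_animal_traits,
    sample_plant_traits,
    sample_seabird_traits,
)
from .niche_web import NICHE_FEEDERS, assign_niche, clip_interval
from .dynamics import claim_seed_area


def _in_evolution_phase(state: IslandState, config: Config) -> bool:
    return state.step < config.evolve_steps


def make_species(
    category: str, state: IslandState, config: Config, biomass: float, origin: str
) -> SpeciesState:
    """Draw a founder-style species of the given category."""
    rng = state.rng
    if category in ("grass", "tree"):
        form = "herbaceous" if category == "grass" else "arboreous"
        traits = sample_plant_traits(form, config, rng)
    elif category == "seabird":
        traits = sample_seabird_traits(config, rng)
    else:
        traits = sample_animal_traits(category, config, rng)
        if traits.feeding_type in NICHE_FEEDERS:
            assign_niche(traits, config, rng)
    return SpeciesState(
        id=state.new_id(),
        category=category,
        traits=traits,
        biomass=biomass,
        origin=origin,
        birth_step=state.step,
    )


def immigrate(state: IslandState, config: Config) -> SpeciesState:
    """One immigration event: uniform category, tenth-strength founder."""
    if not _in_evolution_phase(state, config):
        raise RuntimeError(
            f"immigration refused at step {state.step}: outside the evolution phase"
        )
    category = str(state.rng.choice(IMMIGRANT_CATEGORIES))
    biomass = config.immigrant_biomass_fraction * initial_biomass(category, config)
    sp = make_species(category, state, config, biomass, origin="immigrant")
    state.add_species(sp)
    claim_seed_area(state, sp, config)
    # Propagules arrive from off-island: their nutrient is an import.
    state.cumulative_input += sp.biomass * sp.traits.nutrient_content
    return sp


def select_speciation_candidate(
    state: IslandState, event_counter: int
) -> Optional[SpeciesState]:
    """Rotate the speciation opportunity over grass, tree, herbivore,
    carnivore; pick uniformly within the category, skipping empty ones."""
    n = len(SPECIATION_ROTATION)
    for offset in range(n):
        category = SPECIATION_ROTATION[(event_counter + offset) % n]
        pool = [s for s in state.by_category(category) if s.biomass > 0]
        if pool:
            idx = int(state.rng.integers(len(pool)))
            return pool[idx]
    return None


def _mutate_value(
    value: float, sd_fraction: float, e_rate: float, rng: np.random.Generator,
    low: Optional[float] = None, high: Optional[float] = None,
) -> float:
    v = value + rng.normal(0.0, abs(sd_fraction * value * e_rate))
    if low is not None:
        v = max(v, low)
    if high is not None:
        v = min(v, high)
    return v


def _mutate_csr(
    csr: tuple[float, float, float], sd_fraction: float, e_rate: float,
    rng: np.random.Generator,
) -> tuple[float, float, float]:
    """Perturb two coordinates on the 100-point simplex, derive the third,
    rejecting draws that leave the simplex."""
    sd = sd_fraction * e_rate * 100.0 / 3.0  # ~10% of the mean coordinate
    for _ in range(100):
        c = csr[0] + rng.normal(0.0, sd)
        s = csr[1] + rng.normal(0.0, sd)
        r = 100.0 - c - s
        if c >= 0.0 and s >= 0.0 and r >= 0.0:
            return (c, s, r)
    return csr


def speciate(
    ancestor: SpeciesState, state: IslandState, config: Config
) -> SpeciesState:
    """Split off a daughter species carrying 5% of the ancestor's biomass.

    The lineage's biomass is conserved exactly at the event.  Nutrient
    content is inherited unchanged; all other heritable traits mutate."""
    if ancestor.biomass <= 0:
        raise ValueError(f"cannot speciate extinct ancestor {ancestor.id}")
    rng = state.rng
    sd = config.mutation_sd_fraction
    # Split so the two parts sum to the ancestor's biomass EXACTLY in
    # floating point (M - (M - x) is exact for x <= M/2 by Sterbenz).
    total = ancestor.biomass
    ancestor.biomass = total - config.speciation_biomass_fraction * total
    offspring_biomass = total - ancestor.biomass

    t = ancestor.traits
    if isinstance(t, PlantTraits):
        e = t.evolutionary_rate
        csr = _mutate_csr(t.csr, sd, e, rng)
        traits = plant_traits_from_csr(t.form, csr, config, nitrogen_fixer=t.nitrogen_fixer)
        traits.nutrient_content = t.nutrient_content  # inherited, not re-derived
        traits.evolutionary_rate = t.evolutionary_rate
        if sd == 0.0 or e == 0.0:
            traits = copy.deepcopy(t)
    elif isinstance(t, AnimalTraits):
        e = t.evolutionary_rate
        traits = AnimalTraits(
            feeding_type=t.feeding_type,
            niche_value=_mutate_value(t.niche_value, sd, e, rng, 0.0, 1.0),
            feeding_center=_mutate_value(t.feeding_center, sd, e, rng, 0.0, 1.0),
            feeding_range=_mutate_value(t.feeding_range, sd, e, rng, 0.0, 1.0),
            metabolism_rate=_mutate_value(t.metabolism_rate, sd, e, rng, 0.0),
            assimilation_rate=_mutate_value(t.assimilation_rate, sd, e, rng, 1e-6, 1.0),
            nutrient_content=t.nutrient_content,
            evolutionary_rate=t.evolutionary_rate,
        )
        clip_interval(traits)
    else:
        raise ValueError(f"category {ancestor.category} is not eligible for speciation")

    sp = SpeciesState(
        id=state.new_id(),
        category=ancestor.category,
        traits=traits,
        biomass=offspring_biomass,
        origin="speciation",
        ancestor_id=ancestor.id,
        birth_step=state.step,
    )
    state.add_species(sp)
    claim_seed_area(state, sp, config)
    return sp


def maybe_evolve(state: IslandState, config: Config, event_counter: list[int]) -> None:
    """Fire the immigration/speciation events scheduled for this step.

    ``event_counter`` is a single-element mutable counter of speciation
    opportunities granted so far (drives the category rotation)."""
    if not _in_evolution_phase(state, config):
        return
    if state.step > 0 and state.step % config.immigration_interval == 0:
        immigrate(state, config)
    if state.step > 0 and state.step % config.speciation_interval == 0:
        ancestor = select_speciation_candidate(state, event_counter[0])
        event_counter[0] += 1
        if ancestor is not None:
            speciate(ancestor, state, config)
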
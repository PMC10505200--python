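"""Interaction web: who eats whom, with what preference, and who competes.

Predator-prey links follow the one-dimensional niche model: each consumer
draws a niche position n ~ U(0,1), a feeding-range width r = n*x with
x ~ Beta(1, beta), and a feeding centre c ~ U(r/2, n).  Species whose
diet-axis position falls inside [c - r/2, c + r/2] are potential prey.
Plants are embedded on the herbivore diet axis at C/100 (their competitive
score); animals sit at their niche value on the carnivore axis.

Goats and rats bypass the interval rule: goats eat every plant, rats eat
every plant and invertebrate and additionally scavenge the carcass pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .domain_model import (
    AnimalTraits,
    Config,
    IslandState,
    PLANT_CATEGORIES,
    INVERTEBRATE_CATEGORIES,
    SpeciesState,
)

# Guilds whose members carry a feeding interval.
NICHE_FEEDERS = ("herbivore", "carnivore", "omnivore")


def assign_niche(traits: AnimalTraits, config: Config, rng: np.random.Generator) -> AnimalTraits:
    """Draw the niche-model feeding interval for a consuming guild member.

    Mutates and returns ``traits``.  Detritivores feed on the detritus
    compartments and have no interval; passing one is an error.
    """
    if traits.feeding_type not in NICHE_FEEDERS:
        raise ValueError(f"{traits.feeding_type} has no niche interval")
    n = float(rng.uniform(0.0, 1.0))
    x = float(rng.beta(1.0, config.niche_beta))
    r = n * x
    c = float(rng.uniform(r / 2.0, n)) if n > 0 else 0.0
    traits.niche_value = n
    traits.feeding_range = r
    traits.feeding_center = c
    clip_interval(traits)
    return traits


def clip_interval(traits: AnimalTraits) -> None:
    """Clip the feeding interval into [0, 1], preserving its width where
    possible."""
    r = min(max(traits.feeding_range, 0.0), 1.0)
    c = min(max(traits.feeding_center, r / 2.0), 1.0 - r / 2.0)
    traits.feeding_range = r
    traits.feeding_center = c


def _in_interval(position: float, traits: AnimalTraits) -> bool:
    half = traits.feeding_range / 2.0
    return traits.feeding_center - half <= position <= traits.feeding_center + half


def candidate_prey(predator: SpeciesState, community: list[SpeciesState]) -> list[int]:
    """Ids of community members the predator can feed on.

    Generalists (goat, rat) ignore the niche interval.  Carnivore prey are
    the invertebrate guilds; large vertebrates are outside the invertebrate
    food web.
    """
    if predator.category == "goat":
        return [s.id for s in community if s.is_plant]
    if predator.category == "rat":
        return [
            s.id
            for s in community
            if (s.is_plant or s.category in INVERTEBRATE_CATEGORIES) and s.id != predator.id
        ]

    traits = predator.traits
    if not isinstance(traits, AnimalTraits) or traits.feeding_type not in NICHE_FEEDERS:
        raise ValueError(f"species {predator.id} ({predator.category}) is not a niche feeder")
    if traits.feeding_range <= 0.0:
        return []
    if traits.feeding_type == "herbivore":
        universe = [s for s in community if s.is_plant]
    else:  # carnivore: invertebrate prey on the niche axis
        universe = [
            s for s in community if s.category in INVERTEBRATE_CATEGORIES and s.id != predator.id
        ]
    return [s.id for s in universe if _in_interval(s.diet_axis_position, traits)]


def preference_weight(predator: SpeciesState, prey: SpeciesState) -> float:
    """Feeding-effort weight; strictly decreasing in distance from the
    feeding centre (triangular kernel on the interval).  Generalists rank
    prey by nutrient content instead."""
    if predator.category in ("goat", "rat"):
        return prey.traits.nutrient_content
    traits = predator.traits
    half = traits.feeding_range / 2.0
    if half <= 0.0:
        return 0.0
    d = abs(prey.diet_axis_position - traits.feeding_center)
    return max(0.0, 1.0 - d / half)


def plant_competitor_pairs(
    plants: list[SpeciesState], config: Config
) -> list[tuple[int, int, float]]:
    """Ordered (encroacher_id, encroached_id, H12) triples.

    Plants compete when their diet-axis positions (C/100) are closer than
    the overlap threshold; the taller encroaches the shorter.  Herbaceous
    plants cannot encroach trees.  H12 = (h1 - h2)/(h1 + h2).
    """
    n = len(plants)
    if n < 2:
        return []
    pos = np.array([p.diet_axis_position for p in plants])
    height = np.array([p.traits.height for p in plants])
    herb = np.array([p.traits.form == "herbaceous" for p in plants])
    out: list[tuple[int, int, float]] = []
    for i in range(n - 1):
        j = np.arange(i + 1, n)
        # Within a growth form, only strategically similar plants contest
        # the same ground; across forms the canopy shades the herb layer
        # regardless of strategy, so tree-grass pairs always compete.
        close = (np.abs(pos[j] - pos[i]) < config.competition_overlap_threshold) | (
            herb[j] != herb[i]
        )
        for jj in j[close]:
            h1, h2 = height[i], height[jj]
            if h1 == h2:
                continue
            ti, si = (i, jj) if h1 > h2 else (jj, i)
            if herb[ti] and not herb[si]:
                continue
            h12 = (height[ti] - height[si]) / (height[ti] + height[si])
            out.append((plants[ti].id, plants[si].id, float(h12)))
    return out


def seabird_competitor_pairs(seabirds: list[SpeciesState]) -> list[tuple[int, int]]:
    """All ordered (bigger, smaller) pairs by body size; nest space is a
    single shared resource, so every seabird pair competes."""
    out: list[tuple[int, int]] = []
    for i, s1 in enumerate(seabirds):
        for s2 in seabirds[i + 1 :]:
            if s1.traits.body_size == s2.traits.body_size:
                continue
            big, small = (s1, s2) if s1.traits.body_size > s2.traits.body_size else (s2, s1)
            out.append((big.id, small.id))
    return out


def competitor_pairs(layer: list[SpeciesState], config: Config):
    """Dispatch on layer type: plant pairs carry H12, seabird pairs do not."""
    if not layer:
        return []
    if layer[0].is_seabird:
        return seabird_competitor_pairs(layer)
    return plant_competitor_pairs(layer, config)


@dataclass
class InteractionWeb:
    """Cached link structure, rebuilt whenever the community changes.

    ``diets`` maps each consumer id to its prey ids sorted by descending
    preference weight (ties broken by species id for determinism).
    ``plant_pair_arrays`` holds the same competition pairs as index/value
    numpy arrays over ``plant_refs`` for the per-step fast path.
    """

    diets: dict[int, list[int]] = field(default_factory=dict)
    plant_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    seabird_pairs: list[tuple[int, int]] = field(default_factory=list)
    plant_refs: list[SpeciesState] = field(default_factory=list)
    plant_pair_arrays: Optional[dict[str, np.ndarray]] = None


def _sorted_diet(
    predator: SpeciesState,
    universe_ids: np.ndarray,
    positions: np.ndarray,
    nutrient_contents: np.ndarray,
) -> list[int]:
    """Vectorised candidate selection + preference ordering for one consumer."""
    if predator.category in ("goat", "rat"):
        weights = nutrient_contents
        mask = np.ones(len(universe_ids), dtype=bool)
    else:
        t = predator.traits
        half = t.feeding_range / 2.0
        if half <= 0.0:
            return []
        dist = np.abs(positions - t.feeding_center)
        mask = dist <= half
        weights = 1.0 - dist / half
    ids = universe_ids[mask]
    w = weights[mask]
    order = np.lexsort((ids, -w))
    return ids[order].tolist()


def build_web(state: IslandState, config: Config) -> InteractionWeb:
    """Assemble the full link structure in one pass (vectorised over prey)."""
    web = InteractionWeb()
    plants = state.plants()
    inverts = state.by_category(*INVERTEBRATE_CATEGORIES)
    plant_ids = np.array([s.id for s in plants], dtype=np.int64)
    plant_pos = np.array([s.diet_axis_position for s in plants], dtype=float)
    plant_nf = np.array([s.traits.nutrient_content for s in plants], dtype=float)
    inv_ids = np.array([s.id for s in inverts], dtype=np.int64)
    inv_pos = np.array([s.diet_axis_position for s in inverts], dtype=float)
    inv_nf = np.array([s.traits.nutrient_content for s in inverts], dtype=float)

    for sp in state.species:
        if sp.category == "goat":
            web.diets[sp.id] = _sorted_diet(sp, plant_ids, plant_pos, plant_nf)
        elif sp.category == "rat":
            ids = np.concatenate([plant_ids, inv_ids])
            pos = np.concatenate([plant_pos, inv_pos])
            nf = np.concatenate([plant_nf, inv_nf])
            web.diets[sp.id] = _sorted_diet(sp, ids, pos, nf)
        elif isinstance(sp.traits, AnimalTraits) and sp.traits.feeding_type in NICHE_FEEDERS:
            if sp.traits.feeding_type == "herbivore":
                web.diets[sp.id] = _sorted_diet(sp, plant_ids, plant_pos, plant_nf)
            else:
                diet = _sorted_diet(sp, inv_ids, inv_pos, inv_nf)
                web.diets[sp.id] = [i for i in diet if i != sp.id]
    web.plant_pairs = plant_competitor_pairs(plants, config)
    web.seabird_pairs = seabird_competitor_pairs(state.seabirds())
    web.plant_refs = plants
    idx = {p.id: i for i, p in enumerate(plants)}
    if web.plant_pairs:
        web.plant_pair_arrays = {
            "tall": np.array([idx[t] for t, _, _ in web.plant_pairs], dtype=np.intp),
            "short": np.array([idx[s] for _, s, _ in web.plant_pairs], dtype=np.intp),
            "h12": np.array([h for _, _, h in web.plant_pairs], dtype=float),
            "e1": np.array(
                [plants[idx[t]].traits.area_increase_rate for t, _, _ in web.plant_pairs]
            ),
            "cs2": np.array(
                [plants[idx[s]].traits.stress_tolerance_index for _, s, _ in web.plant_pairs]
            ),
        }
    else:
        web.plant_pair_arrays = None
    return web
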
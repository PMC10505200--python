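"""One daily time-step of the closed nutrient cycle.

Sub-step order is fixed: seabird input -> interference -> plant growth ->
feeding (herbivores, carnivores, omnivores) -> plant competition -> seabird
competition -> detritus cycle -> extinction sweep.  Nutrient enters the
system only as seabird subsidy (droppings plus net biomass growth fuelled by
fish at sea) and nitrogen fixation; it leaves only by weathering of
detritus.  Every other flow is an internal transfer, so the ledger

    total_system_nutrient = initial + cumulative_input - cumulative_weathered

closes to rounding error over arbitrarily long runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .domain_model import (
    AnimalTraits,
    Config,
    IslandState,
    PlantTraits,
    SpeciesState,
)
from .niche_web import InteractionWeb, build_web

_EPS = 1e-15


@dataclass
class StepFluxes:
    """Per-step nutrient ledger (all in tons of nutrient, all >= 0)."""

    nutrient_in: float = 0.0  # seabird subsidy + nitrogen fixation
    nutrient_uptake: float = 0.0  # pool -> plants
    detritus_produced: dict[str, float] = field(
        default_factory=lambda: {"droppings": 0.0, "carcasses": 0.0, "litter": 0.0}
    )
    detritus_consumed: float = 0.0  # detritivore + rat-scavenging intake
    nutrient_released: float = 0.0  # decomposition: detritus -> pool
    weathered: float = 0.0  # export


def holling_flux(m1: float, m2: float, k: float, h: float) -> float:
    """Holling type III potential feeding flux k*M1*M2^2/(h + M2^2)."""
    if m1 < 0 or m2 < 0:
        raise ValueError("biomasses must be non-negative")
    if h <= 0:
        raise ValueError("handling constant h must be positive")
    return k * m1 * m2 * m2 / (h + m2 * m2)


def specific_area(sp: SpeciesState, config: Config) -> float:
    """Habitat area fraction one ton of this plant occupies."""
    return (
        config.specific_area_grass
        if sp.traits.form == "herbaceous"
        else config.specific_area_tree
    )


def ensure_web(state: IslandState, config: Config) -> InteractionWeb:
    web = getattr(state, "_web", None)
    if web is None or state.web_dirty:
        web = build_web(state, config)
        state._web = web
        state.web_dirty = False
    return web


# ---------------------------------------------------------------------------
# Establishment of new plants (used by immigration, speciation, invasion)


def claim_seed_area(state: IslandState, sp: SpeciesState, config: Config) -> None:
    """Give a newly arrived plant its seed area.

    Free ground is used first.  A tree seedling short of free ground may
    additionally displace shorter (herbaceous) vegetation proportionally --
    seedlings establish under an open canopy -- with the displaced biomass
    entering the litter pool.
    """
    if not sp.is_plant:
        return
    target = min(config.seed_area, sp.biomass * specific_area(sp, config))
    plant_total = sum(s.area for s in state.species if s.is_plant and s.id != sp.id)
    free = max(0.0, 1.0 - plant_total)
    if sp.category == "tree":
        forest = sum(s.area for s in state.species if s.category == "tree" and s.id != sp.id)
        target = min(target, max(0.0, state.forest_cap - forest))
    claimed = min(target, free)
    shortfall = target - claimed
    if shortfall > _EPS and sp.category == "tree":
        shorter = [
            s
            for s in state.species
            if s.is_plant and s.id != sp.id and s.traits.height < sp.traits.height and s.area > 0
        ]
        pool_area = sum(s.area for s in shorter)
        if pool_area > _EPS:
            taken = min(shortfall, pool_area)
            frac = taken / pool_area
            for s in shorter:
                lost_area = s.area * frac
                lost_mass = s.biomass * frac
                s.area = max(0.0, s.area - lost_area)
                s.biomass = max(0.0, s.biomass - lost_mass)
                state.pools.add("litter", lost_mass, lost_mass * s.traits.nutrient_content)
            claimed += taken
    sp.area = claimed


# ---------------------------------------------------------------------------
# Sub-steps


def interference(state: IslandState, config: Config) -> tuple[float, float, float]:
    """(tree growth modifier, grass growth modifier, nesting-capacity factor).

    Nesting seabirds trample all vegetation around their colonies.  Goats
    suppress woody regeneration (seedling and sapling browsing) but leave
    the grazing lawn growing; they also shrink the usable nesting layer.
    All factors are linear in the pressure and clipped to [0, 1].
    """
    seabird_pressure = sum(s.traits.trampling_coefficient * s.area for s in state.seabirds())
    goats = state.goat_biomass()
    tree_modifier = min(
        1.0, max(0.0, 1.0 - seabird_pressure - config.goat_trample_plants * goats)
    )
    grass_modifier = min(
        1.0, max(0.0, 1.0 - seabird_pressure - config.goat_trample_grass * goats)
    )
    nest_factor = min(1.0, max(0.0, 1.0 - config.goat_nest_interference * goats))
    return tree_modifier, grass_modifier, nest_factor


def seabird_input(state: IslandState, config: Config, fluxes: StepFluxes) -> None:
    """Seabird subsidy and colony dynamics.

    Droppings are fish-derived (external input).  Seabird biomass relaxes
    logistically toward its nesting-area-limited carrying capacity: growth is
    external input (feeding at sea is never limiting), decline enters the
    carcass pool.  Natural mortality also feeds the carcass pool.
    """
    birds = sorted(state.seabirds(), key=lambda s: s.id)
    if not birds:
        return
    _, _, nest_factor = interference(state, config)
    for sp in birds:
        t = sp.traits
        drop = sp.biomass * t.dropping_rate
        if drop > 0:
            nut = drop * t.nutrient_content
            state.pools.add("droppings", drop, nut)
            state.cumulative_input += nut
            fluxes.nutrient_in += nut
            fluxes.detritus_produced["droppings"] += nut
        carc = sp.biomass * t.carcass_rate
        if carc > 0:
            sp.biomass -= carc
            nut = carc * t.nutrient_content
            state.pools.add("carcasses", carc, nut)
            fluxes.detritus_produced["carcasses"] += nut

    areas = {sp.id: sp.biomass * sp.traits.nesting_area_per_biomass for sp in birds}
    total = sum(areas.values())
    cap = nest_factor
    free = max(0.0, cap - total)
    for sp in birds:
        napb = sp.traits.nesting_area_per_biomass
        if napb <= 0:
            continue
        if total > cap and total > 0:
            avail = cap * areas[sp.id] / total
        else:
            avail = areas[sp.id] + free
        k_cap = avail / napb
        if k_cap <= 0:
            delta = -config.seabird_growth_rate * sp.biomass
        else:
            delta = config.seabird_growth_rate * sp.biomass * (1.0 - sp.biomass / k_cap)
        if delta >= 0:
            sp.biomass += delta
            nut = delta * sp.traits.nutrient_content
            state.cumulative_input += nut
            fluxes.nutrient_in += nut
        else:
            delta = max(delta, -sp.biomass)
            sp.biomass += delta
            nut = -delta * sp.traits.nutrient_content
            state.pools.add("carcasses", -delta, nut)
            fluxes.detritus_produced["carcasses"] += nut

    # Re-derive nesting areas, squeezed proportionally into the usable layer.
    areas = {sp.id: sp.biomass * sp.traits.nesting_area_per_biomass for sp in birds}
    total = sum(areas.values())
    scale = min(1.0, cap / total) if total > 0 else 1.0
    for sp in birds:
        sp.area = areas[sp.id] * scale


def plant_growth(
    state: IslandState,
    config: Config,
    fluxes: StepFluxes,
    tree_modifier: float = 1.0,
    grass_modifier: float = 1.0,
) -> None:
    """Nutrient-regulated plant growth with space-limited area expansion.

    Each plant demands biomass growth proportional to its growth rate and
    remaining space capacity; the nutrient cost is drawn from the pool,
    shared proportionally to demand when the pool is short.  Nitrogen fixers
    cover a fixed fraction of their demand from the atmosphere.  Under
    shortfall, biomass declines in proportion to the unmet fraction and the
    plant's stress sensitivity (Cs).  Litter is shed at a constant rate.
    """
    plants = sorted(state.plants(), key=lambda s: s.id)
    if not plants:
        return
    plant_total = sum(s.area for s in plants)
    forest_total = sum(s.area for s in plants if s.category == "tree")
    free = max(0.0, 1.0 - plant_total)
    forest_room = max(0.0, state.forest_cap - forest_total)
    # Goat trampling/browsing and rat seedling predation kill standing
    # woody vegetation in proportion to the herds; shed to litter below.
    trample_kill = min(
        0.5,
        config.goat_trample_kill * state.goat_biomass()
        + config.rat_tree_kill * state.rat_biomass(),
    )

    wants: dict[int, float] = {}
    needs: dict[int, float] = {}
    fixed: dict[int, float] = {}
    for sp in plants:
        t = sp.traits
        sa = specific_area(sp, config)
        room = min(free, forest_room) if sp.category == "tree" else free
        # The overdensity factor lets biomass overshoot the current-area
        # density cap, giving the headroom needed to encroach competitors;
        # without it a space-limited plant could never expand again.
        k_cap = (sp.area * (1.0 + config.plant_overdensity) + room) / sa
        frac = max(0.0, 1.0 - sp.biomass / k_cap) if k_cap > 0 else 0.0
        modifier = tree_modifier if sp.category == "tree" else grass_modifier
        want = sp.biomass * t.basic_growth_rate * modifier * frac
        need = want * t.nutrient_content
        fx = config.nitrogen_fixation_fraction * need if t.nitrogen_fixer else 0.0
        wants[sp.id] = want
        needs[sp.id] = need - fx
        fixed[sp.id] = fx

    total_need = sum(needs.values())
    ratio = 1.0 if total_need <= state.pools.nutrient else (
        state.pools.nutrient / total_need if total_need > 0 else 1.0
    )

    for sp in plants:
        t = sp.traits
        uptake = needs[sp.id] * ratio
        state.pools.nutrient -= uptake
        got = uptake + fixed[sp.id]
        if fixed[sp.id] > 0:
            state.cumulative_input += fixed[sp.id]
            fluxes.nutrient_in += fixed[sp.id]
        fluxes.nutrient_uptake += uptake
        growth = got / t.nutrient_content
        demand = needs[sp.id] + fixed[sp.id]
        met = got / demand if demand > 0 else 1.0
        decline = (
            sp.biomass * config.plant_decline_rate * (1.0 - met) * t.stress_tolerance_index
            if met < 1.0
            else 0.0
        )
        litter = sp.biomass * config.plant_litter_rate
        # Goat damage to woody vegetation scales with the species' stress
        # sensitivity: high-S (low Cs) trees resist browsing and trampling.
        killed = (
            sp.biomass * trample_kill * t.stress_tolerance_index
            if sp.category == "tree"
            else 0.0
        )
        shed = min(decline + litter + killed, sp.biomass + growth)
        sp.biomass = sp.biomass + growth - shed
        if shed > 0:
            state.pools.add("litter", shed, shed * t.nutrient_content)
            fluxes.detritus_produced["litter"] += shed * t.nutrient_content
    state.pools.nutrient = max(0.0, state.pools.nutrient)

    # Area update: shrink to biomass-supported area, expand at most at the
    # area-increase rate and into remaining open ground (trees also under
    # the forest cap).  Sequential in id order.
    plant_total = sum(s.area for s in plants)
    forest_total = sum(s.area for s in plants if s.category == "tree")
    free = max(0.0, 1.0 - plant_total)
    forest_room = max(0.0, state.forest_cap - forest_total)
    for sp in plants:
        sa = specific_area(sp, config)
        target = sp.biomass * sa
        if target <= sp.area:
            freed = sp.area - target
            free += freed
            if sp.category == "tree":
                forest_room += freed
            sp.area = target
        else:
            grown = sp.area * (1.0 + sp.traits.area_increase_rate) if sp.area > 0 else config.seed_area
            room = max(0.0, min(free, forest_room) if sp.category == "tree" else free)
            new_area = min(target, grown, sp.area + room)
            gained = new_area - sp.area
            free -= gained
            if sp.category == "tree":
                forest_room -= gained
            sp.area = new_area


def _eat_detritus(
    predator: SpeciesState,
    compartment: str,
    state: IslandState,
    config: Config,
    remaining: float,
    fluxes: StepFluxes,
) -> tuple[float, float, float]:
    """Feed on a detritus compartment, removing mass proportionally across
    age cohorts.  Returns (mass eaten, nutrient eaten, remaining demand)."""
    queue = state.pools.compartments()[compartment]
    total = sum(e.mass for e in queue)
    if total <= _EPS or remaining <= _EPS:
        return 0.0, 0.0, remaining
    pot = holling_flux(predator.biomass, total, config.holling_k, config.holling_h)
    take = min(pot, total, remaining)
    if take <= _EPS:
        return 0.0, 0.0, remaining
    factor = take / total
    nut = 0.0
    for e in queue:
        nut += e.nutrient * factor
        e.mass *= 1.0 - factor
        e.nutrient *= 1.0 - factor
    fluxes.detritus_consumed += nut
    return take, nut, remaining - take


def _finish_meal(
    sp: SpeciesState,
    intake_mass: float,
    intake_nut: float,
    state: IslandState,
    config: Config,
    fluxes: StepFluxes,
) -> None:
    """Assimilation, egestion, metabolism and background mortality for one
    animal after its feeding pass.  Growth is nutrient-exact: assimilated
    nutrient converts to predator biomass at the predator's own content."""
    t = sp.traits
    a = t.assimilation_rate
    growth = a * intake_nut / t.nutrient_content
    egest_mass = (1.0 - a) * intake_mass
    egest_nut = (1.0 - a) * intake_nut
    nf = t.nutrient_content
    cap = {
        "goat": config.goat_carrying_capacity,
        "rat": config.rat_carrying_capacity,
    }.get(sp.category, 0.0)
    if cap > 0:
        # Alien vertebrates are space/territory-limited as well as food-
        # limited; above the ceiling, assimilated surplus is excreted
        # instead of grown.
        damp = max(0.0, 1.0 - sp.biomass / cap)
        diverted = growth * (1.0 - damp)
        growth *= damp
        egest_mass += diverted
        egest_nut += diverted * nf
    metab = sp.biomass * t.metabolism_rate
    carc = sp.biomass * config.animal_carcass_rate
    sp.biomass = max(0.0, sp.biomass + growth - metab - carc)
    if egest_mass > 0 or metab > 0:
        state.pools.add("droppings", egest_mass + metab, egest_nut + metab * nf)
        fluxes.detritus_produced["droppings"] += egest_nut + metab * nf
    if carc > 0:
        state.pools.add("carcasses", carc, carc * nf)
        fluxes.detritus_produced["carcasses"] += carc * nf


def feed(
    predator: SpeciesState,
    prey_ids: list[int],
    state: IslandState,
    config: Config,
    fluxes: StepFluxes,
    by_id: dict[int, SpeciesState] | None = None,
) -> dict[str, float]:
    """One predator's feeding bout.

    Prey are visited in descending preference order; the potential flux per
    prey is the Holling type III form, truncated the moment cumulative
    intake reaches the demand (biomass * metabolism * demand_factor /
    assimilation).  Rats make an extra scavenging pass on the carcass pool
    after live prey.
    """
    t = predator.traits
    demand = predator.biomass * t.metabolism_rate * config.demand_factor / t.assimilation_rate
    remaining = demand
    intake_mass = 0.0
    intake_nut = 0.0
    by_id = by_id if by_id is not None else {s.id: s for s in state.species}
    for pid in prey_ids:
        if remaining <= _EPS:
            break
        prey = by_id.get(pid)
        if prey is None or prey.biomass <= 0.0:
            continue
        pot = holling_flux(predator.biomass, prey.biomass, config.holling_k, config.holling_h)
        take = min(pot, prey.biomass, remaining)
        if take <= 0.0:
            continue
        prey.biomass -= take
        remaining -= take
        intake_mass += take
        intake_nut += take * prey.traits.nutrient_content
        # Goats destroy far more woody vegetation than they ingest (bark
        # stripping, browsing damage, killed seedlings); the wrecked biomass
        # enters the litter pool rather than the goat.  Grazing on the herb
        # layer has no such multiplier.
        if (
            predator.category == "goat"
            and prey.category == "tree"
            and config.goat_destruction_factor > 0
        ):
            wrecked = min(take * config.goat_destruction_factor, prey.biomass)
            if wrecked > 0:
                prey.biomass -= wrecked
                state.pools.add("litter", wrecked, wrecked * prey.traits.nutrient_content)
                fluxes.detritus_produced["litter"] += wrecked * prey.traits.nutrient_content
    if predator.category == "rat" and remaining > _EPS:
        m, n, remaining = _eat_detritus(predator, "carcasses", state, config, remaining, fluxes)
        intake_mass += m
        intake_nut += n
    _finish_meal(predator, intake_mass, intake_nut, state, config, fluxes)
    return {"intake_mass": intake_mass, "intake_nutrient": intake_nut, "demand": demand}


def encroach(state: IslandState, config: Config, web: InteractionWeb) -> None:
    """Plant-plant habitat competition, pair by pair in fixed order.

    dA2 = E1 * A1 * A2 * H12 * Cs2: the taller plant takes habitat from the
    shorter; the loser's biomass scales down with its lost area (to litter).
    The winner only occupies what its biomass can support and, for trees
    invading non-forest, what the forest cap allows.
    """
    arrays = web.plant_pair_arrays
    if arrays is None:
        return
    plants = web.plant_refs
    forest_total = sum(s.area for s in state.species if s.category == "tree")
    forest_room = max(0.0, state.forest_cap - forest_total)
    sa_tree = config.specific_area_tree
    sa_grass = config.specific_area_grass
    # Vectorised pre-filter: skip the (typically vast) majority of pairs
    # whose potential transfer this step is negligible.  Removed species
    # have area zeroed, so stale pairs are inert.
    areas = np.fromiter((p.area for p in plants), dtype=float, count=len(plants))
    potential = (
        arrays["e1"] * areas[arrays["tall"]] * areas[arrays["short"]]
        * arrays["h12"] * arrays["cs2"]
    )
    (active,) = np.nonzero(potential > 1e-12)
    for k in active:
        tall = plants[arrays["tall"][k]]
        short = plants[arrays["short"][k]]
        if short.area <= 0.0 or tall.area <= 0.0:
            continue
        d_area = (
            tall.traits.area_increase_rate
            * tall.area
            * short.area
            * arrays["h12"][k]
            * short.traits.stress_tolerance_index
        )
        d_area = min(d_area, short.area)
        sa1 = sa_tree if tall.category == "tree" else sa_grass
        headroom = tall.biomass * sa1 - tall.area
        moved = d_area if d_area < headroom else headroom
        if tall.category == "tree" and short.category != "tree":
            moved = min(moved, forest_room)
        if moved <= 0.0:
            continue
        frac = moved / short.area
        lost_mass = short.biomass * frac
        short.area = max(0.0, short.area - moved)
        short.biomass = max(0.0, short.biomass - lost_mass)
        tall.area += moved
        if tall.category == "tree" and short.category != "tree":
            forest_room -= moved
        state.pools.add("litter", lost_mass, lost_mass * short.traits.nutrient_content)


def seabird_competition(
    state: IslandState,
    config: Config,
    web: InteractionWeb,
    by_id: dict[int, SpeciesState] | None = None,
) -> None:
    """Bigger seabirds encroach the nesting area of smaller ones; displaced
    biomass dies into the carcass pool."""
    if not web.seabird_pairs:
        return
    by_id = by_id if by_id is not None else {s.id: s for s in state.species}
    for big_id, small_id in web.seabird_pairs:
        big = by_id.get(big_id)
        small = by_id.get(small_id)
        if big is None or small is None or small.area <= 0.0:
            continue
        d_area = config.seabird_encroach_rate * big.area * small.area
        d_area = min(d_area, small.area)
        napb = small.traits.nesting_area_per_biomass
        lost_mass = min(d_area / napb if napb > 0 else 0.0, small.biomass)
        small.area = max(0.0, small.area - d_area)
        small.biomass -= lost_mass
        state.pools.add("carcasses", lost_mass, lost_mass * small.traits.nutrient_content)


def detritus_cycle(state: IslandState, config: Config, fluxes: StepFluxes) -> None:
    """Detritivore feeding, weathering, ageing and decomposition.

    Scavengers eat the carcass pool, litter feeders the litter pool (demand-
    truncated Holling fluxes); their droppings re-enter the droppings pool.
    A fixed fraction of every cohort weathers out of the system each step;
    cohorts reaching the decomposition lag release their nutrient into the
    belowground pool.
    """
    for sp in sorted(state.by_category("scavenger", "litter_feeder"), key=lambda s: s.id):
        t = sp.traits
        compartment = "carcasses" if t.feeding_type == "scavenger" else "litter"
        demand = sp.biomass * t.metabolism_rate * config.demand_factor / t.assimilation_rate
        mass, nut, _ = _eat_detritus(sp, compartment, state, config, demand, fluxes)
        _finish_meal(sp, mass, nut, state, config, fluxes)

    w = config.weathering_fraction
    for queue in state.pools.compartments().values():
        kept: list = []
        for e in queue:
            lost = e.nutrient * w
            e.mass *= 1.0 - w
            e.nutrient -= lost
            state.cumulative_weathered += lost
            fluxes.weathered += lost
            e.age += 1
            if e.age >= config.decomposition_lag:
                state.pools.nutrient += e.nutrient
                fluxes.nutrient_released += e.nutrient
            elif e.mass > _EPS or e.nutrient > _EPS:
                kept.append(e)
        queue[:] = kept


def extinction_sweep(state: IslandState, config: Config) -> list[int]:
    """Remove species below the extinction threshold; their residual biomass
    enters the detritus pools (litter for plants, carcasses for animals)."""
    floors = {
        "tree": config.min_viable_tree,
        "grass": config.min_viable_grass,
        "seabird": config.min_viable_seabird,
        "goat": config.min_viable_goat,
    }
    gone: list[int] = []
    for sp in state.species:
        if sp.biomass < max(config.extinction_threshold, floors.get(sp.category, 0.0)):
            compartment = "litter" if sp.is_plant else "carcasses"
            if sp.biomass > 0:
                state.pools.add(compartment, sp.biomass, sp.biomass * sp.traits.nutrient_content)
            # Zero out so stale references in the cached web stay inert.
            sp.biomass = 0.0
            sp.area = 0.0
            gone.append(sp.id)
    state.remove_species(gone)
    return gone


def step(state: IslandState, config: Config) -> StepFluxes:
    """Advance the island by one day.  Returns the step's nutrient ledger."""
    web = ensure_web(state, config)
    fluxes = StepFluxes()
    seabird_input(state, config, fluxes)
    tree_modifier, grass_modifier, _ = interference(state, config)
    plant_growth(state, config, fluxes, tree_modifier, grass_modifier)

    by_id = {s.id: s for s in state.species}
    guilds = (("herbivore", "goat"), ("carnivore",), ("rat",))
    for guild in guilds:
        for sp in sorted(state.by_category(*guild), key=lambda s: s.id):
            if sp.biomass <= 0.0:
                continue
            feed(sp, web.diets.get(sp.id, []), state, config, fluxes, by_id)
    # Grazed plants cannot hold more area than their biomass supports.
    for sp in state.plants():
        sp.area = min(sp.area, sp.biomass * specific_area(sp, config))

    encroach(state, config, web)
    seabird_competition(state, config, web, by_id)
    detritus_cycle(state, config, fluxes)
    extinction_sweep(state, config)
    state.step += 1
    return fluxes
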
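"""Scenario orchestration: phases, checkpoints, replicates, calibration.

A replicate starts from one herbaceous plant and one seabird, evolves the
community for the evolution phase (with immigration and speciation), lets
it settle, introduces the four aliens at the invasion boundary, begins
daily goat removal after the disturbance phase, and runs the post-
eradication phase.  Snapshots are taken immediately before the invasion
(checkpoint 1), immediately before eradication begins (checkpoint 2), and
at the end of the run (final).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .domain_model import (
    CATEGORIES,
    Config,
    IslandState,
    Pools,
    SpeciesState,
    initial_biomass,
    sample_plant_traits,
    sample_seabird_traits,
    total_system_nutrient,
    validate_state,
    vegetation_ratio,
)
from . import dynamics
from .evolution import maybe_evolve
from .invasion import eradicate_goats_step, invade

logger = logging.getLogger("islandevo")

TRAJECTORY_COLUMNS = (
    ["step", "forest", "grassland", "denuded", "pool_nutrient"]
    + [f"count_{c}" for c in CATEGORIES]
    + [f"biomass_{c}" for c in CATEGORIES]
    + ["goat_biomass", "rat_biomass", "popinac_area", "total_nutrient"]
)


def founder_state(config: Config, seed: int) -> IslandState:
    """The initial island: one grass species, one seabird species, and the
    starting belowground nutrient stock."""
    rng = np.random.default_rng(seed)
    state = IslandState(
        step=0,
        species=[],
        pools=Pools(nutrient=config.initial_pool_nutrient),
        rng=rng,
        island_area=config.island_area_km2,
        forest_cap=config.forest_cap,
    )
    grass = SpeciesState(
        id=state.new_id(),
        category="grass",
        traits=sample_plant_traits("herbaceous", config, rng),
        biomass=initial_biomass("grass", config),
    )
    state.add_species(grass)
    dynamics.claim_seed_area(state, grass, config)
    seabird = SpeciesState(
        id=state.new_id(),
        category="seabird",
        traits=sample_seabird_traits(config, rng),
        biomass=initial_biomass("seabird", config),
    )
    seabird.area = min(1.0, seabird.biomass * seabird.traits.nesting_area_per_biomass)
    state.add_species(seabird)
    return state


def snapshot(state: IslandState) -> dict[str, float]:
    """One trajectory record: vegetation ratio, pool nutrient, per-category
    counts and biomasses, alien biomasses, popinac area, total nutrient."""
    forest, grassland, denuded = vegetation_ratio(state)
    rec: dict[str, float] = {
        "step": state.step,
        "forest": forest,
        "grassland": grassland,
        "denuded": denuded,
        "pool_nutrient": state.pools.nutrient,
    }
    for c in CATEGORIES:
        members = state.by_category(c)
        rec[f"count_{c}"] = len(members)
        rec[f"biomass_{c}"] = sum(s.biomass for s in members)
    rec["goat_biomass"] = state.goat_biomass()
    rec["rat_biomass"] = state.rat_biomass()
    rec["popinac_area"] = sum(
        s.area for s in state.species if s.category == "tree" and s.origin == "alien"
    )
    rec["total_nutrient"] = total_system_nutrient(state)
    return rec


@dataclass
class Trajectory:
    """Per-replicate sampled records, checkpoints, event log and audits."""

    seed: int
    records: list[dict] = field(default_factory=list)
    checkpoints: dict[str, dict] = field(default_factory=dict)
    events: list[tuple[int, str, str]] = field(default_factory=list)
    goats_removed_total: float = 0.0
    goat_eradication_complete_step: Optional[int] = None
    initial_nutrient: float = 0.0
    final_nutrient: float = 0.0
    cumulative_input: float = 0.0
    cumulative_weathered: float = 0.0
    eradication_step: int = 0
    invasion_step: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=TRAJECTORY_COLUMNS)

    def digest(self) -> str:
        csv = self.to_dataframe().to_csv(index=False, float_format="%.17g")
        return hashlib.sha256(csv.encode()).hexdigest()

    @property
    def conservation_residual(self) -> float:
        """Relative error of the closed-system nutrient ledger."""
        expected = self.initial_nutrient + self.cumulative_input - self.cumulative_weathered
        scale = max(abs(expected), 1.0)
        return abs(self.final_nutrient - expected) / scale


def run_replicate(config: Config, seed: int) -> Trajectory:
    """Run one full scenario.  Identical seeds give identical trajectories."""
    state = founder_state(config, seed)
    problems = validate_state(state, config)
    if problems:
        raise RuntimeError(f"invalid initial state: {problems}")
    traj = Trajectory(
        seed=seed,
        initial_nutrient=total_system_nutrient(state),
        eradication_step=config.eradication_step,
        invasion_step=config.invasion_step,
    )
    event_counter = [0]
    erad = config.eradication_step
    invasion = config.invasion_step
    goats_done_logged = False

    for t in range(config.total_steps):
        if t == invasion:
            traj.checkpoints["pre_invasion"] = snapshot(state)
            invade(state, config)
            traj.events.append((t, "invasion", "goat, rat, white popinac, lawn grass"))
            logger.info("seed=%d step=%d event=invasion", seed, t)
        if t == erad:
            traj.checkpoints["pre_eradication"] = snapshot(state)
        if t >= erad:
            removed = eradicate_goats_step(state, config)
            traj.goats_removed_total += removed
            if not goats_done_logged and state.goat_biomass() <= 0.0:
                traj.goat_eradication_complete_step = t
                traj.events.append((t, "eradication_complete", ""))
                logger.info("seed=%d step=%d event=eradication_complete", seed, t)
                goats_done_logged = True

        n_before = len(state.species)
        maybe_evolve(state, config, event_counter)
        if len(state.species) != n_before:
            traj.events.append((t, "evolution_event", f"{len(state.species) - n_before:+d}"))

        cadence = (
            config.sample_interval_coarse if t < invasion else config.sample_interval_fine
        )
        if t % cadence == 0 or t == invasion or t == erad:
            traj.records.append(snapshot(state))

        dynamics.step(state, config)

    traj.checkpoints["final"] = snapshot(state)
    traj.records.append(snapshot(state))
    traj.final_nutrient = total_system_nutrient(state)
    traj.cumulative_input = state.cumulative_input
    traj.cumulative_weathered = state.cumulative_weathered
    problems = validate_state(state, config)
    if problems:
        raise RuntimeError(f"seed {seed}: invariants violated at end of run: {problems}")
    return traj


def run_ensemble(
    config: Config, n_replicates: int, base_seed: int
) -> list[Trajectory]:
    """Independent replicates with seeds base_seed + i.  A failed replicate
    is logged and skipped; the ensemble continues."""
    out: list[Trajectory] = []
    for i in range(n_replicates):
        seed = base_seed + i
        try:
            out.append(run_replicate(config, seed))
        except Exception:  # noqa: BLE001 - per-replicate isolation
            logger.exception("replicate seed=%d failed", seed)
    return out


def calibration_score(config: Config, trajectories: list[Trajectory]) -> float:
    """Distance of the pre-eradication state from the observed targets: the
    1991 vegetation ratio plus the relative goat-biomass error."""
    if not trajectories:
        return float("inf")
    score = 0.0
    for traj in trajectories:
        cp = traj.checkpoints.get("pre_eradication")
        if cp is None:
            return float("inf")
        score += (
            abs(cp["forest"] - config.target_forest)
            + abs(cp["grassland"] - config.target_grassland)
            + abs(cp["denuded"] - config.target_denuded)
            + abs(cp["goat_biomass"] - config.target_goat_biomass)
            / max(config.target_goat_biomass, 1e-9)
        )
    return score / len(trajectories)


def calibrate(
    config_template: Config,
    param_ranges: dict[str, tuple[float, float]],
    n_sets: int,
    n_reps: int,
    base_seed: int,
    scale: int = 100,
) -> list[dict]:
    """Random-search calibration: draw ``n_sets`` parameter sets uniformly
    from the given ranges, run ``n_reps`` scaled replicates each, and rank
    by the vegetation-ratio/goat-biomass score (best first)."""
    rng = np.random.default_rng(base_seed)
    ranked: list[dict] = []
    for i in range(n_sets):
        params = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in param_ranges.items()}
        cfg = replace(config_template, **params).scaled(scale)
        trajectories = run_ensemble(cfg, n_reps, base_seed + 1000 * (i + 1))
        ranked.append({"params": params, "score": calibration_score(cfg, trajectories)})
    ranked.sort(key=lambda d: d["score"])
    return ranked
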
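"""Classification of replicate outcomes and ensemble summaries.

A replicate is *restored* when the forest reaches the 95% cap at any point
after eradication begins.  Non-restored replicates fall into four mutually
exclusive patterns, checked in order: (1) all arboreous plants extinct;
(2) white popinac dominates the remaining forest (>= 90% of forest area);
(3) at most three arboreous species survive without popinac dominance;
(4) more than three arboreous species survive but forest biomass stays low.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .runner import Trajectory

FULL_FOREST_TOL = 1e-9
PATTERN_LABELS = (
    "pattern1_trees_extinct",
    "pattern2_popinac_dominant",
    "pattern3_few_species_no_popinac",
    "pattern4_suppressed_by_herbivores",
)


def is_fully_forested(forest_fraction: float, forest_cap: float = 0.95) -> bool:
    return forest_fraction >= forest_cap - FULL_FOREST_TOL


def forest_at_equilibrium(
    trajectory: Trajectory, window_steps: Optional[int] = None, tolerance: float = 0.01
) -> bool:
    """Relative change of forest area below ``tolerance`` over the last
    tenth of the post-eradication phase (or ``window_steps``)."""
    recs = trajectory.records
    if len(recs) < 2:
        return True
    last = recs[-1]["step"]
    if window_steps is None:
        window_steps = max(1, (last - trajectory.eradication_step) // 10)
    window = [r["forest"] for r in recs if r["step"] >= last - window_steps]
    if not window:
        return True
    lo, hi = min(window), max(window)
    return (hi - lo) <= tolerance * max(hi, 1e-12)


def restoration_time(trajectory: Trajectory, forest_cap: float = 0.95) -> Optional[int]:
    """Steps from the start of eradication to the first fully forested
    sample, for replicates whose final state is fully forested; None
    otherwise.  A transient touch of the cap followed by collapse does not
    count as restoration."""
    if not is_fully_forested(trajectory.checkpoints["final"]["forest"], forest_cap):
        return None
    for rec in trajectory.records:
        if rec["step"] >= trajectory.eradication_step and is_fully_forested(
            rec["forest"], forest_cap
        ):
            return int(rec["step"] - trajectory.eradication_step)
    return None


def classify_restoration(trajectory: Trajectory, forest_cap: float = 0.95) -> str:
    if restoration_time(trajectory, forest_cap) is not None:
        return "restored"
    final = trajectory.checkpoints["final"]
    n_trees = final["count_tree"]
    if n_trees == 0:
        return "pattern1_trees_extinct"
    forest = final["forest"]
    popinac_share = final["popinac_area"] / forest if forest > 0 else 0.0
    if popinac_share >= 0.90:
        return "pattern2_popinac_dominant"
    if n_trees <= 3:
        return "pattern3_few_species_no_popinac"
    if n_trees > 3:
        return "pattern4_suppressed_by_herbivores"
    return "other"


@dataclass
class OutcomeRecord:
    seed: int
    fully_forested_at_invasion: bool
    reduced_but_forested: bool
    restoration_label: str
    restoration_time: Optional[int]
    rat_fold_change: float
    forest_equilibrium: bool
    pre_eradication: dict = field(default_factory=dict)
    final: dict = field(default_factory=dict)


def classify(trajectory: Trajectory, forest_cap: float = 0.95) -> OutcomeRecord:
    cp1 = trajectory.checkpoints["pre_invasion"]
    cp2 = trajectory.checkpoints["pre_eradication"]
    final = trajectory.checkpoints["final"]
    label = classify_restoration(trajectory, forest_cap)
    t_restore = restoration_time(trajectory, forest_cap)
    pre_rat = cp2["rat_biomass"]
    fold = final["rat_biomass"] / pre_rat if pre_rat > 0 else float("nan")
    reduced = (
        0.0 < cp2["forest"] < forest_cap - FULL_FOREST_TOL
        and (cp2["grassland"] + cp2["denuded"]) > (cp1["grassland"] + cp1["denuded"])
    )
    return OutcomeRecord(
        seed=trajectory.seed,
        fully_forested_at_invasion=is_fully_forested(cp1["forest"], forest_cap),
        reduced_but_forested=reduced,
        restoration_label=label,
        restoration_time=t_restore,
        rat_fold_change=fold,
        forest_equilibrium=forest_at_equilibrium(trajectory),
        pre_eradication=dict(cp2),
        final=dict(final),
    )


def _mean(values: list[float]) -> float:
    return float(np.mean(values)) if values else float("nan")


def summarize_ensemble(records: list[OutcomeRecord]) -> dict:
    """Ensemble summary: forestation rates, pattern counts, restoration-time
    statistics, rat fold-change, and unrestored/restored contrast ratios of
    the pre-eradication state (pool nutrient, diversity, biomass)."""
    if not records:
        raise ValueError("summarize_ensemble needs at least one record")
    n = len(records)
    restored = [r for r in records if r.restoration_label == "restored"]
    unrestored = [r for r in records if r.restoration_label != "restored"]
    reduced = [r for r in records if r.reduced_but_forested]
    reduced_restored = [r for r in reduced if r.restoration_label == "restored"]
    times = [r.restoration_time for r in restored if r.restoration_time is not None]
    folds = [r.rat_fold_change for r in records if np.isfinite(r.rat_fold_change)]

    pattern_counts = {label: 0 for label in PATTERN_LABELS + ("other",)}
    for r in unrestored:
        pattern_counts[r.restoration_label] += 1

    summary = {
        "n_replicates": n,
        "fraction_fully_forested_at_invasion": sum(
            r.fully_forested_at_invasion for r in records
        ) / n,
        "n_reduced_but_forested": len(reduced),
        "fraction_restored": len(restored) / n,
        "fraction_restored_among_reduced": (
            len(reduced_restored) / len(reduced) if reduced else float("nan")
        ),
        "fraction_final_forest_below_half": sum(
            r.final["forest"] < 0.5 for r in records
        ) / n,
        "pattern_counts": pattern_counts,
        "restoration_time_mean": _mean(times),
        "restoration_time_sd": float(np.std(times, ddof=1)) if len(times) > 1 else float("nan"),
        "rat_fold_change_mean": _mean(folds),
    }

    # Fig.4-style contrasts: unrestored / restored, pre-eradication state.
    contrast_keys = [
        "pool_nutrient",
        "count_tree",
        "count_grass",
        "count_herbivore",
        "count_carnivore",
        "biomass_tree",
        "biomass_grass",
        "biomass_herbivore",
        "biomass_carnivore",
        "biomass_seabird",
    ]
    contrasts = {}
    for key in contrast_keys:
        num = _mean([r.pre_eradication[key] for r in unrestored])
        den = _mean([r.pre_eradication[key] for r in restored])
        contrasts[key] = num / den if den and np.isfinite(den) and den != 0 else float("nan")
    summary["unrestored_over_restored_pre_eradication"] = contrasts
    return summary
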
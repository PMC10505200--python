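# islandevo

An eco-evolutionary simulator of a small oceanic island's nutrient cycle,
built to ask a restoration-ecology question: **after invasive goats are
eradicated, why might the island's forest fail to come back?**

The model grows a whole island community from two founder species (one
herbaceous plant, one seabird) by rare immigration and frequent speciation,
lets it settle, disturbs it with four alien species — feral goats, rats,
white popinac (*Leucaena leucocephala*) and a lawn grass — then removes a
fixed mass of goats per day and watches whether the forest recovers.
Because every replicate carries its own evolutionary history, the fate of
the island after eradication can depend on events from the distant past
(the founder effect): which trees happened to colonise first, and how much
nutrient their strategies left in the soil.

## The model in brief

* **Closed nutrient cycle.** A single nutrient currency (nitrogen mass
  fractions) flows between a belowground pool, three age-structured
  detritus compartments (droppings, carcasses, litter) and living biomass.
  Seabirds feeding at sea are the only substantial import; weathering of
  detritus is the only export. The ledger
  `total = initial + inputs − weathered` closes to rounding error and is
  audited every step.
* **Trait-based plants.** Every plant species allocates 100 points across
  Grime's C-S-R strategies; competitive score buys height, ruderal score
  buys colonisation speed, stress-tolerant score buys resistance to
  encroachment and to oligotrophic die-back. Plants compete for space:
  the taller encroaches the shorter at rate
  `dA₂ = E₁·A₁·A₂·H₁₂·C_s2`.
* **Niche-model food web.** Consumers draw a feeding interval on a
  one-dimensional diet axis (the classic niche model); feeding follows a
  Holling type III functional response `k·M₁·M₂²/(h+M₂²)`, visited in
  preference order and truncated at the consumer's demand.
* **Evolution.** A new species immigrates every 1000 steps; every 100
  steps one species (rotating over grasses, trees, herbivores,
  carnivores) splits off a daughter with 5% of its biomass and
  Gaussian-mutated traits (SD ≈ 10% of each trait value).
* **Scenario.** 100k steps of evolution, 100k of settling, alien invasion,
  10k steps of disturbance, then daily removal of 400 kg of goats (the
  carcasses stay on the island) and 100k steps of recovery. Replicates
  are classified as *restored* (forest back at the 95% cover cap) or into
  four non-restoration patterns (trees extinct; popinac-dominated partial
  forest; few-species equilibrium; herbivore-suppressed forest).

A `--scale N` divisor shrinks every phase for desk-scale work; `--scale
100` (3,100-step scenario, ~7 s per replicate) is the supported study
configuration and the one the tests exercise.

## Worked example

```python
from islandevo import Config, run_replicate, classify

cfg = Config().scaled(100)          # desk-scale study configuration
traj = run_replicate(cfg, seed=3)
rec = classify(traj, cfg.forest_cap)

cp = traj.checkpoints
print("forest at invasion:        %.2f" % cp["pre_invasion"]["forest"])
print("forest before eradication: %.2f" % cp["pre_eradication"]["forest"])
print("final forest:              %.2f" % cp["final"]["forest"])
print("outcome:", rec.restoration_label, "| restoration time:", rec.restoration_time)
print("rat biomass fold-change:   %.1f" % rec.rat_fold_change)
```

prints

```
forest at invasion:        0.95
forest before eradication: 0.09
final forest:              0.31
outcome: pattern4_suppressed_by_herbivores | restoration time: None
rat biomass fold-change:   38.8
```

This replicate closed its canopy before the invasion, lost almost all of
it to the goats, and never recovered full cover after they were removed:
many tree species survive but herbivores (rats included, up almost
forty-fold once the goats were gone) keep the regrowing forest at a third
of the island — the model's analogue of an island that stays unrestored
decades after a successful eradication. Other seeds restore; run a few.

The same scenario is available from a shell:

```bash
islandevo run --seed 3 --scale 100 --out traj.csv
islandevo classify --seed 0 --scale 100 --replicates 30 --out summary.json
islandevo calibrate --scale 100 --sets 20 --replicates 3 --seed 0 --out calib.json
```

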
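import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from islandevo import Config, IslandState, Pools, SpeciesState, holling_flux, step, total_system_nutrient
from islandevo import dynamics
from islandevo.domain_model import AnimalTraits, DetritusEntry, plant_traits_from_csr
from islandevo.dynamics import (
    StepFluxes,
    detritus_cycle,
    encroach,
    feed,
    interference,
    plant_growth,
)
from islandevo.niche_web import build_web


def _state(pool=0.0, seed=0):
    return IslandState(step=0, species=[], pools=Pools(nutrient=pool), rng=np.random.default_rng(seed))


def _add_plant(state, config, form="herbaceous", csr=(30.0, 30.0, 40.0),
               biomass=1.0, area=None, growth=None, nf=None):
    traits = plant_traits_from_csr(form, csr, config)
    if growth is not None:
        traits.basic_growth_rate = growth
    if nf is not None:
        traits.nutrient_content = nf
    sp = SpeciesState(
        id=state.new_id(),
        category="grass" if form == "herbaceous" else "tree",
        traits=traits,
        biomass=biomass,
    )
    sa = dynamics.specific_area(sp, config)
    sp.area = biomass * sa if area is None else area
    state.add_species(sp)
    return sp


def _add_animal(state, category="herbivore", biomass=1.0, m=0.01, a=0.5, nf=0.025,
                feeding_type=None, c=0.5, r=1.0):
    traits = AnimalTraits(
        feeding_type=feeding_type or category,
        niche_value=0.5,
        feeding_center=c,
        feeding_range=r,
        metabolism_rate=m,
        assimilation_rate=a,
        nutrient_content=nf,
    )
    sp = SpeciesState(id=state.new_id(), category=category, traits=traits, biomass=biomass)
    state.add_species(sp)
    return sp


class TestHollingFlux:
    def test_zero_prey_gives_zero(self):
        assert holling_flux(5.0, 0.0, 1.0, 1.0) == 0.0

    def test_half_saturation_point(self):
        assert holling_flux(1.0, 1.0, 1.0, 1.0) == pytest.approx(0.5)

    def test_worked_value(self):
        assert holling_flux(10.0, 50.0, 0.01, 100.0) == pytest.approx(250.0 / 2600.0)

    def test_matches_closed_form_on_random_inputs(self):
        rng = np.random.default_rng(42)
        m1 = rng.uniform(0, 1e4, 1000)
        m2 = rng.uniform(0, 1e4, 1000)
        k = rng.uniform(0.001, 1, 1000)
        h = rng.uniform(1, 1e4, 1000)
        expected = k * m1 * m2**2 / (h + m2**2)
        got = np.array([holling_flux(*args) for args in zip(m1, m2, k, h)])
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_rejects_negative_biomass(self):
        with pytest.raises(ValueError):
            holling_flux(-1.0, 1.0, 1.0, 1.0)

    @given(
        m1=st.floats(0, 1e6), m2=st.floats(0, 1e6),
        dm=st.floats(0, 1e3), k=st.floats(1e-6, 10), h=st.floats(1e-6, 1e6),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_saturating(self, m1, m2, dm, k, h):
        base = holling_flux(m1, m2, k, h)
        slack = 1e-12 * max(1.0, abs(base))  # float rounding near saturation
        assert holling_flux(m1 + dm, m2, k, h) >= base - slack
        assert holling_flux(m1, m2 + dm, k, h) >= base - slack
        assert base <= k * m1 + 1e-9


class TestPlantGrowth:
    def test_proportional_sharing_when_pool_short(self, config):
        state = _state(pool=1.5)
        cfg = dataclasses.replace(config, plant_litter_rate=0.0, plant_decline_rate=0.0)
        # demands: 100 t * 0.4 * 0.05 = 2 t and 100 t * 0.2 * 0.05 = 1 t
        p1 = _add_plant(state, cfg, biomass=100.0, growth=0.4, nf=0.05, area=0.4)
        p2 = _add_plant(state, cfg, csr=(60.0, 20.0, 20.0), biomass=100.0, growth=0.2, nf=0.05, area=0.4)
        plant_growth(state, cfg, StepFluxes())
        # uptakes 1.0 and 0.5 -> growth 20 t and 10 t
        assert p1.biomass == pytest.approx(100.0 + 1.0 / 0.05, rel=1e-3)
        assert p2.biomass == pytest.approx(100.0 + 0.5 / 0.05, rel=1e-3)
        assert state.pools.nutrient == pytest.approx(0.0, abs=1e-12)

    def test_ample_pool_full_growth(self, config):
        state = _state(pool=100.0)
        cfg = dataclasses.replace(config, plant_litter_rate=0.0, plant_decline_rate=0.0)
        p = _add_plant(state, cfg, biomass=10.0, growth=0.05, nf=0.02, area=0.1)
        plant_growth(state, cfg, StepFluxes())
        assert p.biomass == pytest.approx(10.5, rel=1e-3)
        assert state.pools.nutrient == pytest.approx(100.0 - 0.5 * 0.02, rel=1e-3)

    def test_empty_pool_causes_decline(self, config):
        state = _state(pool=0.0)
        p = _add_plant(state, config, biomass=10.0, area=0.01)
        plant_growth(state, config, StepFluxes())
        assert p.biomass < 10.0

    def test_nitrogen_fixer_grows_without_pool(self, config):
        state = _state(pool=0.0)
        cfg = dataclasses.replace(config, plant_litter_rate=0.0, plant_decline_rate=0.0)
        p = _add_plant(state, cfg, form="arboreous", biomass=10.0, growth=0.05, area=1e-3)
        p.traits.nitrogen_fixer = True
        before_in = state.cumulative_input
        plant_growth(state, cfg, StepFluxes())
        assert p.biomass > 10.0
        assert state.cumulative_input > before_in  # fixation is an import


class TestFeed:
    def test_demand_truncation_partially_grazes_second_prey(self, config):
        # demand 1.0; first prey offers 0.6, second could offer 0.9
        state = _state()
        cfg = dataclasses.replace(config, demand_factor=1.0, animal_carcass_rate=0.0,
                                  holling_k=1e6, holling_h=1e-6)
        pred = _add_animal(state, biomass=10.0, m=0.05, a=0.5)  # demand 10*0.05/0.5 = 1.0
        prey1 = _add_plant(state, cfg, biomass=0.6, nf=0.02)
        prey2 = _add_plant(state, cfg, csr=(60.0, 20.0, 20.0), biomass=0.9, nf=0.02)
        feed(pred, [prey1.id, prey2.id], state, cfg, StepFluxes())
        assert prey1.biomass == pytest.approx(0.0)
        assert prey2.biomass == pytest.approx(0.5)  # only 0.4 of it eaten

    def test_starving_predator_shrinks_by_metabolism(self, config):
        state = _state()
        cfg = dataclasses.replace(config, animal_carcass_rate=0.0)
        pred = _add_animal(state, biomass=10.0, m=0.01)
        feed(pred, [], state, cfg, StepFluxes())
        assert pred.biomass == pytest.approx(10.0 * 0.99)

    def test_assimilation_partition(self, config):
        state = _state()
        cfg = dataclasses.replace(config, demand_factor=1.0, animal_carcass_rate=0.0,
                                  holling_k=1e6, holling_h=1e-6)
        # equal nutrient contents so mass and nutrient bookkeeping coincide
        pred = _add_animal(state, biomass=20.0, m=0.035, a=0.7, nf=0.02)  # demand 1.0
        prey = _add_plant(state, cfg, biomass=5.0, nf=0.02)
        fluxes = StepFluxes()
        record = feed(pred, [prey.id], state, cfg, fluxes)
        assert record["intake_mass"] == pytest.approx(1.0)
        # growth 0.7 t, metabolism 0.7 t: net 0; egestion 0.3 t to droppings
        assert pred.biomass == pytest.approx(20.0)
        assert state.pools.detritus_mass("droppings") == pytest.approx(0.3 + 0.7)

    def test_goat_destroys_extra_woody_biomass(self, config):
        state = _state()
        cfg = dataclasses.replace(config, demand_factor=1.0, animal_carcass_rate=0.0,
                                  holling_k=1e6, holling_h=1e-6, goat_destruction_factor=3.0)
        goat = _add_animal(state, category="goat", biomass=8.0, m=0.05, a=0.5,
                           nf=cfg.goat_nutrient_content)  # demand 0.8
        tree = _add_plant(state, cfg, form="arboreous", biomass=100.0)
        feed(goat, [tree.id], state, cfg, StepFluxes())
        # 0.8 ingested + 2.4 destroyed
        assert tree.biomass == pytest.approx(100.0 - 0.8 - 2.4)
        assert state.pools.detritus_mass("litter") == pytest.approx(2.4)


class TestEncroach:
    def _pair_state(self, config, e1=0.001, a1=0.3, a2=0.2, h_ratio=None, cs2=0.8):
        state = _state()
        tall = _add_plant(state, config, form="arboreous", csr=(40.0, 30.0, 30.0),
                          biomass=1e5, area=a1)
        tall.traits.area_increase_rate = e1
        tall.traits.height = 9.0
        short = _add_plant(state, config, csr=(42.0, 30.0, 28.0), biomass=1000.0, area=a2)
        short.traits.height = 0.3
        short.traits.stress_tolerance_index = cs2
        return state, tall, short

    def test_closed_form_transfer(self, config):
        state, tall, short = self._pair_state(config)
        # override H12 via explicit heights: use the pair builder's H12
        web = build_web(state, config)
        (t_id, s_id, h12) = web.plant_pairs[0]
        expected = 0.001 * 0.3 * 0.2 * h12 * 0.8
        encroach(state, config, web)
        assert short.area == pytest.approx(0.2 - expected)
        assert tall.area == pytest.approx(0.3 + expected)

    def test_zero_area_loser_unchanged(self, config):
        state, tall, short = self._pair_state(config, a2=0.0)
        short.biomass = 0.0
        web = build_web(state, config)
        encroach(state, config, web)
        assert short.area == 0.0

    def test_stress_tolerant_short_plant_resists(self, config):
        state, tall, short = self._pair_state(config, cs2=0.0)
        web = build_web(state, config)
        encroach(state, config, web)
        assert short.area == pytest.approx(0.2)

    def test_loser_biomass_scales_with_lost_area(self, config):
        state, tall, short = self._pair_state(config, e1=0.1)
        web = build_web(state, config)
        a_before, m_before = short.area, short.biomass
        encroach(state, config, web)
        lost_frac = (a_before - short.area) / a_before
        assert short.biomass == pytest.approx(m_before * (1 - lost_frac))


class TestInterference:
    def test_neutral_without_goats_or_seabirds(self, config):
        state = _state()
        assert interference(state, config) == (1.0, 1.0, 1.0)

    def test_goat_pressure_linear_in_biomass(self, config):
        state = _state()
        goat = _add_animal(state, category="goat", biomass=2.0)
        t1, g1, n1 = interference(state, config)
        goat.biomass = 4.0
        t2, g2, n2 = interference(state, config)
        assert 1 - t2 == pytest.approx(2 * (1 - t1))
        assert 1 - n2 == pytest.approx(2 * (1 - n1))

    def test_goat_halves_nesting_capacity(self, config):
        state = _state()
        _add_animal(state, category="goat", biomass=0.5 / config.goat_nest_interference)
        _, _, nest = interference(state, config)
        assert nest == pytest.approx(0.5)


class TestDetritusCycle:
    def test_weathering_and_ageing(self, config):
        state = _state()
        cfg = dataclasses.replace(config, weathering_fraction=0.1)
        state.pools.litter.append(DetritusEntry(mass=1.0, nutrient=0.02, age=0))
        detritus_cycle(state, cfg, StepFluxes())
        entry = state.pools.litter[0]
        assert entry.mass == pytest.approx(0.9)
        assert entry.age == 1
        assert state.cumulative_weathered == pytest.approx(0.002)

    def test_decomposition_releases_nutrient_to_pool(self, config):
        state = _state()
        cfg = dataclasses.replace(config, weathering_fraction=0.0)
        state.pools.litter.append(DetritusEntry(mass=2.0, nutrient=0.1, age=cfg.decomposition_lag - 1))
        detritus_cycle(state, cfg, StepFluxes())
        assert state.pools.litter == []
        assert state.pools.nutrient == pytest.approx(0.1)

    def test_empty_pools_noop(self, config):
        state = _state(pool=3.0)
        detritus_cycle(state, config, StepFluxes())
        assert state.pools.nutrient == 3.0

    def test_scavenger_eats_carcasses(self, config):
        state = _state()
        _add_animal(state, category="scavenger", feeding_type="scavenger", biomass=5.0, a=0.3)
        state.pools.carcasses.append(DetritusEntry(mass=10.0, nutrient=0.25, age=0))
        before = state.pools.detritus_mass("carcasses")
        detritus_cycle(state, config, StepFluxes())
        assert state.pools.detritus_mass("carcasses") < before


class TestStepConservation:
    def test_per_step_ledger_closes(self, midweb, config):
        state = midweb
        for _ in range(50):
            before = total_system_nutrient(state)
            fluxes = step(state, config)
            after = total_system_nutrient(state)
            assert after - before == pytest.approx(
                fluxes.nutrient_in - fluxes.weathered, abs=1e-9
            )

    def test_no_negative_quantities_after_steps(self, config):
        for seed in range(3):
            state = _random_community(config, seed)
            for _ in range(200):
                step(state, config)
            for sp in state.species:
                assert sp.biomass >= 0
                assert sp.area >= 0
            assert state.pools.nutrient >= 0
            for q in state.pools.compartments().values():
                for e in q:
                    assert e.mass >= 0 and e.nutrient >= 0

    def test_step_increments_counter(self, midweb, config):
        t0 = midweb.step
        step(midweb, config)
        assert midweb.step == t0 + 1


def _random_community(config, seed):
    from islandevo.domain_model import sample_plant_traits, sample_seabird_traits

    rng = np.random.default_rng(seed)
    state = _state(pool=float(rng.uniform(0, 50)), seed=seed)
    for _ in range(rng.integers(1, 5)):
        form = "herbaceous" if rng.random() < 0.6 else "arboreous"
        _add_plant(state, config, form=form,
                   csr=tuple(rng.dirichlet((1, 1, 1)) * 100), biomass=float(rng.uniform(0.1, 500)))
    for _ in range(rng.integers(0, 4)):
        _add_animal(state, biomass=float(rng.uniform(0.01, 20)),
                    c=float(rng.uniform(0.2, 0.8)), r=float(rng.uniform(0, 0.5)))
    sp = SpeciesState(
        id=state.new_id(), category="seabird",
        traits=sample_seabird_traits(config, rng), biomass=float(rng.uniform(0.1, 50)),
    )
    sp.area = min(1.0, sp.biomass * sp.traits.nesting_area_per_biomass)
    state.add_species(sp)
    # Normalise plant areas into the unit interval
    total = sum(s.area for s in state.species if s.is_plant)
    if total > 1:
        for s in state.species:
            if s.is_plant:
                s.area /= total * 1.01
    return state


class TestTwoSpeciesOracle:
    """One plant + one herbivore against an independent re-implementation of
    the update equations, and the classic boom-crash shape."""

    def _config(self, config):
        # No litter, mortality, weathering or decomposition within the test
        # horizon: the oracle tracks only the pool and the two biomasses.
        return dataclasses.replace(
            config,
            plant_litter_rate=0.0,
            plant_decline_rate=0.0,
            animal_carcass_rate=0.0,
            weathering_fraction=0.0,
            nitrogen_fixation_fraction=0.0,
            demand_factor=2.5,
            decomposition_lag=100_000,
        )

    def _build(self, config):
        state = _state(pool=50.0)
        plant = _add_plant(state, config, biomass=100.0, growth=0.05, nf=0.02, area=0.14)
        herb = _add_animal(state, biomass=5.0, m=0.01, a=0.5, nf=0.02, c=0.3, r=1.0)
        return state, plant, herb

    def test_matches_brute_force_oracle(self, config):
        cfg = self._config(config)
        state, plant, herb = self._build(cfg)

        # Independent oracle: the same model written as two explicit
        # difference equations (no shared code with dynamics.step).
        m_p, m_h, pool = 100.0, 5.0, 50.0
        area = 0.14
        sa = cfg.specific_area_grass
        traj = []
        for _ in range(300):
            # plant growth (space- and nutrient-limited)
            free = max(0.0, 1.0 - area)
            k_cap = (area * (1 + cfg.plant_overdensity) + free) / sa
            want = m_p * 0.05 * max(0.0, 1.0 - m_p / k_cap)
            need = want * 0.02
            uptake = min(need, pool)
            pool -= uptake
            m_p += uptake / 0.02
            # area tracks biomass
            target = m_p * sa
            if target <= area:
                area = target
            else:
                area = min(target, area * (1 + plant.traits.area_increase_rate), area + free)
            # herbivore feeding, demand-truncated Holling III
            demand = m_h * 0.01 * 2.5 / 0.5
            pot = cfg.holling_k * m_h * m_p**2 / (cfg.holling_h + m_p**2)
            take = min(pot, m_p, demand)
            m_p -= take
            area = min(area, m_p * sa)
            m_h = m_h + 0.5 * take - m_h * 0.01
            traj.append((m_p, m_h))

        for i in range(300):
            step(state, cfg)
        assert plant.biomass == pytest.approx(traj[-1][0], rel=1e-9)
        assert herb.biomass == pytest.approx(traj[-1][1], rel=1e-9)

    def test_boom_crash_shape(self, config):
        cfg = self._config(config)
        state, plant, herb = self._build(cfg)
        series = []
        for _ in range(2000):
            step(state, cfg)
            series.append(herb.biomass)
        peak = max(series)
        assert peak > 2 * series[0]  # boom
        assert series[-1] < 0.5 * peak  # crash
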
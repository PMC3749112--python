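"""Management schedules and event application."""

import datetime as dt

import pytest

from canesim import engine, management as mgmt, plants


class TestPastureSchedule:
    def test_fifteen_years_gives_180_monthly_graze_events(self):
        sched = mgmt.build_pasture_schedule(1998, 15, stocking=1.0)
        assert len(sched.events) == 180
        assert all(e.kind == "graze" for e in sched.events)
        assert sched.stocking == 1.0

    def test_monthly_fractions_compound_to_annual_targets(self):
        # twelve monthly removals f satisfy 1-(1-f)^12 = 0.10 -> f ~ 0.00874
        f_live = mgmt.annual_to_monthly_fraction(0.10)
        assert f_live == pytest.approx(0.008742, abs=1e-6)
        assert 1.0 - (1.0 - f_live) ** 12 == pytest.approx(0.10, rel=1e-12)
        sched = mgmt.build_pasture_schedule(1998, 1)
        assert sched.events[0].live_frac == pytest.approx(f_live)
        assert 1.0 - (1.0 - sched.events[0].dead_frac) ** 12 == \
            pytest.approx(0.01, rel=1e-9)

    def test_zero_stocking_sensitivity_mode(self):
        sched = mgmt.build_pasture_schedule(1998, 2, stocking=0.0)
        assert sched.stocking == 0.0
        assert len(sched.events) == 24  # removals still happen


class TestEnergyCaneSchedule:
    def test_five_cycles_on_spodosol(self):
        sched = mgmt.build_energy_cane_schedule(2013, 5, "spodosol")
        kinds = [e.kind for e in sched.events]
        assert kinds.count("harvest") == 15
        assert kinds.count("plow") == 5
        assert kinds.count("plant") == 5
        ferts = [e for e in sched.events if e.kind == "fertilize"]
        assert len(ferts) == 30
        assert all(e.magnitude == pytest.approx(10.2) for e in ferts)
        assert sum(e.magnitude for e in ferts) == pytest.approx(306.0)

    def test_histosol_never_fertilized(self):
        sched = mgmt.build_energy_cane_schedule(2013, 5, "histosol")
        assert not any(e.kind == "fertilize" for e in sched.events)

    def test_harvest_fraction_always_80_percent(self):
        sched = mgmt.build_energy_cane_schedule(2013, 3, "histosol")
        harvests = [e for e in sched.events if e.kind == "harvest"]
        assert all(e.magnitude == 0.80 for e in harvests)

    def test_irrigation_calendar_monthly_dry_bimonthly_rainy(self):
        sched = mgmt.build_energy_cane_schedule(2013, 1, "histosol")
        months = sorted({e.date.month for e in sched.events
                         if e.kind == "irrigate"})
        assert months == [1, 2, 3, 4, 5, 7, 9, 11, 12]

    def test_unknown_soil_rejected(self):
        with pytest.raises(ValueError):
            mgmt.build_energy_cane_schedule(2013, 5, "vertisol")

    def test_events_sorted_by_date(self):
        sched = mgmt.build_energy_cane_schedule(2013, 2, "spodosol")
        dates = [e.date for e in sched.events]
        assert dates == sorted(dates)


class TestScheduleSerialization:
    def test_yaml_round_trip(self, tmp_path):
        sched = mgmt.build_energy_cane_schedule(2013, 2, "spodosol")
        path = tmp_path / "schedule.yaml"
        sched.to_yaml(path)
        back = mgmt.Schedule.from_yaml(path)
        assert back.events == sched.events
        assert (back.scenario, back.soil_type, back.stocking) == \
            (sched.scenario, sched.soil_type, sched.stocking)


@pytest.fixture()
def cane_state():
    state = engine.initial_state("spodosol",
                                 plants.load_plant_params("energy_cane"))
    p = state.plant
    p.leaf_c, p.stem_c, p.dead_c, p.root_c = 400.0, 500.0, 100.0, 300.0
    p.leaf_n, p.stem_n, p.dead_n, p.root_n = 8.0, 4.0, 1.0, 3.0
    return state


def total_cn(state):
    return (state.plant.total_c + state.som.total_c,
            state.plant.total_n + state.som.total_n + state.mineral.total)


class TestApplyEvent:
    def test_harvest_splits_export_and_residue(self, cane_state):
        c0, n0 = total_cn(cane_state)
        ev = mgmt.ManagementEvent(dt.date(2013, 12, 15), "harvest",
                                  magnitude=0.80)
        out = mgmt.apply_event(cane_state, ev)
        assert out["harvest_c"] == pytest.approx(0.8 * 1000.0)
        # the unharvested 20% goes to surface litter, nothing vanishes
        c1, n1 = total_cn(cane_state)
        assert c1 + out["harvest_c"] == pytest.approx(c0, rel=1e-12)
        assert n1 + out["harvest_n"] == pytest.approx(n0, rel=1e-12)
        assert cane_state.plant.aboveground_c == 0.0
        assert cane_state.plant.root_c == 300.0  # ratoon keeps its roots

    def test_fertilize_splits_ammonium_nitrate_evenly(self, cane_state):
        ev = mgmt.ManagementEvent(dt.date(2013, 2, 15), "fertilize",
                                  magnitude=10.2)
        mgmt.apply_event(cane_state, ev)
        assert cane_state.mineral.nh4 == pytest.approx(0.5 + 5.1)
        assert cane_state.mineral.no3 == pytest.approx(0.5 + 5.1)

    def test_irrigate_fills_to_field_capacity_idempotently(self, cane_state):
        ev = mgmt.ManagementEvent(dt.date(2013, 1, 1), "irrigate")
        cane_state.water.water = 2.0
        mgmt.apply_event(cane_state, ev)
        assert cane_state.water.water == cane_state.water.field_capacity
        mgmt.apply_event(cane_state, ev)
        assert cane_state.water.water == cane_state.water.field_capacity

    def test_plow_incorporates_everything_and_arms_cultivation(self, cane_state):
        c0, n0 = total_cn(cane_state)
        ev = mgmt.ManagementEvent(dt.date(2015, 12, 20), "plow",
                                  magnitude=30.0)
        mgmt.apply_event(cane_state, ev)
        assert cane_state.plant.total_c == 0.0
        assert cane_state.cultivation_days_left == \
            cane_state.bgc_params.cultivation_days
        c1, n1 = total_cn(cane_state)
        assert c1 == pytest.approx(c0, rel=1e-12)
        assert n1 == pytest.approx(n0, rel=1e-12)

    def test_graze_returns_half_as_manure(self, cane_state):
        c0, n0 = total_cn(cane_state)
        met0 = cane_state.som.surface_metabolic_c
        ev = mgmt.ManagementEvent(dt.date(2000, 5, 15), "graze",
                                  live_frac=0.1, dead_frac=0.01)
        out = mgmt.apply_event(cane_state, ev)
        removed_c = 0.1 * 900.0 + 0.01 * 100.0
        assert out["grazed_c"] == pytest.approx(0.5 * removed_c)
        assert cane_state.som.surface_metabolic_c - met0 == \
            pytest.approx(0.5 * removed_c)
        c1, n1 = total_cn(cane_state)
        assert c1 + out["grazed_c"] == pytest.approx(c0, rel=1e-12)
        assert n1 + out["grazed_n"] == pytest.approx(n0, rel=1e-12)

    def test_plant_seeds_biomass_as_external_input(self, cane_state):
        c0, _ = total_cn(cane_state)
        ev = mgmt.ManagementEvent(dt.date(2013, 1, 15), "plant",
                                  magnitude=60.0)
        out = mgmt.apply_event(cane_state, ev)
        c1, _ = total_cn(cane_state)
        assert out["seed_c"] == pytest.approx(60.0)
        assert c1 - c0 == pytest.approx(60.0)

    @pytest.mark.parametrize("kind,kw", [
        ("plow", dict(magnitude=20.0)),
        ("harvest", dict(magnitude=1.5)),
        ("fertilize", dict(magnitude=-1.0)),
        ("graze", dict(live_frac=1.2)),
        ("till", dict()),
    ])
    def test_invalid_events_rejected(self, kind, kw):
        with pytest.raises(ValueError):
            mgmt.ManagementEvent(dt.date(2013, 1, 1), kind, **kw)
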
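"""Shared fixtures: parameter sets and the two-soil conversion experiments.

The full land-use-change runs use a 150-year savanna spin-up: long enough
for litter/active pools and the plant community to equilibrate while keeping
the suite desk-scale (the spin-up length is configurable; the packaged
default is 2000 years).
"""

import pytest

from canesim import bgc, engine, plants, soil, weather

EXPERIMENT_SPIN_UP_YEARS = 150
EXPERIMENT_SEED = 1


@pytest.fixture(scope="session")
def bgc_params():
    return bgc.load_bgc_params()


@pytest.fixture(scope="session")
def cane_params():
    return plants.load_plant_params("energy_cane")


@pytest.fixture(scope="session")
def grass_params():
    return plants.load_plant_params("bahiagrass")


@pytest.fixture(scope="session")
def histosol_profile():
    return soil.load_soil_params("histosol")


@pytest.fixture(scope="session")
def spodosol_profile():
    return soil.load_soil_params("spodosol")


@pytest.fixture(scope="session")
def florida_spec():
    return weather.florida_default_spec(seed=11)


def _run(soil_type: str) -> engine.ConversionResult:
    cfg = engine.SimulationConfig(
        soil_type=soil_type,
        climate_seed=EXPERIMENT_SEED,
        spin_up_years=EXPERIMENT_SPIN_UP_YEARS,
    )
    return engine.run_conversion_experiment(
        soil_type, seed=EXPERIMENT_SEED, config=cfg)


@pytest.fixture(scope="session")
def spodosol_run() -> engine.ConversionResult:
    return _run("spodosol")


@pytest.fixture(scope="session")
def histosol_run() -> engine.ConversionResult:
    return _run("histosol")
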
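"""Management calendars: grazing, plowing, planting, harvest, fertilizer, irrigation.

Two canonical schedules encode the land-use experiment:

* **Pasture** -- monthly grazing events whose compounded annual removals are
  10% of live shoots and 1.0% of standing dead shoots, with the cattle
  stocking rate recorded for the enteric CH4 source.  No fertilizer, no
  irrigation.
* **Energy cane** -- three-year plant/ratoon/ratoon cycles: planting in
  mid-January of year 1, an 80% aboveground harvest each mid-December, and a
  plow to 30 cm after the second-ratoon harvest before replanting.  On
  Spodosols, 10.2 g N m-2 of ammonium-nitrate is applied in mid-February and
  mid-June of every year (Histosols are never fertilized).  Irrigation fills
  the soil bucket to field capacity monthly in the November-April dry season
  and every second month in the May-October rainy season.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field, asdict
from typing import TYPE_CHECKING

import yaml

if TYPE_CHECKING:  # pragma: no cover
    from .engine import EcosystemState

__all__ = [
    "ManagementEvent",
    "Schedule",
    "build_pasture_schedule",
    "build_energy_cane_schedule",
    "apply_event",
    "annual_to_monthly_fraction",
    "PLOW_DEPTH_CM",
    "FERTILIZER_RATE_G_N_M2",
    "HARVEST_FRACTION",
    "SEED_C",
]

log = logging.getLogger(__name__)

PLOW_DEPTH_CM = 30.0
FERTILIZER_RATE_G_N_M2 = 10.2   # = 102 kg N ha-1 per application
HARVEST_FRACTION = 0.80
GRAZE_LIVE_ANNUAL = 0.10
GRAZE_DEAD_ANNUAL = 0.01
GRAZE_EXPORT_FRACTION = 0.5     # removed biomass: half offtake, half manure
SEED_C = 60.0                   # g C m-2 planted propagule mass

_KINDS = ("plow", "plant", "harvest", "graze", "fertilize", "irrigate",
          "remove_biomass")


def annual_to_monthly_fraction(annual: float) -> float:
    """Monthly removal fraction f with (1-f)^12 = 1 - annual (compounded)."""
    return 1.0 - (1.0 - annual) ** (1.0 / 12.0)


@dataclass(frozen=True)
class ManagementEvent:
    """A dated action applied to the ecosystem state.

    ``magnitude`` is kind-specific: plow depth (cm), harvested fraction,
    fertilizer dose (g N m-2); grazing carries ``live_frac``/``dead_frac``.
    Irrigation has no magnitude -- it fills to field capacity.
    """

    date: _dt.date
    kind: str
    magnitude: float = 0.0
    live_frac: float = 0.0
    dead_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "harvest" and not 0.0 <= self.magnitude <= 1.0:
            raise ValueError("harvest fraction must be in [0, 1]")
        if self.kind == "fertilize" and self.magnitude < 0:
            raise ValueError("fertilizer dose must be >= 0")
        if self.kind == "graze" and not (
                0.0 <= self.live_frac <= 1.0 and 0.0 <= self.dead_frac <= 1.0):
            raise ValueError("graze fractions must be in [0, 1]")
        if self.kind == "plow" and self.magnitude != PLOW_DEPTH_CM:
            raise ValueError("plow depth is fixed at 30 cm")


@dataclass
class Schedule:
    """Date-ordered management events for one scenario phase."""

    events: list[ManagementEvent]
    scenario: str
    soil_type: str
    stocking: float = 0.0   # head cattle ha-1 (enteric CH4 source)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.date)

    def events_on(self, date: _dt.date) -> list[ManagementEvent]:
        return [e for e in self.events if e.date == date]

    def by_date(self) -> dict[_dt.date, list[ManagementEvent]]:
        out: dict[_dt.date, list[ManagementEvent]] = {}
        for e in self.events:
            out.setdefault(e.date, []).append(e)
        return out

    def to_yaml(self, path) -> None:
        doc = {
            "scenario": self.scenario,
            "soil_type": self.soil_type,
            "stocking": self.stocking,
            "events": [
                {"date": e.date.isoformat(), "kind": e.kind,
                 "magnitude": e.magnitude, "live_frac": e.live_frac,
                 "dead_frac": e.dead_frac}
                for e in self.events
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Schedule":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        events = [
            ManagementEvent(
                date=_dt.date.fromisoformat(str(e["date"])), kind=e["kind"],
                magnitude=e["magnitude"], live_frac=e["live_frac"],
                dead_frac=e["dead_frac"])
            for e in doc["events"]
        ]
        return cls(events=events, scenario=doc["scenario"],
                   soil_type=doc["soil_type"], stocking=doc["stocking"])


def build_pasture_schedule(start_year: int, n_years: int,
                           stocking: float = 1.0,
                           soil_type: str = "spodosol") -> Schedule:
    """Grazed bahiagrass pasture: 12 graze events per year, nothing else.

    Monthly removal fractions are the compounded equivalents of the annual
    targets (10% of live shoots, 1.0% of standing dead), so the annual
    totals match exactly.  ``stocking`` feeds the enteric CH4 source only;
    set it to 0 for an ungrazed sensitivity run (removals still occur).
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    live_f = annual_to_monthly_fraction(GRAZE_LIVE_ANNUAL)
    dead_f = annual_to_monthly_fraction(GRAZE_DEAD_ANNUAL)
    events = [
        ManagementEvent(_dt.date(year, month, 15), "graze",
                        live_frac=live_f, dead_frac=dead_f)
        for year in range(start_year, start_year + n_years)
        for month in range(1, 13)
    ]
    return Schedule(events=events, scenario="pasture", soil_type=soil_type,
                    stocking=stocking)


# irrigation months: monthly through the Nov-Apr dry season, every second
# month in the May-Oct rainy season
_IRRIGATION_MONTHS = (1, 2, 3, 4, 5, 7, 9, 11, 12)


def build_energy_cane_schedule(start_year: int, n_cycles: int,
                               soil_type: str) -> Schedule:
    """Energy cane plant/ratoon/ratoon cycles with soil-specific fertilization."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if soil_type not in ("spodosol", "histosol"):
        raise ValueError(f"unknown soil_type {soil_type!r}")
    events: list[ManagementEvent] = []
    for cycle in range(n_cycles):
        y0 = start_year + 3 * cycle
        events.append(ManagementEvent(_dt.date(y0, 1, 15), "plant",
                                      magnitude=SEED_C))
        for yr in (y0, y0 + 1, y0 + 2):
            events.append(ManagementEvent(_dt.date(yr, 12, 15), "harvest",
                                          magnitude=HARVEST_FRACTION))
        events.append(ManagementEvent(_dt.date(y0 + 2, 12, 20), "plow",
                                      magnitude=PLOW_DEPTH_CM))
    n_years = 3 * n_cycles
    for year in range(start_year, start_year + n_years):
        if soil_type == "spodosol":
            events.append(ManagementEvent(_dt.date(year, 2, 15), "fertilize",
                                          magnitude=FERTILIZER_RATE_G_N_M2))
            events.append(ManagementEvent(_dt.date(year, 6, 15), "fertilize",
                                          magnitude=FERTILIZER_RATE_G_N_M2))
        for month in _IRRIGATION_MONTHS:
            events.append(ManagementEvent(_dt.date(year, month, 1), "irrigate"))
    return Schedule(events=events, scenario="energy_cane", soil_type=soil_type,
                    stocking=0.0)


def apply_event(state: "EcosystemState", event: ManagementEvent) -> dict:
    """Apply one management event to the ecosystem state.

    Returns an export dict: ``harvest_c``/``harvest_n`` for harvest and
    biomass-removal events, ``grazed_c``/``grazed_n`` for the exported half
    of grazed material (the other half returns as manure to the metabolic
    litter pool), ``seed_c``/``seed_n`` for planted propagule inputs.  Every
    event conserves C and N across state + exports + returns exactly.
    """
    from .bgc import partition_residue  # deferred: avoids cycle at import

    plant = state.plant
    pp = state.plant_params
    out = {"harvest_c": 0.0, "harvest_n": 0.0, "grazed_c": 0.0,
           "grazed_n": 0.0, "seed_c": 0.0, "seed_n": 0.0}

    if event.kind == "plow":
        # all standing material and roots enter the litter pools; microbial
        # activity is stimulated for the following weeks
        above_c = plant.leaf_c + plant.stem_c + plant.dead_c
        above_n = plant.leaf_n + plant.stem_n + plant.dead_n + plant.reserve_n
        partition_residue(state.som, above_c, above_n,
                          pp.lignin_frac_leaf, state.bgc_params)
        partition_residue(state.som, plant.root_c, plant.root_n,
                          pp.lignin_frac_root, state.bgc_params)
        plant.leaf_c = plant.stem_c = plant.root_c = plant.dead_c = 0.0
        plant.leaf_n = plant.stem_n = plant.root_n = plant.dead_n = 0.0
        plant.reserve_n = 0.0
        plant.reset_phenology()
        state.cultivation_days_left = state.bgc_params.cultivation_days
    elif event.kind == "remove_biomass":
        out["harvest_c"] = plant.leaf_c + plant.stem_c + plant.dead_c
        out["harvest_n"] = plant.leaf_n + plant.stem_n + plant.dead_n
        plant.leaf_c = plant.stem_c = plant.dead_c = 0.0
        plant.leaf_n = plant.stem_n = plant.dead_n = 0.0
    elif event.kind == "plant":
        seed_c = event.magnitude if event.magnitude > 0 else SEED_C
        plant.leaf_c += 0.5 * seed_c
        plant.stem_c += 0.2 * seed_c
        plant.root_c += 0.3 * seed_c
        seed_n = (0.5 * seed_c / pp.min_cn_leaf + 0.2 * seed_c / pp.min_cn_stem
                  + 0.3 * seed_c / pp.cn_root)
        plant.leaf_n += 0.5 * seed_c / pp.min_cn_leaf
        plant.stem_n += 0.2 * seed_c / pp.min_cn_stem
        plant.root_n += 0.3 * seed_c / pp.cn_root
        plant.reset_phenology()
        out["seed_c"] = seed_c
        out["seed_n"] = seed_n
    elif event.kind == "harvest":
        frac = event.magnitude
        above_c = plant.leaf_c + plant.stem_c + plant.dead_c
        above_n = plant.leaf_n + plant.stem_n + plant.dead_n
        out["harvest_c"] = frac * above_c
        out["harvest_n"] = frac * above_n
        residue_c = (1.0 - frac) * above_c
        residue_n = (1.0 - frac) * above_n
        partition_residue(state.som, residue_c, residue_n,
                          pp.lignin_frac_leaf, state.bgc_params)
        plant.leaf_c = plant.stem_c = plant.dead_c = 0.0
        plant.leaf_n = plant.stem_n = plant.dead_n = 0.0
        plant.reset_phenology()
    elif event.kind == "graze":
        rem_c = event.live_frac * (plant.leaf_c + plant.stem_c) \
            + event.dead_frac * plant.dead_c
        rem_n = event.live_frac * (plant.leaf_n + plant.stem_n) \
            + event.dead_frac * plant.dead_n
        plant.leaf_c *= 1.0 - event.live_frac
        plant.stem_c *= 1.0 - event.live_frac
        plant.leaf_n *= 1.0 - event.live_frac
        plant.stem_n *= 1.0 - event.live_frac
        plant.dead_c *= 1.0 - event.dead_frac
        plant.dead_n *= 1.0 - event.dead_frac
        exported_c = GRAZE_EXPORT_FRACTION * rem_c
        exported_n = GRAZE_EXPORT_FRACTION * rem_n
        # the other half returns as manure: labile, straight to metabolic
        state.som.surface_metabolic_c += rem_c - exported_c
        state.som.surface_metabolic_n += rem_n - exported_n
        out["grazed_c"] = exported_c
        out["grazed_n"] = exported_n
    elif event.kind == "fertilize":
        # ammonium-nitrate: a 50/50 NH4+/NO3- split by N mass
        state.mineral.nh4 += 0.5 * event.magnitude
        state.mineral.no3 += 0.5 * event.magnitude
    elif event.kind == "irrigate":
        state.water.water = max(state.water.water, state.water.field_capacity)
    else:  # pragma: no cover
        log.warning("event %s is a no-op on this state", event.kind)
    return out
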
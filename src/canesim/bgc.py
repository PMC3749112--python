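"""Soil water bucket, SOM decomposition, N trace gases, NO3 leaching, CH4.

The soil organic matter submodel is a Century-family five-pool cascade over
the 0-30 cm active column: two litter pools (metabolic and structural, fed
by plant residue split on its lignin:N ratio) and three soil pools (active,
slow, passive) with first-order decay.  Each decaying flow loses a respired
fraction as heterotrophic CO2 and transfers the remainder along a fixed
topology; nitrogen follows carbon at donor C:N, with net mineralization to
the ammonium pool when receiver C:N targets are exceeded and immobilization
from it when residue is N-poor.

Trace gases: nitrification converts NH4 to NO3 with a fixed fractional N2O
leak; denitrification switches on above a water-filled-pore-space threshold
and consumes NO3 in proportion to labile C, partitioning toward N2 as the
soil approaches saturation.  Methane is a small temperature- and
aeration-dependent soil oxidation sink plus, under grazing, an enteric
cattle source.  All rate constants live in ``bgc_defaults.yaml`` and can be
overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

from ._resources import load_packaged_yaml

__all__ = [
    "SOMPools",
    "SoilWaterState",
    "MineralN",
    "DailyFluxes",
    "BGCParams",
    "load_bgc_params",
    "water_balance_step",
    "partition_residue",
    "decompose_step",
    "nitrify_denitrify",
    "ch4_flux",
    "leach_no3",
    "temperature_factor",
    "moisture_factor",
]


@dataclass
class SOMPools:
    """Litter and soil organic matter pools, g C or g N m-2 (0-30 cm)."""

    surface_metabolic_c: float = 0.0
    surface_metabolic_n: float = 0.0
    surface_structural_c: float = 0.0
    surface_structural_n: float = 0.0
    active_c: float = 0.0
    active_n: float = 0.0
    slow_c: float = 0.0
    slow_n: float = 0.0
    passive_c: float = 0.0
    passive_n: float = 0.0

    @property
    def litter_c(self) -> float:
        return self.surface_metabolic_c + self.surface_structural_c

    @property
    def soil_c(self) -> float:
        """Soil organic carbon proper (active + slow + passive)."""
        return self.active_c + self.slow_c + self.passive_c

    @property
    def total_c(self) -> float:
        return self.litter_c + self.soil_c

    @property
    def total_n(self) -> float:
        return (self.surface_metabolic_n + self.surface_structural_n
                + self.active_n + self.slow_n + self.passive_n)


@dataclass
class SoilWaterState:
    """Single-bucket soil water over the 0-30 cm column, depths in cm."""

    water: float
    field_capacity: float
    wilting_point: float
    saturation: float

    @property
    def wfps(self) -> float:
        return min(1.0, max(0.0, self.water / self.saturation))

    @property
    def stress(self) -> float:
        """Plant water limitation factor: 0 at wilting point, 1 at field capacity."""
        rel = ((self.water - self.wilting_point)
               / (self.field_capacity - self.wilting_point))
        return min(1.0, max(0.0, rel))


@dataclass
class MineralN:
    """Mineral nitrogen pools, g N m-2."""

    nh4: float = 0.0
    no3: float = 0.0

    @property
    def total(self) -> float:
        return self.nh4 + self.no3


@dataclass
class DailyFluxes:
    """One day's soil-atmosphere fluxes (g C or g N m-2 d-1)."""

    rh: float = 0.0
    root_resp: float = 0.0
    n_mineralized: float = 0.0
    n2o_n: float = 0.0
    n2_n: float = 0.0
    ch4_c_net: float = 0.0
    no3_leached: float = 0.0

    @property
    def total_soil_co2(self) -> float:
        return self.rh + self.root_resp


@dataclass(frozen=True)
class BGCParams:
    # first-order decay constants, yr-1
    k_surface_metabolic: float = 14.8
    k_surface_structural: float = 3.9
    k_active: float = 7.3
    k_slow: float = 0.2
    k_passive: float = 0.0045
    # respired fraction of each decaying flow
    resp_surface_metabolic: float = 0.55
    resp_surface_structural: float = 0.45
    resp_active: float = 0.55
    resp_slow: float = 0.45
    resp_passive: float = 0.55
    # receiver C:N targets
    cn_active: float = 8.0
    cn_slow: float = 16.0
    cn_passive: float = 8.0
    cn_structural: float = 150.0
    # residue split: metabolic fraction = fm_intercept - fm_slope * lignin:N
    fm_intercept: float = 0.85
    fm_slope: float = 0.013
    # climate response
    q10: float = 2.0
    t_ref: float = 20.0
    # nitrification / denitrification
    k_nit: float = 0.10             # d-1 of NH4
    f_n2o_nit: float = 0.02         # N2O-N fraction of nitrified N
    wfps_denit_threshold: float = 0.60
    k_denit: float = 0.08           # d-1 of NO3 at full activity
    denit_labile_half_sat: float = 300.0  # g active C m-2
    # methane
    k_ch4_ox: float = 0.0013        # g C m-2 d-1 at f_temp=1, dry soil
    enteric_ef: float = 90.0        # kg CH4 head-1 yr-1
    # leaching
    no3_mobility: float = 0.7
    # immobilization cap: share of NH4+NO3 available to microbes per day
    immob_frac: float = 0.5
    # cultivation stimulation after a plow event
    cultivation_multiplier: float = 1.6
    cultivation_days: int = 30


def load_bgc_params(overrides: dict | None = None) -> BGCParams:
    """Packaged biogeochemistry constants, with optional field overrides."""
    raw = load_packaged_yaml("bgc_defaults.yaml")
    if overrides:
        raw.update(overrides)
    return BGCParams(**raw)


def temperature_factor(tavg: float, params: BGCParams) -> float:
    """Q10 temperature response referenced to ``t_ref`` on mean air temperature."""
    return params.q10 ** ((tavg - params.t_ref) / 10.0)


def moisture_factor(water: SoilWaterState) -> float:
    """Decomposition moisture limitation: linear wilting point -> field capacity."""
    return water.stress


def water_balance_step(state: SoilWaterState, precip_mm: float,
                       irrigation_cm: float, et_demand_cm: float) -> float:
    """Daily bucket water balance; returns drainage (cm).

    Water gains precipitation and irrigation, loses the supplied (actual)
    evapotranspiration, and sheds any excess above field capacity as
    drainage.  The store never goes negative and never ends the day above
    field capacity.
    """
    if precip_mm < 0 or irrigation_cm < 0 or et_demand_cm < 0:
        raise ValueError("water inputs must be >= 0")
    state.water += precip_mm / 10.0 + irrigation_cm
    state.water -= min(et_demand_cm, state.water)
    drainage = max(0.0, state.water - state.field_capacity)
    state.water -= drainage
    return drainage


def partition_residue(pools: SOMPools, c_in: float, n_in: float,
                      lignin_frac: float, params: BGCParams) -> None:
    """Add plant residue to the litter pools, split on its lignin:N ratio.

    The metabolic fraction is ``fm = fm_intercept - fm_slope * (lignin:N)``
    (clipped to [0.2, fm_intercept]); structural material takes N at its
    fixed wide C:N, the remainder of the residue N goes metabolic.
    """
    if c_in <= 0.0:
        # residue may be pure N (e.g. a plant N reserve plowed under)
        if n_in > 0.0:
            pools.surface_metabolic_n += n_in
        return
    if n_in <= 0.0:
        fm = 0.2
    else:
        lig_n = (lignin_frac * c_in) / n_in
        fm = min(params.fm_intercept,
                 max(0.2, params.fm_intercept - params.fm_slope * lig_n))
    met_c = fm * c_in
    str_c = c_in - met_c
    str_n = min(n_in, str_c / params.cn_structural)
    met_n = n_in - str_n
    pools.surface_metabolic_c += met_c
    pools.surface_metabolic_n += met_n
    pools.surface_structural_c += str_c
    pools.surface_structural_n += str_n


# pool cascade: donor -> (k, respired fraction, ((receiver, share), ...))
_TOPOLOGY = (
    ("surface_metabolic", "k_surface_metabolic", "resp_surface_metabolic",
     (("active", 1.0),)),
    ("surface_structural", "k_surface_structural", "resp_surface_structural",
     (("active", 0.7), ("slow", 0.3))),
    ("active", "k_active", "resp_active", (("slow", 0.95), ("passive", 0.05))),
    ("slow", "k_slow", "resp_slow", (("active", 0.95), ("passive", 0.05))),
    ("passive", "k_passive", "resp_passive", (("active", 1.0),)),
)

_CN_TARGET = {"active": "cn_active", "slow": "cn_slow", "passive": "cn_passive"}


def decompose_step(pools: SOMPools, f_temp: float, f_water: float,
                   cultivation_multiplier: float, params: BGCParams,
                   mineral_n_available: float = 0.0) -> dict:
    """One day of first-order decomposition through the pool cascade.

    Each pool decays by the daily fraction ``1 - exp(-k * mult / 365)`` with
    ``mult = f_temp * f_water * cultivation_multiplier``; the respired share
    of every flow leaves as heterotrophic CO2, the rest transfers along the
    cascade.  N moves with C at donor C:N; receivers are filled toward their
    target C:N, surplus N mineralizes to the ammonium pool and deficits are
    met by immobilizing up to ``immob_frac`` of ``mineral_n_available``.

    Returns a dict with ``rh``, ``n_mineral_delta`` (net change to mineral N;
    negative = immobilization), ``gross_n_release`` and ``c_out`` (= rh,
    since transfers are internal).  C is conserved exactly:
    ``delta(total pools) + rh = 0`` in the absence of inputs.
    """
    if f_temp < 0 or f_water < 0 or cultivation_multiplier < 0:
        raise ValueError("decomposition multipliers must be >= 0")
    mult = f_temp * f_water * cultivation_multiplier
    rh = 0.0
    release_n = 0.0
    recv_c: dict[str, float] = {"active": 0.0, "slow": 0.0, "passive": 0.0}
    for donor, k_attr, resp_attr, receivers in _TOPOLOGY:
        c = getattr(pools, donor + "_c")
        if c <= 0.0:
            continue
        frac = 1.0 - math.exp(-getattr(params, k_attr) * mult / 365.0)
        flow_c = c * frac
        n = getattr(pools, donor + "_n")
        flow_n = n * frac
        setattr(pools, donor + "_c", c - flow_c)
        setattr(pools, donor + "_n", n - flow_n)
        resp = getattr(params, resp_attr)
        rh += flow_c * resp
        release_n += flow_n
        remaining = flow_c * (1.0 - resp)
        for recv, share in receivers:
            recv_c[recv] += remaining * share
    demand_n = sum(c / getattr(params, _CN_TARGET[r]) for r, c in recv_c.items())
    immob_avail = params.immob_frac * max(0.0, mineral_n_available)
    given_n = min(demand_n, release_n + immob_avail)
    scale = given_n / demand_n if demand_n > 0 else 0.0
    for recv, c in recv_c.items():
        setattr(pools, recv + "_c", getattr(pools, recv + "_c") + c)
        setattr(pools, recv + "_n",
                getattr(pools, recv + "_n")
                + scale * c / getattr(params, _CN_TARGET[recv]))
    n_mineral_delta = release_n - given_n
    return {"rh": rh, "n_mineral_delta": n_mineral_delta,
            "gross_n_release": release_n, "c_out": rh}


def nitrify_denitrify(mineral: MineralN, wfps: float, f_temp: float,
                      labile_c_proxy: float, params: BGCParams
                      ) -> tuple[float, float]:
    """Daily nitrification and denitrification; returns ``(n2o_n, n2_n)``.

    Nitrification moves ``k_nit * f_temp * f_w`` of the NH4 pool to NO3,
    leaking ``f_n2o_nit`` of the converted N as N2O.  Denitrification is
    active only above the WFPS threshold, scales with NO3, labile C
    (active-pool C, Michaelis saturation) and a quadratic WFPS response, and
    shifts its product toward N2 as the soil approaches saturation.
    Emissions never exceed the substrate pools.
    """
    if wfps < 0 or wfps > 1 or f_temp < 0 or labile_c_proxy < 0:
        raise ValueError("invalid nitrify_denitrify inputs")
    # nitrification moisture response: optimal near field capacity, shut
    # down in saturated (anaerobic) soil
    f_w_nit = min(1.0, max(0.0, 1.0 - abs(wfps - 0.55) / 0.45))
    nitrified = min(mineral.nh4, params.k_nit * mineral.nh4
                    * min(f_temp, 2.0) * f_w_nit)
    n2o_nit = params.f_n2o_nit * nitrified
    mineral.nh4 -= nitrified
    mineral.no3 += nitrified - n2o_nit

    n2o_den = n2_den = 0.0
    thr = params.wfps_denit_threshold
    if wfps > thr and mineral.no3 > 0.0:
        g = ((wfps - thr) / (1.0 - thr)) ** 2
        f_labile = labile_c_proxy / (labile_c_proxy + params.denit_labile_half_sat)
        denit = min(0.8 * mineral.no3,
                    params.k_denit * mineral.no3 * min(f_temp, 2.0) * f_labile * g)
        # N2O share of denitrified N falls from 0.5 toward 0.05 as wfps -> 1
        n2o_share = max(0.05, 0.5 * (1.0 - (wfps - thr) / (1.0 - thr)))
        n2o_den = denit * n2o_share
        n2_den = denit - n2o_den
        mineral.no3 -= denit
    return n2o_nit + n2o_den, n2_den


def ch4_flux(wfps: float, f_temp: float, stocking: float,
             enteric_ef: float, params: BGCParams) -> float:
    """Net daily CH4 flux, g CH4-C m-2 d-1 (positive = efflux).

    Enteric source: ``stocking`` (head ha-1) times the per-head emission
    factor (kg CH4 head-1 yr-1), converted to g CH4-C m-2 d-1 (x 12/16).
    Soil sink: ``k_ch4_ox * f_temp * (1 - wfps)``, calibrated so an
    unstocked pasture takes up a few tenths of a g C m-2 yr-1.
    """
    if stocking < 0:
        raise ValueError("stocking must be >= 0")
    enteric = stocking * enteric_ef * 1000.0 / 1e4 / 365.0 * (12.0 / 16.0)
    sink = params.k_ch4_ox * f_temp * (1.0 - min(1.0, max(0.0, wfps)))
    return enteric - sink


def leach_no3(mineral: MineralN, drainage_cm: float,
              water_holding_cm: float, params: BGCParams) -> float:
    """NO3 leached with drainage (g N m-2 d-1); removed from the pool.

    Leached fraction = ``min(1, drainage / water-holding depth) * mobility``;
    never exceeds the NO3 pool.
    """
    if drainage_cm < 0:
        raise ValueError("drainage must be >= 0")
    if drainage_cm == 0.0 or mineral.no3 <= 0.0:
        return 0.0
    frac = min(1.0, drainage_cm / water_holding_cm) * params.no3_mobility
    leached = mineral.no3 * frac
    mineral.no3 -= leached
    return leached
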
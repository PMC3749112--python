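"""Daily plant production, allocation, N uptake, senescence.

Three parameter sets drive the land-use-change experiment: a savanna grass
mix (with symbiotic N fixation) used for spin-up, bahiagrass pasture, and
energy cane.  Production uses a transparent multiplicative-limitation model:

    assimilation = max_daily_npp * f(temperature) * f(water) * f(canopy) * f(N)

with each factor in [0, 1].  The temperature response is a Gaussian around a
warm-season optimum (default 30 degC, width 10 degC, C4-like); the canopy
factor saturates with standing leaf mass so that a freshly planted or
freshly harvested (ratoon) crop ramps up rather than growing at full rate
from day one.  A fixed fraction of assimilate is respired belowground
(root/autotrophic respiration); the remainder is allocated to leaf, stem and
root pools by fixed fractions.  Nitrogen uptake holds every live pool's C:N
between a parameterized minimum (luxury consumption) and maximum (dilution
limit): when mineral N cannot keep new tissue at or below the maximum C:N,
growth itself is curtailed.

Phenology is growing-degree-day driven: pools are dormant until an emergence
threshold, grow until a senescence threshold, and an explicit kill/harvest
event (see :mod:`canesim.management`) resets the accumulator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from ._resources import load_packaged_yaml

__all__ = [
    "PlantParams",
    "PlantState",
    "load_plant_params",
    "gdd_update",
    "daily_production",
    "allocate_and_uptake",
    "senesce_and_die",
]

log = logging.getLogger(__name__)

DORMANT, GROWING, SENESCENT = "dormant", "growing", "senescent"


@dataclass(frozen=True)
class PlantParams:
    name: str
    gdd_base: float                 # degC
    gdd_emergence: float            # degC day
    gdd_senescence: float           # degC day
    max_daily_npp: float            # g C m-2 d-1 potential assimilation
    alloc_stem: float
    alloc_leaf: float
    alloc_root: float
    min_cn_leaf: float
    max_cn_leaf: float
    min_cn_stem: float
    max_cn_stem: float
    cn_root: float                  # root tissue target C:N
    tissue_c_frac_leaf: float       # g C per g dry mass
    tissue_c_frac_stem: float
    n_fixation_rate: float = 0.0    # g N m-2 yr-1 (savanna mix only)
    temp_opt: float = 30.0
    temp_width: float = 10.0
    root_resp_frac: float = 0.25    # share of assimilate respired belowground
    leaf_turnover: float = 0.003    # d-1 background senescence of leaves
    stem_turnover: float = 0.0      # d-1 background stem senescence (grasses)
    senescent_turnover: float = 0.010  # d-1 live->dead in the senescent phase
    dead_fall_rate: float = 0.010   # d-1 standing dead -> surface litter
    root_turnover: float = 0.0025   # d-1 root -> root litter
    n_resorption_frac: float = 0.30  # share of senescing N recovered to reserve
    lignin_frac_leaf: float = 0.10
    lignin_frac_stem: float = 0.15
    lignin_frac_root: float = 0.12
    lai_ramp_c: float = 150.0       # g leaf C for ~63% canopy closure
    n_reserve_cap: float = 5.0      # g N m-2 internal (luxury) N storage

    def __post_init__(self) -> None:
        if abs(self.alloc_stem + self.alloc_leaf + self.alloc_root - 1.0) > 1e-6:
            raise ValueError("allocation fractions must sum to 1")
        for lo, hi in ((self.min_cn_leaf, self.max_cn_leaf),
                       (self.min_cn_stem, self.max_cn_stem)):
            if not 0 < lo <= hi:
                raise ValueError("require 0 < min_cn <= max_cn")
        for cf in (self.tissue_c_frac_leaf, self.tissue_c_frac_stem):
            if not 0.3 < cf < 0.5:
                raise ValueError("tissue C fraction must lie in (0.3, 0.5)")

    @property
    def aboveground_c_frac(self) -> float:
        """Whole-shoot C fraction of dry mass implied by allocation and tissue composition."""
        ab = self.alloc_leaf + self.alloc_stem
        return (self.alloc_leaf * self.tissue_c_frac_leaf
                + self.alloc_stem * self.tissue_c_frac_stem) / ab


@dataclass
class PlantState:
    """Live and standing-dead plant pools, g C or g N per m2."""

    leaf_c: float = 0.0
    stem_c: float = 0.0
    root_c: float = 0.0
    dead_c: float = 0.0
    leaf_n: float = 0.0
    stem_n: float = 0.0
    root_n: float = 0.0
    dead_n: float = 0.0
    reserve_n: float = 0.0   # retranslocated N available for regrowth
    gdd_accum: float = 0.0
    phenophase: str = DORMANT

    @property
    def live_c(self) -> float:
        return self.leaf_c + self.stem_c + self.root_c

    @property
    def aboveground_c(self) -> float:
        return self.leaf_c + self.stem_c + self.dead_c

    @property
    def total_c(self) -> float:
        return self.live_c + self.dead_c

    @property
    def total_n(self) -> float:
        return (self.leaf_n + self.stem_n + self.root_n + self.dead_n
                + self.reserve_n)

    def reset_phenology(self) -> None:
        self.gdd_accum = 0.0
        self.phenophase = DORMANT


_PARAM_FILES = {
    "energy_cane": "energy_cane.yaml",
    "bahiagrass": "bahiagrass.yaml",
    "savanna_mix": "savanna_mix.yaml",
}


def load_plant_params(name: str, overrides: dict | None = None) -> PlantParams:
    """Load one of the packaged species parameterizations."""
    if name not in _PARAM_FILES:
        raise ValueError(f"unknown species {name!r}; choose from {sorted(_PARAM_FILES)}")
    raw = load_packaged_yaml(_PARAM_FILES[name])
    if overrides:
        raw.update(overrides)
    return PlantParams(**raw)


def gdd_update(state: PlantState, tmax: float, tmin: float,
               params: PlantParams) -> float:
    """Accumulate growing degree days and move through phenophases.

    The daily increment is ``max(0, (tmax + tmin)/2 - gdd_base)``.  The plant
    emerges (dormant -> growing) at ``gdd_emergence`` and enters senescence
    at ``gdd_senescence``.  Returns the increment.
    """
    inc = max(0.0, 0.5 * (tmax + tmin) - params.gdd_base)
    state.gdd_accum += inc
    if state.phenophase == DORMANT and state.gdd_accum >= params.gdd_emergence:
        state.phenophase = GROWING
    if state.phenophase == GROWING and state.gdd_accum >= params.gdd_senescence:
        state.phenophase = SENESCENT
    return inc


def _temperature_factor(tavg: float, params: PlantParams) -> float:
    z = (tavg - params.temp_opt) / params.temp_width
    return math.exp(-z * z)


def _min_n_requirement(state: PlantState, d_leaf: float, d_stem: float,
                       d_root: float, params: PlantParams) -> tuple[float, float]:
    """(existing-tissue N deficit, per-unit-growth N need) at maximum C:N."""
    deficit = max(0.0, state.leaf_c / params.max_cn_leaf - state.leaf_n) \
        + max(0.0, state.stem_c / params.max_cn_stem - state.stem_n)
    slope = (d_leaf / params.max_cn_leaf + d_stem / params.max_cn_stem
             + d_root / params.cn_root)
    return deficit, slope


def daily_production(state: PlantState, tavg: float, soil_water_stress: float,
                     n_available: float, params: PlantParams
                     ) -> tuple[float, float]:
    """Realized daily assimilation and the external N uptake it commits to.

    Parameters
    ----------
    soil_water_stress : float
        Water limitation factor in [0, 1] (1 = unstressed).
    n_available : float
        Mineral N accessible to roots today, g N m-2.

    Returns
    -------
    (npp, n_uptake)
        ``npp`` is gross daily assimilation (g C m-2 d-1); a fraction
        ``root_resp_frac`` of it is respired belowground and the remainder
        enters the pools via :func:`allocate_and_uptake`.  ``n_uptake`` is
        the external mineral N (g N m-2) the growth requires/claims; it never
        drives any live pool's C:N above its maximum.
    """
    if n_available < 0:
        raise ValueError("n_available must be >= 0")
    if state.phenophase != GROWING:
        return 0.0, 0.0
    if not 0.0 <= soil_water_stress <= 1.0:
        raise ValueError("soil_water_stress must be in [0, 1]")
    f_t = _temperature_factor(tavg, params)
    f_canopy = 1.0 - math.exp(-(state.leaf_c + 0.25 * state.stem_c) / params.lai_ramp_c)
    potential = params.max_daily_npp * f_t * soil_water_stress * f_canopy
    if potential <= 0.0:
        return 0.0, 0.0
    growth = potential * (1.0 - params.root_resp_frac)
    d_leaf = growth * params.alloc_leaf
    d_stem = growth * params.alloc_stem
    d_root = growth * params.alloc_root
    deficit, slope = _min_n_requirement(state, d_leaf, d_stem, d_root, params)
    supply = state.reserve_n + n_available
    need_full = deficit + slope
    if need_full <= supply or need_full <= 0.0:
        f_n = 1.0
    elif supply <= deficit:
        f_n = 0.0
    else:
        f_n = (supply - deficit) / slope
    npp = potential * f_n
    n_required = deficit + slope * f_n
    n_external = max(0.0, n_required - state.reserve_n)
    n_external = min(n_external, n_available)
    return npp, n_external


def allocate_and_uptake(state: PlantState, npp: float, n_uptake: float,
                        params: PlantParams) -> dict:
    """Apply a day's growth: split C by allocation fractions, place N.

    ``npp`` is gross assimilation; ``root_resp_frac * npp`` is respired
    (returned in the flux dict, for the soil CO2 ledger) and the rest grows
    the pools.  ``n_uptake`` plus any internal reserve N is distributed
    preferring leaves, then stems, then roots, holding each pool between its
    minimum and maximum C:N where the supply allows.  C and N are conserved
    exactly: growth C + root respiration = npp; N placed + reserve change =
    n_uptake.
    """
    if npp < 0 or n_uptake < 0:
        raise ValueError("npp and n_uptake must be >= 0")
    root_resp = npp * params.root_resp_frac
    growth = npp - root_resp
    d_leaf = growth * params.alloc_leaf
    d_stem = growth * params.alloc_stem
    d_root = growth * params.alloc_root
    state.leaf_c += d_leaf
    state.stem_c += d_stem
    state.root_c += d_root
    pool_n = state.reserve_n + n_uptake
    # tissue N target interpolates from the maximum C:N (N-poor growth) to
    # the minimum C:N (luxury consumption), but only once the internal
    # reserve is comfortably full -- scarce N is spent on growth, not on
    # enriching tissue that may be exported
    if params.n_reserve_cap > 0:
        rel = state.reserve_n / params.n_reserve_cap
        fullness = min(1.0, max(0.0, (rel - 0.6) / 0.4))
    else:
        fullness = 0.0
    placed = 0.0
    for attr_c, attr_n, cn_min, cn_max in (
        ("leaf_c", "leaf_n", params.min_cn_leaf, params.max_cn_leaf),
        ("stem_c", "stem_n", params.min_cn_stem, params.max_cn_stem),
        ("root_c", "root_n", params.cn_root, params.cn_root),
    ):
        c = getattr(state, attr_c)
        n = getattr(state, attr_n)
        n_target = c / cn_max + (c / cn_min - c / cn_max) * fullness
        want = max(0.0, n_target - n)
        give = min(want, pool_n - placed)
        if give > 0:
            setattr(state, attr_n, n + give)
            placed += give
        if c > 0 and (n + max(give, 0.0)) * cn_max < c - 1e-9:
            log.debug("%s C:N above maximum after allocation", attr_c)
    state.reserve_n = pool_n - placed
    return {"growth_c": growth, "root_resp": root_resp,
            "d_leaf": d_leaf, "d_stem": d_stem, "d_root": d_root,
            "n_placed": placed}


def senesce_and_die(state: PlantState, params: PlantParams,
                    day_of_year: int) -> dict:
    """Daily tissue turnover: live -> standing dead -> surface litter; roots -> soil.

    Leaves turn over at a background rate while growing and at the senescent
    rate once the senescence threshold is passed (stems only senesce in the
    senescent phase).  A resorption fraction of the N in senescing leaf/stem
    tissue is withdrawn to the internal reserve before the tissue joins the
    standing-dead pool; standing dead sheds to surface litter at a constant
    rate; roots slough to root litter carrying their full N.  C and N are
    conserved across all transfers.

    Returns a flux dict with ``litter_c``/``litter_n`` (surface) and
    ``root_litter_c``/``root_litter_n``.
    """
    senescing = state.phenophase == SENESCENT
    leaf_rate = params.senescent_turnover if senescing else params.leaf_turnover
    stem_rate = params.senescent_turnover if senescing else params.stem_turnover

    dead_c_in = dead_n_in = resorb = 0.0
    for attr_c, attr_n, rate in (("leaf_c", "leaf_n", leaf_rate),
                                 ("stem_c", "stem_n", stem_rate)):
        c = getattr(state, attr_c)
        n = getattr(state, attr_n)
        dc = c * rate
        dn = n * rate
        keep = dn * params.n_resorption_frac
        setattr(state, attr_c, c - dc)
        setattr(state, attr_n, n - dn)
        dead_c_in += dc
        dead_n_in += dn - keep
        resorb += keep
    state.reserve_n += resorb
    state.dead_c += dead_c_in
    state.dead_n += dead_n_in

    fall_c = state.dead_c * params.dead_fall_rate
    fall_n = state.dead_n * params.dead_fall_rate
    state.dead_c -= fall_c
    state.dead_n -= fall_n

    root_c = state.root_c * params.root_turnover
    root_n = state.root_n * params.root_turnover
    state.root_c -= root_c
    state.root_n -= root_n
    return {"litter_c": fall_c, "litter_n": fall_n,
            "root_litter_c": root_c, "root_litter_n": root_n}
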
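"""Greenhouse-gas accounting: CO2 equivalents, budgets, and unit conversions.

Fluxes are simulated in elemental units (g CH4-C, g N2O-N per m2) and
converted to CO2 equivalents by element mass -> gas mass -> global warming
potential.  The default GWP factors are mass-basis multipliers: CO2 = 1, CH4 = 23, N2O = 296 (100-yr horizon, TAR-era
values); they can be overridden explicitly, which changes CO2eq outputs only.

Total system C flux is the annual change in ecosystem C storage (plant +
litter + soil organic matter of the modeled 0-30 cm column) expressed as
CO2 exchange with the atmosphere, positive toward the atmosphere.  Exported
biomass (harvest, grazing offtake) leaves storage and therefore appears as a
source the year it is removed -- harvested feedstock is assumed oxidized
(burned or digested) rather than sequestered.  A 15-year cumulative budget
sums total system C flux, CH4 and N2O in CO2eq; the grand total is exactly
the sum of the three components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GWPFactors",
    "GHGBudget",
    "ch4_c_to_co2eq",
    "n2o_n_to_co2eq",
    "total_system_c_flux",
    "cumulative_budget",
    "delta_table",
    "carbon_to_dry_mass_yield",
    "ethanol_volume",
    "budget_from_summaries",
]

CH4_C_TO_CH4 = 16.0 / 12.0
N2O_N_TO_N2O = 44.0 / 28.0
C_TO_CO2 = 44.0 / 12.0


@dataclass(frozen=True)
class GWPFactors:
    """Mass-basis global warming potentials (g CO2eq per g gas)."""

    co2: float = 1.0
    ch4: float = 23.0
    n2o: float = 296.0


@dataclass(frozen=True)
class GHGBudget:
    """Cumulative CO2-equivalent ledger over a window of years.

    Sign convention: positive = flux to the atmosphere.  ``total_ghg`` is
    exactly the sum of the three components.
    """

    window_years: int
    total_system_c_co2eq: float
    ch4_co2eq: float
    n2o_co2eq: float

    @property
    def total_ghg_co2eq(self) -> float:
        return self.total_system_c_co2eq + self.ch4_co2eq + self.n2o_co2eq


def ch4_c_to_co2eq(flux_ch4_c: float, factors: GWPFactors = GWPFactors()) -> float:
    """g CH4-C m-2 -> g CO2eq m-2 (x 16/12 x GWP); sign preserved."""
    return flux_ch4_c * CH4_C_TO_CH4 * factors.ch4


def n2o_n_to_co2eq(flux_n2o_n: float, factors: GWPFactors = GWPFactors()) -> float:
    """g N2O-N m-2 -> g CO2eq m-2 (x 44/28 x GWP); sign preserved."""
    return flux_n2o_n * N2O_N_TO_N2O * factors.n2o


def total_system_c_flux(annual_ecosystem_c, exports=None,
                        initial_c: float | None = None,
                        exports_are_lateral: bool = False) -> np.ndarray:
    """Annual net ecosystem C exchange with the atmosphere, g CO2eq m-2 yr-1.

    Parameters
    ----------
    annual_ecosystem_c : sequence
        End-of-year ecosystem C storage (g C m-2).  With ``initial_c`` given
        it is prepended, so n storage values yield n annual fluxes;
        otherwise differences of the series are used (n - 1 fluxes).
    exports : sequence, optional
        Annual lateral C removals (harvest, offtake).  By default exports
        are treated as returned to the atmosphere (biofuel feedstock is
        burned), so they are *not* credited as uptake and the flux is simply
        ``-(delta storage) * 44/12``.  With ``exports_are_lateral=True``
        exported C is excluded from the atmospheric exchange, crediting the
        uptake that produced it: ``-(delta storage + exports) * 44/12``.

    Positive values are a source to the atmosphere.
    """
    storage = np.asarray(annual_ecosystem_c, dtype=float)
    if initial_c is not None:
        storage = np.concatenate([[initial_c], storage])
    if storage.size < 2:
        raise ValueError("need at least two yearly storage values")
    delta = np.diff(storage)
    if exports is not None:
        exports = np.asarray(exports, dtype=float)
        if exports.size != delta.size:
            raise ValueError("exports length must match the number of years")
    if exports_are_lateral and exports is not None:
        delta = delta + exports
    return -delta * C_TO_CO2


def cumulative_budget(tsc_co2eq, ch4_co2eq, n2o_co2eq,
                      window: slice | None = None) -> GHGBudget:
    """Sum annual CO2eq series into a cumulative budget over ``window``."""
    tsc = np.asarray(tsc_co2eq, dtype=float)
    ch4 = np.asarray(ch4_co2eq, dtype=float)
    n2o = np.asarray(n2o_co2eq, dtype=float)
    if not tsc.size == ch4.size == n2o.size:
        raise ValueError("annual series must have equal lengths")
    if window is not None:
        idx = range(*window.indices(tsc.size))
        if len(list(idx)) == 0:
            raise ValueError("window selects no years")
        tsc, ch4, n2o = tsc[window], ch4[window], n2o[window]
    return GHGBudget(
        window_years=tsc.size,
        total_system_c_co2eq=float(tsc.sum()),
        ch4_co2eq=float(ch4.sum()),
        n2o_co2eq=float(n2o.sum()),
    )


def delta_table(pasture: pd.Series | dict, cane: pd.Series | dict) -> pd.Series:
    """Energy-cane-minus-pasture differences over matched row labels."""
    p = pd.Series(pasture, dtype=float)
    c = pd.Series(cane, dtype=float)
    if set(p.index) != set(c.index):
        raise ValueError("pasture and cane tables must share row labels")
    return c - p.reindex(c.index)


def carbon_to_dry_mass_yield(production_g_c_m2: float, c_frac: float) -> float:
    """g C m-2 yr-1 aboveground -> Mg dry mass ha-1 yr-1 (divide by C fraction)."""
    if not 0.0 < c_frac < 1.0:
        raise ValueError("c_frac must be in (0, 1)")
    return production_g_c_m2 / c_frac * 1e-2


def ethanol_volume(yield_mg_ha: float, area_ha: float,
                   conversion_l_per_mg: float = 310.0) -> float:
    """Cellulosic ethanol volume (L) from dry-mass yield, area and conversion."""
    if yield_mg_ha < 0 or area_ha < 0 or conversion_l_per_mg < 0:
        raise ValueError("inputs must be non-negative")
    return yield_mg_ha * area_ha * conversion_l_per_mg


def budget_from_summaries(summaries, initial_c: float,
                          factors: GWPFactors = GWPFactors()) -> GHGBudget:
    """15-yr style budget from a phase's annual summaries.

    Uses each year's end-of-year ecosystem C (plus the phase-start stock)
    for the total-system-C term and the annual CH4-C and N2O-N sums for the
    gas terms.
    """
    storage = [s.ecosystem_c_end for s in summaries]
    tsc = total_system_c_flux(storage, initial_c=initial_c)
    ch4 = [ch4_c_to_co2eq(s.ch4_c_net, factors) for s in summaries]
    n2o = [n2o_n_to_co2eq(s.n2o_n, factors) for s in summaries]
    return cumulative_budget(tsc, ch4, n2o)
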
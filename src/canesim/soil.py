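"""Soil profiles for the two study soils and Histosol subsidence bookkeeping.

Two contrasting soils from south-central Florida are represented:

* **Spodosols** -- nutrient-poor sands: 0.77 %C / 0.04 %N in the top 30 cm,
  0.36 %C / 0.02 %N from 30-100 cm.
* **Histosols** -- drained organic "muck": 7.77 %C / 0.50 %N, uniform over
  the profile.

The biogeochemistry operates on a 0-30 cm active column.  Drained Histosols
oxidize and subside: as organic matter in the top 30 cm is lost, the surface
drops and soil from below 30 cm (the *deep reservoir*, 30-100 cm) becomes
part of the active column, importing its carbon and nitrogen.  The
:func:`subsidence_step` function performs that annual mass balance: the soil
mass equivalent of the C oxidized is removed from the column, the surface
elevation loss follows from bulk density, and an equal soil mass is drawn
from the deep reservoir along with its C and N.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import yaml

from ._resources import load_packaged_yaml

__all__ = [
    "SoilLayer",
    "SoilProfile",
    "SubsidenceState",
    "load_soil_params",
    "subsidence_step",
    "profile_c_stock",
]

ACTIVE_DEPTH_CM = 30.0
PROFILE_DEPTH_CM = 100.0


@dataclass(frozen=True)
class SoilLayer:
    """One depth layer with composition and water-retention parameters.

    Depths in cm (top-inclusive, bottom-exclusive); ``bulk_density`` in
    g soil cm^-3; ``c_frac`` / ``n_frac`` in g per g soil; water constants
    as volumetric fractions; texture fractions sum to 1.
    """

    top_depth: float
    bottom_depth: float
    bulk_density: float
    c_frac: float
    n_frac: float
    field_capacity: float
    wilting_point: float
    saturation: float
    sand: float
    silt: float
    clay: float

    def __post_init__(self) -> None:
        if self.bottom_depth <= self.top_depth:
            raise ValueError("layer bottom must be below top")
        if not 0.0 < self.bulk_density < 2.2:
            raise ValueError(f"bulk_density {self.bulk_density} outside (0, 2.2)")
        if not 0.0 <= self.n_frac < self.c_frac < 1.0:
            raise ValueError("require 0 <= n_frac < c_frac < 1")
        if not self.wilting_point < self.field_capacity < self.saturation <= 1.0:
            raise ValueError("require wilting < field capacity < saturation <= 1")
        if abs(self.sand + self.silt + self.clay - 1.0) > 0.01:
            raise ValueError("texture fractions must sum to 1 +/- 0.01")

    @property
    def thickness_cm(self) -> float:
        return self.bottom_depth - self.top_depth

    def c_stock(self) -> float:
        """Layer C stock, g C m^-2 (= c_frac * BD [g cm^-3] * thickness [cm] * 1e4)."""
        return self.c_frac * self.bulk_density * self.thickness_cm * 1e4

    def n_stock(self) -> float:
        return self.n_frac * self.bulk_density * self.thickness_cm * 1e4


@dataclass(frozen=True)
class SoilProfile:
    """A 0-100 cm profile of contiguous layers for one of the study soils."""

    soil_type: str
    layers: tuple[SoilLayer, ...]
    active_depth: float = ACTIVE_DEPTH_CM

    def __post_init__(self) -> None:
        if self.soil_type not in ("spodosol", "histosol"):
            raise ValueError(f"unknown soil_type {self.soil_type!r}")
        if self.active_depth != ACTIVE_DEPTH_CM:
            raise ValueError("active_depth is fixed at 30 cm")
        if not self.layers:
            raise ValueError("profile needs at least one layer")
        if self.layers[0].top_depth != 0.0:
            raise ValueError("first layer must start at 0 cm")
        if self.layers[-1].bottom_depth != PROFILE_DEPTH_CM:
            raise ValueError("last layer must end at 100 cm")
        for above, below in zip(self.layers, self.layers[1:]):
            if above.bottom_depth != below.top_depth:
                raise ValueError("layers must be contiguous and non-overlapping")

    @property
    def top(self) -> SoilLayer:
        """The layer containing the active (0-30 cm) column."""
        return self.layers[0]

    def layer_below(self, depth_cm: float) -> SoilLayer:
        for layer in self.layers:
            if layer.top_depth <= depth_cm < layer.bottom_depth:
                return layer
        raise ValueError(f"depth {depth_cm} outside profile")


@dataclass
class SubsidenceState:
    """Running ledger of Histosol subsidence.

    ``deep_reservoir_soil_mass`` (g soil m^-2) and the matching C and N
    stocks start at the 30-100 cm totals of the profile; subsidence debits
    them as deep soil is incorporated into the active column.
    """

    cumulative_depth_loss: float = 0.0
    deep_reservoir_soil_mass: float = 0.0
    deep_reservoir_c: float = 0.0
    deep_reservoir_n: float = 0.0
    cumulative_c_added: float = 0.0
    cumulative_n_added: float = 0.0

    @classmethod
    def from_profile(cls, profile: SoilProfile) -> "SubsidenceState":
        mass = c = n = 0.0
        for layer in profile.layers:
            if layer.bottom_depth <= ACTIVE_DEPTH_CM:
                continue
            top = max(layer.top_depth, ACTIVE_DEPTH_CM)
            thick = layer.bottom_depth - top
            lm = layer.bulk_density * thick * 1e4  # g soil m^-2
            mass += lm
            c += lm * layer.c_frac
            n += lm * layer.n_frac
        return cls(0.0, mass, c, n)


_DEFAULT_FILES = {"spodosol": "spodosol.yaml", "histosol": "histosol.yaml"}


def load_soil_params(soil_type: str, overrides: dict | None = None) -> SoilProfile:
    """Load a packaged soil profile, optionally overriding layer fields.

    Composition defaults come from the measured profiles (see module
    docstring); physical defaults (bulk density, water constants, texture)
    are NRCS-typical values for these soil series.  ``overrides`` maps layer
    index -> {field: value}; invalid values are rejected by the layer
    invariants.
    """
    if soil_type not in _DEFAULT_FILES:
        raise ValueError(f"soil_type must be spodosol or histosol, got {soil_type!r}")
    raw = load_packaged_yaml(_DEFAULT_FILES[soil_type])
    layers = []
    for i, spec in enumerate(raw["layers"]):
        spec = dict(spec)
        if overrides and i in overrides:
            spec.update(overrides[i])
        layers.append(SoilLayer(**spec))
    return SoilProfile(soil_type=soil_type, layers=tuple(layers))


def subsidence_step(
    profile: SoilProfile, state: SubsidenceState, annual_c_oxidized: float
) -> tuple[SubsidenceState, float, float]:
    """One year of Histosol subsidence bookkeeping.

    Parameters
    ----------
    annual_c_oxidized : float
        Net C (g C m^-2) lost from the active 0-30 cm column over the year.
        All oxidative loss is attributed to this disturbed, aerated layer.

    Returns
    -------
    (new_state, c_added, n_added)
        ``c_added`` / ``n_added`` (g m^-2) ride in with the deep soil mass
        that replaces the oxidized mass from below; for a profile with
        uniform C content the C replacement equals the C oxidized.

    Notes
    -----
    Soil mass lost ``m = annual_c_oxidized / c_frac(0-30)``; surface drop
    ``d = m / (bulk_density * 1e4) `` cm; the deep reservoir is debited by
    the same soil mass ``m``.  Spodosol profiles are a no-op.  Reservoir
    exhaustion raises ``RuntimeError`` -- at realistic oxidation rates the
    30-100 cm reservoir lasts far beyond a 15-year simulation.
    """
    if annual_c_oxidized < 0:
        raise ValueError("annual_c_oxidized must be >= 0")
    if profile.soil_type != "histosol" or annual_c_oxidized == 0.0:
        return state, 0.0, 0.0
    top = profile.top
    soil_mass_lost = annual_c_oxidized / top.c_frac  # g soil m^-2
    depth_loss_cm = soil_mass_lost / (top.bulk_density * 1e4)
    if soil_mass_lost > state.deep_reservoir_soil_mass:
        raise RuntimeError(
            "deep soil reservoir exhausted: subsidence has consumed the "
            "entire 30-100 cm profile"
        )
    frac = soil_mass_lost / state.deep_reservoir_soil_mass
    c_added = state.deep_reservoir_c * frac
    n_added = state.deep_reservoir_n * frac
    new_state = SubsidenceState(
        cumulative_depth_loss=state.cumulative_depth_loss + depth_loss_cm,
        deep_reservoir_soil_mass=state.deep_reservoir_soil_mass - soil_mass_lost,
        deep_reservoir_c=state.deep_reservoir_c - c_added,
        deep_reservoir_n=state.deep_reservoir_n - n_added,
        cumulative_c_added=state.cumulative_c_added + c_added,
        cumulative_n_added=state.cumulative_n_added + n_added,
    )
    return new_state, c_added, n_added


def profile_c_stock(
    profile: SoilProfile,
    top_cm: float = 0.0,
    bottom_cm: float = PROFILE_DEPTH_CM,
    som_c_0_30: float | None = None,
) -> float:
    """C stock (g C m^-2) over a depth window.

    By default the stock is integrated from layer composition
    (``c_frac * BD * thickness``).  When ``som_c_0_30`` is given it replaces
    the composition-based 0-30 cm contribution with the simulated SOM pool
    total, so a running simulation can report a live 0-100 cm stock.
    """
    if not 0.0 <= top_cm <= bottom_cm <= PROFILE_DEPTH_CM:
        raise ValueError("depth window must lie within 0-100 cm")
    stock = 0.0
    for layer in profile.layers:
        lo = max(layer.top_depth, top_cm)
        hi = min(layer.bottom_depth, bottom_cm)
        if hi > lo:
            stock += layer.c_frac * layer.bulk_density * (hi - lo) * 1e4
    if som_c_0_30 is not None:
        overlap = max(0.0, min(bottom_cm, ACTIVE_DEPTH_CM) - top_cm)
        if overlap > 0:
            # swap the measured 0-30 stock for the simulated one, pro-rated
            measured = 0.0
            for layer in profile.layers:
                lo = max(layer.top_depth, top_cm)
                hi = min(layer.bottom_depth, min(bottom_cm, ACTIVE_DEPTH_CM))
                if hi > lo:
                    measured += layer.c_frac * layer.bulk_density * (hi - lo) * 1e4
            stock += (som_c_0_30 * overlap / ACTIVE_DEPTH_CM) - measured
    return stock
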
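"""Synthetic daily weather generation and DayMet-style file I/O.

The simulator is driven by daily minimum/maximum air temperature (degC) and
precipitation (mm).  For the subtropical Florida study region no packaged
station record is shipped; instead a stochastic generator produces series
with the climate's first-order structure: smooth seasonal temperature cycles
with Gaussian day-to-day noise, and a Bernoulli wet/dry rainfall process with
exponentially distributed wet-day amounts scaled so that long-run monthly
totals converge to the climatological normals (wet season June-September,
roughly 1300 mm per year for Highlands County).
"""

from __future__ import annotations

import calendar
import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DailyWeather",
    "ClimateSpec",
    "florida_default_spec",
    "generate_weather",
    "generate_weather_arrays",
    "read_weather_file",
    "write_weather_file",
    "climate_summary",
]

_DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


@dataclass(frozen=True)
class DailyWeather:
    """One day's weather record.

    Attributes
    ----------
    date : datetime.date
    tmax, tmin : float
        Daily maximum / minimum air temperature, degC.  ``tmax >= tmin``.
    precip : float
        Precipitation depth, mm.  Non-negative.
    """

    date: _dt.date
    tmax: float
    tmin: float
    precip: float

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise ValueError(
                f"{self.date}: tmax ({self.tmax}) < tmin ({self.tmin})"
            )
        if self.precip < 0:
            raise ValueError(f"{self.date}: negative precip ({self.precip})")

    @property
    def tavg(self) -> float:
        return 0.5 * (self.tmax + self.tmin)


@dataclass
class ClimateSpec:
    """Monthly climate normals parameterizing the weather generator.

    All monthly fields hold 12 values, January first.  ``precip`` entries are
    monthly *totals* (mm); ``wet_prob`` is the probability that any given day
    of the month is wet; ``temp_sd`` is the day-to-day Gaussian noise applied
    to both temperature extremes (degC).
    """

    tmax: list[float]
    tmin: list[float]
    precip: list[float]
    wet_prob: list[float]
    temp_sd: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tmax", "tmin", "precip", "wet_prob"):
            vals = getattr(self, name)
            if len(vals) != 12:
                raise ValueError(f"{name} must have 12 monthly values")
        if any(not 0.0 <= p <= 1.0 for p in self.wet_prob):
            raise ValueError("wet_prob entries must be in [0, 1]")
        if any(p < 0 for p in self.precip):
            raise ValueError("monthly precip totals must be >= 0")
        if self.temp_sd < 0:
            raise ValueError("temp_sd must be >= 0")
        if any(a < b for a, b in zip(self.tmax, self.tmin)):
            raise ValueError("monthly mean tmax must be >= tmin")


def florida_default_spec(seed: int = 0) -> ClimateSpec:
    """Climate normals for south-central Florida (Highlands County).

    Subtropical, with a June-September wet season; annual precipitation
    sums to ~1300 mm, matching the regional mean.
    """
    return ClimateSpec(
        tmax=[22.8, 24.1, 26.4, 29.1, 31.6, 32.8, 33.2, 33.2, 32.3, 29.7, 26.3, 23.4],
        tmin=[9.9, 11.3, 13.9, 16.6, 19.9, 22.4, 23.2, 23.3, 22.5, 19.2, 14.9, 11.2],
        precip=[55.0, 60.0, 75.0, 65.0, 95.0, 215.0, 200.0, 210.0, 175.0, 65.0, 45.0, 40.0],
        wet_prob=[0.20, 0.20, 0.20, 0.20, 0.30, 0.55, 0.55, 0.55, 0.50, 0.25, 0.20, 0.20],
        temp_sd=2.5,
        seed=seed,
    )


def _interp_monthly(series: list[float], dates: pd.DatetimeIndex) -> np.ndarray:
    """Linear interpolation of monthly means between month midpoints.

    Avoids step discontinuities at month boundaries; wraps across years.
    """
    doy = dates.dayofyear.to_numpy(dtype=float)
    # month midpoints in day-of-year coordinates (non-leap reference)
    starts = np.concatenate(([0], np.cumsum(_DAYS_IN_MONTH)))[:12]
    mids = starts + _DAYS_IN_MONTH / 2.0
    xp = np.concatenate(([mids[-1] - 365.0], mids, [mids[0] + 365.0]))
    fp = np.concatenate(([series[-1]], series, [series[0]]))
    return np.interp(doy, xp, fp)


def generate_weather_arrays(spec: ClimateSpec, start_year: int, n_years: int):
    """Array form of :func:`generate_weather` used by the simulation engine.

    Returns ``(dates, tmax, tmin, precip)`` with ``dates`` a pandas
    DatetimeIndex and the rest float arrays.  Bit-identical to the record
    form for the same spec.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(spec.seed)
    dates = pd.date_range(
        start=f"{start_year}-01-01", end=f"{start_year + n_years - 1}-12-31", freq="D"
    )
    month = dates.month.to_numpy() - 1
    tmax_clim = _interp_monthly(spec.tmax, dates)
    tmin_clim = _interp_monthly(spec.tmin, dates)
    anomaly = rng.normal(0.0, spec.temp_sd, size=len(dates))
    tmax = tmax_clim + anomaly
    tmin = tmin_clim + anomaly
    # rainfall: expected monthly total = p_wet * n_days * mean_amount
    p_wet = np.asarray(spec.wet_prob)[month]
    ndays = _DAYS_IN_MONTH[month]
    monthly_total = np.asarray(spec.precip)[month]
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_amount = np.where(
            p_wet > 0, monthly_total / (ndays * np.maximum(p_wet, 1e-12)), 0.0
        )
    wet = rng.random(len(dates)) < p_wet
    deterministic = (spec.temp_sd == 0.0) and np.all(
        (np.asarray(spec.wet_prob) == 0) | (np.asarray(spec.wet_prob) == 1)
    )
    if deterministic:
        amounts = mean_amount
    else:
        amounts = rng.exponential(1.0, size=len(dates)) * mean_amount
    precip = np.where(wet, amounts, 0.0)
    return dates, tmax, tmin, precip


def generate_weather(
    spec: ClimateSpec, start_year: int, n_years: int
) -> list[DailyWeather]:
    """Generate ``n_years`` of daily weather starting January 1 of ``start_year``.

    The same spec (including its seed) always yields the identical series.
    Rainfall is a per-day Bernoulli wet/dry draw with exponential wet-day
    amounts whose mean is scaled so the expected monthly total equals the
    spec's normal.  Temperatures are interpolated monthly means plus Gaussian
    noise (a shared daily anomaly, preserving ``tmax >= tmin``).
    """
    dates, tmax, tmin, precip = generate_weather_arrays(spec, start_year, n_years)
    return [
        DailyWeather(d.date(), float(tx), float(tn), float(pr))
        for d, tx, tn, pr in zip(dates, tmax, tmin, precip)
    ]


def write_weather_file(series: list[DailyWeather], path) -> None:
    """Write a 7-column whitespace text file: day month year doy tmax tmin precip."""
    with open(path, "w") as fh:
        fh.write("# day month year doy tmax_degC tmin_degC precip_mm\n")
        for rec in series:
            doy = rec.date.timetuple().tm_yday
            fh.write(
                f"{rec.date.day} {rec.date.month} {rec.date.year} {doy} "
                f"{rec.tmax!r} {rec.tmin!r} {rec.precip!r}\n"
            )


def read_weather_file(path) -> list[DailyWeather]:
    """Read the 7-column weather dialect written by :func:`write_weather_file`.

    One leading header line (starting with ``#`` or non-numeric) is permitted
    and skipped.  Invariant violations (tmax < tmin, negative precipitation,
    date gaps) are reported with the offending line number.
    """
    records: list[DailyWeather] = []
    prev: _dt.date | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                continue
            parts = line.split()
            if lineno == 1:
                try:
                    float(parts[0])
                except ValueError:
                    continue  # header line
            if len(parts) < 7:
                raise ValueError(f"line {lineno}: expected 7 columns, got {len(parts)}")
            day, month, year = int(parts[0]), int(parts[1]), int(parts[2])
            tmax, tmin, precip = float(parts[4]), float(parts[5]), float(parts[6])
            try:
                date = _dt.date(year, month, day)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
            if tmax < tmin:
                raise ValueError(f"line {lineno}: tmax {tmax} < tmin {tmin}")
            if precip < 0:
                raise ValueError(f"line {lineno}: negative precip {precip}")
            if prev is not None and (date - prev).days != 1:
                raise ValueError(f"line {lineno}: date gap ({prev} -> {date})")
            records.append(DailyWeather(date, tmax, tmin, precip))
            prev = date
    return records


def climate_summary(series: list[DailyWeather]) -> pd.DataFrame:
    """Annual climate summary: mean tmax/tmin (degC) and total precip (mm).

    One row per complete calendar year; partial years are excluded (a warning
    is logged).  Raises on an empty series.
    """
    if not series:
        raise ValueError("empty weather series")
    df = pd.DataFrame(
        {
            "year": [r.date.year for r in series],
            "date": [r.date for r in series],
            "tmax": [r.tmax for r in series],
            "tmin": [r.tmin for r in series],
            "precip": [r.precip for r in series],
        }
    )
    rows = []
    for year, grp in df.groupby("year"):
        expected = 366 if calendar.isleap(int(year)) else 365
        if len(grp) != expected:
            import logging

            logging.getLogger(__name__).warning(
                "excluding partial year %s (%d of %d days)", year, len(grp), expected
            )
            continue
        rows.append(
            {
                "year": int(year),
                "tmax_mean": grp["tmax"].mean(),
                "tmin_mean": grp["tmin"].mean(),
                "precip_total": grp["precip"].sum(),
            }
        )
    if not rows:
        raise ValueError("no complete calendar year in series")
    return pd.DataFrame(rows)
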
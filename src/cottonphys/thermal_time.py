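"""Thermal time (growing degree days) from daily weather.

Cotton growth stage is tracked by accumulated growing degree days (GDD):
the daily mean of capped maximum and minimum air temperature above a crop
base temperature, summed from planting. For cotton the base temperature is
15.6 °C and the maximum temperature is capped at 33.9 °C; days whose capped
mean falls below the base contribute zero.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from cottonphys.exceptions import InvalidWeatherError, WeatherGapError

#: Cotton base temperature (°C) below which development is assumed to stop.
BASE_TEMP_C = 15.6
#: Upper cap (°C) applied to the daily maximum temperature.
CEILING_TEMP_C = 33.9


@dataclass(frozen=True)
class WeatherDay:
    """One day of weather: temperatures in °C, solar radiation in MJ m⁻² d⁻¹."""

    date: dt.date
    tmax: float
    tmin: float
    solar: float

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise InvalidWeatherError(
                f"{self.date}: tmax ({self.tmax}) < tmin ({self.tmin})"
            )
        if self.solar < 0:
            raise InvalidWeatherError(f"{self.date}: negative solar radiation")


@dataclass(frozen=True)
class ThermalTimeSeries:
    """Daily and cumulative GDD from planting, inclusive of both endpoints."""

    planting_date: dt.date
    dates: tuple[dt.date, ...]
    daily: tuple[float, ...]
    cumulative: tuple[float, ...]
    _index: dict[dt.date, int] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {d: i for i, d in enumerate(self.dates)}
        )

    def gdd_at(self, date: dt.date) -> float:
        """Cumulative GDD from planting through ``date`` (inclusive)."""
        try:
            return self.cumulative[self._index[date]]
        except KeyError:
            raise WeatherGapError(f"no thermal-time entry for {date}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.dates, "daily_gdd": self.daily, "cumulative_gdd": self.cumulative}
        )


def daily_gdd(
    tmax: float,
    tmin: float,
    base: float = BASE_TEMP_C,
    ceiling: float = CEILING_TEMP_C,
) -> float:
    """Growing degree days contributed by a single day (°C·d).

    ``max(0, (min(tmax, ceiling) + tmin) / 2 - base)``. Only the maximum
    temperature is capped; the clamp at zero is applied per day.
    """
    if tmax < tmin:
        raise InvalidWeatherError(f"tmax ({tmax}) < tmin ({tmin})")
    capped = min(tmax, ceiling)
    return max(0.0, (capped + tmin) / 2.0 - base)


def _weather_map(weather: Iterable[WeatherDay]) -> dict[dt.date, WeatherDay]:
    return {w.date: w for w in weather}


def accumulate_gdd(
    weather: Sequence[WeatherDay],
    planting_date: dt.date,
    until_date: dt.date,
    base: float = BASE_TEMP_C,
    ceiling: float = CEILING_TEMP_C,
) -> ThermalTimeSeries:
    """Accumulate daily GDD from planting through ``until_date`` inclusive.

    Raises :class:`WeatherGapError` naming the first missing date if the
    weather table does not cover every day of the range.
    """
    if until_date < planting_date:
        raise InvalidWeatherError(
            f"until_date {until_date} precedes planting {planting_date}"
        )
    by_date = _weather_map(weather)
    dates: list[dt.date] = []
    daily: list[float] = []
    cumulative: list[float] = []
    total = 0.0
    day = planting_date
    while day <= until_date:
        if day not in by_date:
            raise WeatherGapError(f"weather table has no entry for {day}")
        w = by_date[day]
        g = daily_gdd(w.tmax, w.tmin, base=base, ceiling=ceiling)
        total += g
        dates.append(day)
        daily.append(g)
        cumulative.append(total)
        day += dt.timedelta(days=1)
    return ThermalTimeSeries(
        planting_date=planting_date,
        dates=tuple(dates),
        daily=tuple(daily),
        cumulative=tuple(cumulative),
    )


def read_weather_csv(path) -> list[WeatherDay]:
    """Read a weather table: columns date, tmax_c, tmin_c, solar_mj_m2."""
    df = pd.read_csv(path)
    required = {"date", "tmax_c", "tmin_c", "solar_mj_m2"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidWeatherError(f"weather CSV missing columns: {sorted(missing)}")
    return [
        WeatherDay(
            date=dt.date.fromisoformat(str(r.date)),
            tmax=float(r.tmax_c),
            tmin=float(r.tmin_c),
            solar=float(r.solar_mj_m2),
        )
        for r in df.itertuples()
    ]


def write_weather_csv(weather: Sequence[WeatherDay], path) -> None:
    pd.DataFrame(
        {
            "date": [w.date.isoformat() for w in weather],
            "tmax_c": [w.tmax for w in weather],
            "tmin_c": [w.tmin for w in weather],
            "solar_mj_m2": [w.solar for w in weather],
        }
    ).to_csv(path, index=False)
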
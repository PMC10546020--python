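"""Radiation budget: light interception, cumulative PAR, RUE, harvest index.

The fraction of intercepted photosynthetically active radiation is
IPAR_f = (PAR_above − PAR_below) / PAR_above, measured with above- and
below-canopy sensors. Cumulative incident PAR from planting to a sampling
date takes PAR as 45% of total solar radiation; cumulative IPAR is
IPAR_f × cumulative incident PAR. Radiation use efficiency between the
first sampling date (reference) and date n is
RUE_n = Δ biomass / Δ cumulative IPAR (g MJ⁻¹). Measured harvest index is
lint yield over the season-maximum above-ground dry biomass, both in
kg ha⁻¹ (biomass in g m⁻² is converted with the factor 10).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Sequence

from cottonphys.exceptions import DegenerateInputError, InvalidReadingError
from cottonphys.indices import VIRecord
from cottonphys.thermal_time import WeatherDay, WeatherGapError

logger = logging.getLogger(__name__)

#: PAR as a fraction of total solar radiation.
PAR_FRACTION = 0.45

#: Conversion factor g m⁻² → kg ha⁻¹.
G_M2_TO_KG_HA = 10.0

#: Open-interval clamp for IPAR_f so beta-family likelihoods stay finite.
IPAR_EPS = 1e-6


@dataclass
class PlotObservation:
    """One plot × date record joining physiology and imagery predictors."""

    plot_id: str
    date: dt.date
    gdd: float
    ipar_f: float
    cum_par: float
    cum_ipar: float
    biomass: float
    rue: float | None = None
    vis: VIRecord | None = None


@dataclass(frozen=True)
class SeasonSummary:
    """Season-level aggregates for one plot."""

    plot_id: str
    max_biomass_kg_ha: float
    lint_yield_kg_ha: float
    hi: float


def ipar_fraction(par_above: float, par_below: float, eps: float = IPAR_EPS) -> float:
    """Fraction of intercepted PAR, clamped to the open interval (0, 1).

    The clamp (ε = 1e-6 by default) keeps the value strictly inside (0, 1)
    for beta-distribution modeling. Readings with par_below > par_above
    (sensor noise) are clamped up to ε with a warning.
    """
    if par_above <= 0:
        raise InvalidReadingError(f"par_above must be positive, got {par_above}")
    if par_below < 0:
        raise InvalidReadingError(f"par_below must be non-negative, got {par_below}")
    f = (par_above - par_below) / par_above
    if f < 0:
        logger.warning(
            "par_below (%s) exceeds par_above (%s); clamping IPAR_f to eps",
            par_below, par_above,
        )
    return min(max(f, eps), 1.0 - eps)


def cumulative_incident_par(
    weather: Sequence[WeatherDay],
    planting_date: dt.date,
    date: dt.date,
    par_fraction: float = PAR_FRACTION,
) -> float:
    """Cumulative incident PAR (MJ m⁻²) from planting through ``date``."""
    by_date = {w.date: w for w in weather}
    total = 0.0
    day = planting_date
    while day <= date:
        if day not in by_date:
            raise WeatherGapError(f"weather table has no entry for {day}")
        total += by_date[day].solar * par_fraction
        day += dt.timedelta(days=1)
    return total


def cumulative_ipar(ipar_f: float, cum_par: float) -> float:
    """Cumulative intercepted PAR: IPAR_f × cumulative incident PAR."""
    if not 0.0 <= ipar_f <= 1.0:
        raise InvalidReadingError(f"ipar_f must lie in [0, 1], got {ipar_f}")
    return ipar_f * cum_par


def rue_series(
    biomass: Sequence[float], cum_ipar: Sequence[float]
) -> list[float | None]:
    """Per-date RUE (g MJ⁻¹) referenced to the first sampling date.

    Entry 0 (the reference date) is ``None``; entry n is
    (biomass_n − biomass_1) / (cum_ipar_n − cum_ipar_1). The series must
    have at least two dates with strictly increasing cumulative IPAR.
    """
    if len(biomass) != len(cum_ipar):
        raise DegenerateInputError("biomass and cum_ipar series differ in length")
    if len(biomass) < 2:
        raise DegenerateInputError("RUE needs at least two sampling dates")
    out: list[float | None] = [None]
    for n in range(1, len(biomass)):
        denom = cum_ipar[n] - cum_ipar[0]
        if denom <= 0:
            raise DegenerateInputError(
                f"cumulative IPAR not increasing at index {n} "
                f"({cum_ipar[n]} vs reference {cum_ipar[0]})"
            )
        out.append((biomass[n] - biomass[0]) / denom)
    return out


def measured_hi(
    lint_yield_kg_ha: float, biomass_series_g_m2: Sequence[float]
) -> float:
    """Harvest index: lint yield over season-maximum biomass (both kg ha⁻¹)."""
    if lint_yield_kg_ha < 0:
        raise InvalidReadingError(f"negative lint yield: {lint_yield_kg_ha}")
    if len(biomass_series_g_m2) == 0:
        raise DegenerateInputError("empty biomass series")
    max_biomass = max(biomass_series_g_m2) * G_M2_TO_KG_HA
    if max_biomass <= 0:
        raise DegenerateInputError("season-maximum biomass is zero")
    return lint_yield_kg_ha / max_biomass
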
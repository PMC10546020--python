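"""Vegetation indices from per-plot mean band reflectance.

Twenty standard multispectral vegetation indices plus the five raw band
means serve as candidate predictors of cotton light interception, biomass
and radiation use efficiency. All formulas operate on reflectance (0–1).

Division by zero yields ``nan`` (an explicit undefined marker that
propagates; rows carrying it are dropped, with a logged count, before any
model fitting — never silently replaced by 0).

Two indices are implemented in a non-classical printed form used by the
source tables this package mirrors and flagged here:

* ``EVI`` uses the numerator ``2.5·NIR − R`` (the classical form
  ``2.5·(NIR − R)`` is available as ``EVI_classic``).
* ``RGBVI`` uses ``(G − B·R) / (G² + B·R)`` (products, not squares, of
  B and R; the classical squared form is available as ``RGBVI_classic``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

import datetime as dt

from cottonphys.exceptions import ConfigError
from cottonphys.segmentation import BandMeans

NAN = float("nan")


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else NAN


def _ndvi(b, g, r, re, nir):
    return _safe_div(nir - r, nir + r)


def _gndvi(b, g, r, re, nir):
    return _safe_div(nir - g, nir + g)


def _ndre(b, g, r, re, nir):
    return _safe_div(nir - re, nir + re)


def _exg(b, g, r, re, nir):
    return 2.0 * g - r - b


def _rvi(b, g, r, re, nir):
    return _safe_div(nir, r)


def _sccci(b, g, r, re, nir):
    ndvi = _ndvi(b, g, r, re, nir)
    ndre = _ndre(b, g, r, re, nir)
    if math.isnan(ndvi) or math.isnan(ndre) or ndvi == 0:
        return NAN
    return ndre / ndvi


def _savi(b, g, r, re, nir):
    return 1.5 * _safe_div(nir - r, nir + r + 0.5)


def _evi(b, g, r, re, nir):
    return _safe_div(2.5 * nir - r, nir + 6.0 * r - 7.5 * b + 1.0)


def _evi_classic(b, g, r, re, nir):
    return _safe_div(2.5 * (nir - r), nir + 6.0 * r - 7.5 * b + 1.0)


def _evi2(b, g, r, re, nir):
    return _safe_div(2.5 * nir - r, nir + 2.5 * r + 1.0)


def _msavi(b, g, r, re, nir):
    disc = (2.0 * nir + 1.0) ** 2 - 8.0 * (nir - r)
    if disc < 0:
        return NAN
    return ((2.0 * nir + 1.0) - math.sqrt(disc)) / 2.0


def _vari(b, g, r, re, nir):
    return _safe_div(g - r, g + r - b)


def _wdrvi(b, g, r, re, nir):
    return _safe_div(0.2 * nir - r, 0.2 * nir + r)


def _reci(b, g, r, re, nir):
    return _safe_div(nir, re) - 1.0 if re != 0 else NAN


def _re_r(b, g, r, re, nir):
    return _safe_div(re, r)


def _nir_g(b, g, r, re, nir):
    return _safe_div(nir, g)


def _rgbvi(b, g, r, re, nir):
    return _safe_div(g - b * r, g * g + b * r)


def _rgbvi_classic(b, g, r, re, nir):
    return _safe_div(g * g - b * r, g * g + b * r)


def _grvi(b, g, r, re, nir):
    return _safe_div(g - r, g + r)


def _tcari(b, g, r, re, nir):
    if r == 0:
        return NAN
    return 3.0 * ((re - r) - 0.2 * (re - g) * (re / r))


def _osavi(b, g, r, re, nir):
    return 1.16 * _safe_div(nir - r, nir + r + 0.16)


def _tcari_osavi(b, g, r, re, nir):
    t = _tcari(b, g, r, re, nir)
    o = _osavi(b, g, r, re, nir)
    if math.isnan(t) or math.isnan(o) or o == 0:
        return NAN
    return t / o


_FORMULAS: dict[str, Callable[[float, float, float, float, float], float]] = {
    "ExG": _exg,
    "NDVI": _ndvi,
    "GNDVI": _gndvi,
    "NDRE": _ndre,
    "RVI": _rvi,
    "SCCCI": _sccci,
    "SAVI": _savi,
    "EVI": _evi,
    "EVI2": _evi2,
    "MSAVI": _msavi,
    "VARI": _vari,
    "WDRVI": _wdrvi,
    "RECI": _reci,
    "RE/R": _re_r,
    "NIR/G": _nir_g,
    "RGBVI": _rgbvi,
    "GRVI": _grvi,
    "TCARI": _tcari,
    "OSAVI": _osavi,
    "TCARI/OSAVI": _tcari_osavi,
    # Sensitivity variants — not part of the default predictor set.
    "EVI_classic": _evi_classic,
    "RGBVI_classic": _rgbvi_classic,
    # Raw band means as predictors in their own right.
    "BLUE": lambda b, g, r, re, nir: b,
    "GREEN": lambda b, g, r, re, nir: g,
    "RED": lambda b, g, r, re, nir: r,
    "REDEDGE": lambda b, g, r, re, nir: re,
    "NIR": lambda b, g, r, re, nir: nir,
}

#: The 20 vegetation indices.
VI_NAMES: tuple[str, ...] = (
    "ExG", "NDVI", "GNDVI", "NDRE", "RVI", "SCCCI", "SAVI", "EVI", "EVI2",
    "MSAVI", "VARI", "WDRVI", "RECI", "RE/R", "NIR/G", "RGBVI", "GRVI",
    "TCARI", "OSAVI", "TCARI/OSAVI",
)

#: The 25 candidate model predictors: 20 indices plus the 5 raw bands.
PREDICTOR_NAMES: tuple[str, ...] = VI_NAMES + (
    "BLUE", "GREEN", "RED", "REDEDGE", "NIR",
)


@dataclass(frozen=True)
class VIRecord:
    """All candidate predictor values for one plot × date."""

    plot_id: str
    date: dt.date | None
    values: dict[str, float]


def _band_tuple(bands: BandMeans | Mapping[str, float]) -> tuple[float, ...]:
    means = bands.means if isinstance(bands, BandMeans) else bands
    try:
        return tuple(
            float(means[k]) for k in ("blue", "green", "red", "rededge", "nir")
        )
    except KeyError as exc:
        raise ConfigError(f"band means missing band {exc}") from None


def compute_vi(bands: BandMeans | Mapping[str, float], name: str) -> float:
    """Evaluate one index by name on a set of band means."""
    if name not in _FORMULAS:
        raise ConfigError(f"unknown vegetation index: {name!r}")
    b, g, r, re, nir = _band_tuple(bands)
    return float(_FORMULAS[name](b, g, r, re, nir))


def compute_all(bands: BandMeans) -> VIRecord:
    """All 20 indices plus raw band means for one plot × date."""
    values = {name: compute_vi(bands, name) for name in PREDICTOR_NAMES}
    return VIRecord(plot_id=bands.plot_id, date=bands.date, values=values)
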
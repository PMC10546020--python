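"""Synthetic UAV plot-trial generator.

Emulates a nitrogen-rate cotton trial — a randomized complete block design
with 5 N rates × 5 blocks, sampled ~5 times per season — with exactly the
statistical structure the downstream analysis assumes:

* weather: seasonal sinusoids with gaussian day-to-day noise;
* canopy cover: logistic in thermal time, with an N-responsive asymptote;
* plot rasters: row-structured Bernoulli mixing of soil and canopy
  endmember spectra with band noise (the canopy red endmember decreases
  with N rate, a chlorophyll proxy, so reflectance carries the treatment
  signal the models rely on);
* IPAR_f: beta-distributed with logit mean linear in (VI, GDD, VI·GDD);
* biomass: gamma-distributed with log mean linear in the same terms;
* lint yield: true HI × season-maximum true biomass, HI ~ truncated normal;
* harvest RGB: soil background, defoliated-vegetation blobs, and white
  boll disks whose count is Poisson in true yield; the painted white-area
  fraction inside the ROI is recorded as the true CFI.

Everything is deterministic given the config seed: the root seed is split
into named substreams (weather, cover, rasters, physiology, harvest), and
plots and dates are always traversed in a fixed order.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special
from skimage.draw import disk as draw_disk

from cottonphys.exceptions import ConfigError
from cottonphys.radiation import IPAR_EPS, G_M2_TO_KG_HA, cumulative_incident_par
from cottonphys.segmentation import BAND_NAMES, MultispectralRaster, ROIPolygon
from cottonphys.thermal_time import WeatherDay, accumulate_gdd


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study. Defaults are the study conditions."""

    seed: int = 0
    n_blocks: int = 5
    n_rates: tuple[float, ...] = (0.0, 44.0, 89.0, 135.0, 179.0)  # kg N ha⁻¹
    n_dates: int = 5
    season_length_days: int = 150
    planting_date: dt.date = dt.date(2022, 4, 26)
    first_sampling_day: int = 40  # days after planting
    last_sampling_day: int = 140
    season: str = "synthetic-2022"

    # raster rendering
    plot_shape: tuple[int, int] = (120, 40)  # (rows, cols), multispectral
    soil_endmember: tuple[float, ...] = (0.08, 0.12, 0.16, 0.20, 0.24)
    canopy_endmember: tuple[float, ...] = (0.03, 0.08, 0.05, 0.25, 0.45)
    red_n_span: float = 0.02  # canopy red drops by this × rate/max(rate)
    band_noise_sd: float = 0.01
    n_crop_rows: int = 4
    row_sd_px: float = 3.0

    # canopy growth (logistic in GDD)
    c_base: float = 0.55
    c_span: float = 0.40
    k_g: float = 0.006  # per °C·d
    g_mid: float = 700.0  # °C·d

    # generative physiology
    beta_ipar: tuple[float, ...] = (-3.0, 2.5, 0.002, 0.0005)
    phi_beta: float = 60.0
    beta_biomass: tuple[float, ...] = (0.8, 2.4, 0.0011, 0.0009)
    alpha_gamma: float = 25.0
    hi_mean: float = 0.4
    hi_sd: float = 0.03
    hi_bounds: tuple[float, float] = (0.2, 0.6)
    par_above: float = 2000.0  # µmol m⁻² s⁻¹, constant synthetic reading

    # weather noise scale (0 → smooth sinusoids)
    weather_noise: float = 1.0

    # harvest RGB rendering (finer resolution than the multispectral plots)
    harvest_shape: tuple[int, int] = (240, 80)
    boll_per_kg_ha: float = 0.05
    boll_radius_px: tuple[int, int] = (2, 4)
    boll_intensity: tuple[float, float] = (235.0, 8.0)  # mean, sd
    soil_intensity: tuple[float, float] = (100.0, 10.0)
    veg_intensity: tuple[float, float] = (130.0, 10.0)
    n_veg_blobs: int = 20

    def __post_init__(self) -> None:
        if self.phi_beta <= 0 or self.alpha_gamma <= 0 or self.band_noise_sd < 0:
            raise ConfigError("dispersion/noise parameters must be positive")
        if not 0 < self.c_base + self.c_span <= 1:
            raise ConfigError("canopy cover asymptote must lie in (0, 1]")
        if len(self.beta_ipar) != 4 or len(self.beta_biomass) != 4:
            raise ConfigError("generative coefficient vectors must have 4 terms")

    def noiseless(self) -> "SimConfig":
        """A copy with observation noise effectively switched off."""
        return replace(
            self,
            band_noise_sd=0.0,
            phi_beta=1e6,
            alpha_gamma=1e6,
            weather_noise=0.0,
            hi_sd=0.0,
        )


@dataclass(frozen=True)
class PlotInfo:
    plot_id: str
    block: int
    n_rate: float


@dataclass
class StudyBundle:
    """Everything one synthetic season produces, in memory."""

    config: SimConfig
    weather: list[WeatherDay]
    sampling_dates: list[dt.date]
    plots: list[PlotInfo]
    rois: dict[str, ROIPolygon]
    harvest_rois: dict[str, ROIPolygon]
    rasters: dict[tuple[str, dt.date], MultispectralRaster]
    harvest_images: dict[str, np.ndarray]
    observations: pd.DataFrame  # the "ground-measurement" table
    truth: pd.DataFrame  # per plot × date generative state
    plot_truth: pd.DataFrame  # per plot season-level truth
    thermal: object = field(default=None, repr=False)


def simulate_weather(
    n_days: int,
    seed: int,
    start_date: dt.date = dt.date(2022, 4, 26),
    noise_scale: float = 1.0,
) -> list[WeatherDay]:
    """Seasonal sinusoid weather with gaussian noise; deterministic per seed."""
    if n_days < 1:
        raise ConfigError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.arange(n_days)
    phase = np.pi * t / max(n_days - 1, 1)
    tmax = 32.0 + 4.0 * np.sin(phase) + rng.normal(0.0, 2.0 * noise_scale, n_days)
    tmin = tmax - 10.0 + rng.normal(0.0, 1.5 * noise_scale, n_days)
    tmin = np.minimum(tmin, tmax)
    solar = 18.0 + 6.0 * np.sin(phase) + rng.normal(0.0, 3.0 * noise_scale, n_days)
    solar = np.maximum(solar, 2.0)
    return [
        WeatherDay(
            date=start_date + dt.timedelta(days=int(i)),
            tmax=float(tmax[i]),
            tmin=float(tmin[i]),
            solar=float(solar[i]),
        )
        for i in t
    ]


def simulate_canopy(gdd: float, n_rate: float, config: SimConfig) -> float:
    """Logistic canopy cover in thermal time with an N-responsive asymptote."""
    if gdd < 0:
        raise ConfigError("gdd must be non-negative")
    c_max = config.c_base + config.c_span * n_rate / max(config.n_rates)
    return c_max / (1.0 + math.exp(-config.k_g * (gdd - config.g_mid)))


def canopy_endmember_for_rate(n_rate: float, config: SimConfig) -> np.ndarray:
    """Canopy spectrum; red reflectance falls with N rate (chlorophyll proxy)."""
    em = np.array(config.canopy_endmember, dtype=float)
    em[2] -= config.red_n_span * n_rate / max(config.n_rates)
    return em


def true_vi(n_rate: float, config: SimConfig) -> float:
    """NDVI of the plot's (noiseless) canopy endmember — the generative VI."""
    em = canopy_endmember_for_rate(n_rate, config)
    nir, r = em[4], em[2]
    return (nir - r) / (nir + r)


def _row_cover_probability(cover: float, config: SimConfig) -> np.ndarray:
    """Per-column canopy probability with crop-row structure, mean = cover."""
    h, w = config.plot_shape
    cols = np.arange(w) + 0.5
    centers = (np.arange(config.n_crop_rows) + 0.5) * w / config.n_crop_rows
    weight = np.zeros(w)
    for c in centers:
        weight += np.exp(-0.5 * ((cols - c) / config.row_sd_px) ** 2)
    if cover <= 0:
        return np.zeros(w)
    if cover >= 1:
        return np.ones(w)
    # scale the row profile so the clipped mean equals the target cover
    lo, hi = 0.0, 1.0
    while np.mean(np.clip(hi * weight, 0, 1)) < cover:
        hi *= 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if np.mean(np.clip(mid * weight, 0, 1)) < cover:
            lo = mid
        else:
            hi = mid
    return np.clip(0.5 * (lo + hi) * weight, 0, 1)


def render_plot_raster(
    canopy_cover: float,
    config: SimConfig,
    seed_or_rng,
    n_rate: float = 0.0,
) -> tuple[MultispectralRaster, np.ndarray]:
    """Render one plot as a soil/canopy Bernoulli mixture.

    Returns the raster and the true canopy mask used to paint it.
    """
    if not 0.0 <= canopy_cover <= 1.0:
        raise ConfigError("canopy_cover must lie in [0, 1]")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    h, w = config.plot_shape
    p = _row_cover_probability(canopy_cover, config)
    is_canopy = rng.random((h, w)) < p[None, :]
    soil = np.array(config.soil_endmember, dtype=float)
    canopy = canopy_endmember_for_rate(n_rate, config)
    stack = np.empty((len(BAND_NAMES), h, w))
    for i in range(len(BAND_NAMES)):
        base = np.where(is_canopy, canopy[i], soil[i])
        if config.band_noise_sd > 0:
            base = base + rng.normal(0.0, config.band_noise_sd, (h, w))
        stack[i] = base
    return MultispectralRaster.from_stack(stack), is_canopy


def middle_rows_roi(plot_id: str, shape: tuple[int, int], config: SimConfig) -> ROIPolygon:
    """ROI polygon covering the middle two crop rows, with a margin."""
    h, w = shape
    quarter = w / config.n_crop_rows
    x0, x1 = quarter, w - quarter
    y0, y1 = h * 0.05, h * 0.95
    return ROIPolygon.from_vertices(plot_id, [(x0, y0), (x1, y0), (x1, y1), (x0, y1)])


def simulate_ground_truth(
    vi: np.ndarray,
    gdd: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw IPAR_f and biomass observations from the generative GLMs.

    μ_ipar = expit(β·(1, VI, GDD, VI·GDD)); IPAR_f ~ Beta(μφ, (1−μ)φ).
    μ_bio = exp(β·terms); biomass ~ Gamma(shape α, mean μ_bio).
    """
    vi = np.asarray(vi, dtype=float)
    gdd = np.asarray(gdd, dtype=float)
    X = np.column_stack([np.ones(vi.size), vi, gdd, vi * gdd])
    mu_ipar = special.expit(X @ np.asarray(config.beta_ipar))
    ipar_obs = rng.beta(mu_ipar * config.phi_beta, (1.0 - mu_ipar) * config.phi_beta)
    ipar_obs = np.clip(ipar_obs, IPAR_EPS, 1.0 - IPAR_EPS)
    mu_bio = np.exp(X @ np.asarray(config.beta_biomass))
    bio_obs = rng.gamma(config.alpha_gamma, mu_bio / config.alpha_gamma)
    return pd.DataFrame(
        {
            "vi_true": vi,
            "gdd": gdd,
            "ipar_f_true": mu_ipar,
            "ipar_f_obs": ipar_obs,
            "biomass_true": mu_bio,
            "biomass_obs": bio_obs,
        }
    )


def _draw_truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, bounds: tuple[float, float]
) -> float:
    if sd == 0:
        return float(np.clip(mean, *bounds))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if bounds[0] < x < bounds[1]:
            return float(x)
    return float(np.clip(mean, *bounds))


def render_harvest_rgb(
    lint_yield_true: float,
    config: SimConfig,
    seed_or_rng,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a pre-harvest RGB plot image.

    Returns (uint8 RGB image, boolean mask of painted boll pixels).
    Boll count ~ Poisson(boll_per_kg_ha × yield).
    """
    if lint_yield_true < 0:
        raise ConfigError("lint yield must be non-negative")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    h, w = config.harvest_shape
    img = rng.normal(config.soil_intensity[0], config.soil_intensity[1], (h, w, 3))
    # defoliated-vegetation blobs
    for _ in range(config.n_veg_blobs):
        r0, c0 = rng.uniform(0, h), rng.uniform(0, w)
        radius = rng.uniform(3, 8)
        rr, cc = draw_disk((r0, c0), radius, shape=(h, w))
        level = rng.normal(config.veg_intensity[0], config.veg_intensity[1])
        img[rr, cc, :] = level + rng.normal(0, 3, (rr.size, 3))
    # white boll disks
    boll_mask = np.zeros((h, w), dtype=bool)
    n_bolls = int(rng.poisson(config.boll_per_kg_ha * lint_yield_true))
    lo_r, hi_r = config.boll_radius_px
    for _ in range(n_bolls):
        r0, c0 = rng.uniform(0, h), rng.uniform(0, w)
        radius = int(rng.integers(lo_r, hi_r + 1))
        rr, cc = draw_disk((r0, c0), radius, shape=(h, w))
        level = min(255.0, rng.normal(config.boll_intensity[0], config.boll_intensity[1]))
        img[rr, cc, :] = level
        boll_mask[rr, cc] = True
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), boll_mask


def _sampling_dates(config: SimConfig) -> list[dt.date]:
    days = np.linspace(
        config.first_sampling_day, config.last_sampling_day, config.n_dates
    )
    return [config.planting_date + dt.timedelta(days=int(round(d))) for d in days]


def generate_study(config: SimConfig) -> StudyBundle:
    """Generate a complete deterministic synthetic season."""
    root = np.random.SeedSequence(config.seed)
    seeds = root.spawn(4)
    weather_seed = int(seeds[0].generate_state(1)[0] % (2**31))
    rng_raster = np.random.default_rng(seeds[1])
    rng_phys = np.random.default_rng(seeds[2])
    rng_harvest = np.random.default_rng(seeds[3])

    weather = simulate_weather(
        config.season_length_days,
        weather_seed,
        start_date=config.planting_date,
        noise_scale=config.weather_noise,
    )
    harvest_date = weather[-1].date
    thermal = accumulate_gdd(weather, config.planting_date, harvest_date)
    sampling_dates = _sampling_dates(config)

    plots = [
        PlotInfo(plot_id=f"B{b + 1}N{int(rate)}", block=b + 1, n_rate=rate)
        for b in range(config.n_blocks)
        for rate in config.n_rates
    ]

    rois = {
        p.plot_id: middle_rows_roi(p.plot_id, config.plot_shape, config)
        for p in plots
    }
    harvest_rois = {
        p.plot_id: middle_rows_roi(p.plot_id, config.harvest_shape, config)
        for p in plots
    }

    cum_par_by_date = {
        d: cumulative_incident_par(weather, config.planting_date, d)
        for d in sampling_dates
    }

    rasters: dict[tuple[str, dt.date], MultispectralRaster] = {}
    truth_rows = []
    obs_rows = []
    for p in plots:
        vi_p = true_vi(p.n_rate, config)
        gdds = np.array([thermal.gdd_at(d) for d in sampling_dates])
        covers = np.array(
            [simulate_canopy(g, p.n_rate, config) for g in gdds]
        )
        phys = simulate_ground_truth(
            np.full(config.n_dates, vi_p), gdds, config, rng_phys
        )
        for j, d in enumerate(sampling_dates):
            raster, _ = render_plot_raster(
                float(covers[j]), config, rng_raster, n_rate=p.n_rate
            )
            rasters[(p.plot_id, d)] = raster
            cum_par = cum_par_by_date[d]
            truth_rows.append(
                {
                    "plot_id": p.plot_id,
                    "date": d,
                    "n_rate": p.n_rate,
                    "canopy_cover": float(covers[j]),
                    "gdd": float(gdds[j]),
                    "vi_true": vi_p,
                    "ipar_f_true": float(phys["ipar_f_true"].iloc[j]),
                    "ipar_f_obs": float(phys["ipar_f_obs"].iloc[j]),
                    "biomass_true": float(phys["biomass_true"].iloc[j]),
                    "biomass_obs": float(phys["biomass_obs"].iloc[j]),
                    "cum_par": cum_par,
                    "cum_ipar_true": float(phys["ipar_f_true"].iloc[j]) * cum_par,
                }
            )
            obs_rows.append(
                {
                    "plot_id": p.plot_id,
                    "date": d,
                    "par_above": config.par_above,
                    "par_below": (1.0 - float(phys["ipar_f_obs"].iloc[j]))
                    * config.par_above,
                    "biomass_g_m2": float(phys["biomass_obs"].iloc[j]),
                    "lint_yield_kg_ha": np.nan,
                }
            )

    truth = pd.DataFrame(truth_rows)

    # Season-level truth and harvest imagery
    plot_rows = []
    harvest_images: dict[str, np.ndarray] = {}
    for p in plots:
        sub = truth[truth["plot_id"] == p.plot_id]
        max_bio_true = float(sub["biomass_true"].max())
        hi_true = _draw_truncated_normal(
            rng_phys, config.hi_mean, config.hi_sd, config.hi_bounds
        )
        lint_yield = hi_true * G_M2_TO_KG_HA * max_bio_true
        img, boll_mask = render_harvest_rgb(lint_yield, config, rng_harvest)
        harvest_images[p.plot_id] = img
        roi = harvest_rois[p.plot_id]
        from cottonphys.segmentation import pixel_centers_in_polygon

        in_roi = pixel_centers_in_polygon(roi.polygon, boll_mask.shape)
        true_cfi = float(boll_mask[in_roi].sum() / in_roi.sum())
        plot_rows.append(
            {
                "plot_id": p.plot_id,
                "block": p.block,
                "n_rate": p.n_rate,
                "season": config.season,
                "max_biomass_true": max_bio_true,
                "hi_true": hi_true,
                "lint_yield_true": lint_yield,
                "true_cfi": true_cfi,
            }
        )
        obs_rows.append(
            {
                "plot_id": p.plot_id,
                "date": harvest_date,
                "par_above": np.nan,
                "par_below": np.nan,
                "biomass_g_m2": np.nan,
                "lint_yield_kg_ha": lint_yield,
            }
        )

    observations = pd.DataFrame(obs_rows)
    plot_truth = pd.DataFrame(plot_rows)

    return StudyBundle(
        config=config,
        weather=weather,
        sampling_dates=sampling_dates,
        plots=plots,
        rois=rois,
        harvest_rois=harvest_rois,
        rasters=rasters,
        harvest_images=harvest_images,
        observations=observations,
        truth=truth,
        plot_truth=plot_truth,
        thermal=thermal,
    )
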
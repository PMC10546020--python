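"""End-to-end orchestration: rasters + weather + ground data → models.

Stage order: thermal time → canopy segmentation → vegetation indices →
radiation budget → GLM sweep over all 25 candidate predictors for each of
the three responses → CFI/lint-yield regression → harvest index. Each
stage's output is the next stage's input, so stages are also usable in
isolation.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cottonphys.cfi import (
    CFIResult,
    YieldModel,
    compute_cfi,
    enhance_image,
    fit_yield_model,
    predict_yield,
)
from cottonphys.config import PipelineConfig
from cottonphys.exceptions import ConfigError, DegenerateInputError
from cottonphys.glm import (
    FittedModel,
    ModelScore,
    ModelSpec,
    SplitPlan,
    TERMS_FULL,
    TERMS_MAIN,
    TERMS_VI_ONLY,
    cross_validate,
    fit_glm,
    fit_null_model,
    mechanistic_rue,
    predict_response,
    rank_models,
    remove_outliers,
    score_train,
    stratified_split,
)
from cottonphys.harvest import HIEstimate, evaluate_hi, predict_hi
from cottonphys.indices import PREDICTOR_NAMES, compute_all
from cottonphys.radiation import (
    G_M2_TO_KG_HA,
    cumulative_incident_par,
    cumulative_ipar,
    ipar_fraction,
    measured_hi,
    rue_series,
)
from cottonphys.segmentation import (
    MultispectralRaster,
    ROIPolygon,
    canopy_mask,
    classification_index,
    extract_roi_reflectance,
)
from cottonphys.simulate import SimConfig, StudyBundle, generate_study
from cottonphys.thermal_time import accumulate_gdd

logger = logging.getLogger(__name__)


def extract_observations(
    rasters: dict[tuple[str, dt.date], MultispectralRaster],
    rois: dict[str, ROIPolygon],
    ground: pd.DataFrame,
    weather,
    planting_date: dt.date,
    segmentation_threshold: float = 0.02,
    par_fraction: float = 0.45,
    base_temp_c: float = 15.6,
    ceiling_temp_c: float = 33.9,
) -> pd.DataFrame:
    """Segment every plot × date raster and join VIs with ground physiology.

    Returns one row per plot × sampling date with columns: plot_id, date,
    gdd, ipar_f, cum_par, cum_ipar, biomass, and the 25 predictors.
    """
    sampling = ground[ground["par_above"].notna()]
    last_date = max(d for _, d in rasters)
    thermal = accumulate_gdd(
        weather, planting_date, last_date, base=base_temp_c, ceiling=ceiling_temp_c
    )
    cum_par_by_date = {
        d: cumulative_incident_par(weather, planting_date, d, par_fraction)
        for d in sorted({date for _, date in rasters})
    }
    rows = []
    for r in sampling.itertuples():
        key = (str(r.plot_id), r.date)
        if key not in rasters:
            raise ConfigError(f"no raster for plot {key[0]} on {key[1]}")
        raster = rasters[key]
        index = classification_index(raster)
        mask = canopy_mask(index, segmentation_threshold)
        means = extract_roi_reflectance(
            raster, mask, rois[key[0]], date=r.date
        )
        vis = compute_all(means)
        f = ipar_fraction(float(r.par_above), float(r.par_below))
        cum_par = cum_par_by_date[r.date]
        row = {
            "plot_id": key[0],
            "date": r.date,
            "gdd": thermal.gdd_at(r.date),
            "ipar_f": f,
            "cum_par": cum_par,
            "cum_ipar": cumulative_ipar(f, cum_par),
            "biomass": float(r.biomass_g_m2),
            "n_canopy_pixels": means.n_canopy_pixels,
        }
        row.update(vis.values)
        rows.append(row)
    return pd.DataFrame(rows)


def build_rue_records(observations: pd.DataFrame) -> pd.DataFrame:
    """Per-plot RUE records referenced to the first sampling date.

    One record per plot × later date, with ``rue`` as the response and each
    predictor replaced by its average over the sampling dates spanning the
    RUE calculation period (reference date through date n).
    """
    rows = []
    for plot_id, grp in observations.groupby("plot_id", sort=True):
        grp = grp.sort_values("date").reset_index(drop=True)
        if len(grp) < 2:
            continue
        rues = rue_series(grp["biomass"].tolist(), grp["cum_ipar"].tolist())
        for n in range(1, len(grp)):
            row = {
                "plot_id": plot_id,
                "date": grp["date"].iloc[n],
                "rue": rues[n],
            }
            for name in PREDICTOR_NAMES:
                row[name] = float(grp[name].iloc[: n + 1].mean())
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SweepResult:
    """Outcome of one response's sweep over all candidate predictors."""

    response: str
    scores: list[ModelScore]
    models: dict[str, FittedModel]
    train: pd.DataFrame
    validation: pd.DataFrame
    n_outliers_removed: int

    @property
    def best(self) -> FittedModel:
        return self.models[self.scores[0].predictor]


def sweep_predictors(
    records: pd.DataFrame,
    response: str,
    seed: int,
    predictors=PREDICTOR_NAMES,
    train_fraction: float = 0.6,
    outlier_factor: float = 1.5,
    terms: str = "full",
) -> SweepResult:
    """Outlier removal → stratified split → fit/score/rank every predictor."""
    keep, removed = remove_outliers(records[response], factor=outlier_factor)
    cleaned = records.loc[keep].reset_index(drop=True)
    plan = SplitPlan(train_fraction=train_fraction, stratify_by="date", seed=seed)
    train, valid = stratified_split(cleaned, plan)
    if response == "rue":
        term_tuple = TERMS_VI_ONLY
    else:
        term_tuple = TERMS_FULL if terms == "full" else TERMS_MAIN
    scores: list[ModelScore] = []
    models: dict[str, FittedModel] = {}
    for predictor in predictors:
        spec = ModelSpec(response=response, predictor=predictor, terms=term_tuple)
        try:
            model = fit_glm(spec, train)
            if not model.converged:
                logger.warning("%s/%s did not converge; excluded", response, predictor)
                continue
            null = fit_null_model(spec, train)
            r2, aicc, bic = score_train(model, null)
            r2_cv, rmse_cv = cross_validate(model, valid)
        except DegenerateInputError as exc:
            logger.warning("%s/%s excluded: %s", response, predictor, exc)
            continue
        models[predictor] = model
        scores.append(
            ModelScore(
                predictor=predictor, r2_train=r2, aicc=aicc, bic=bic,
                r2_cv=r2_cv, rmse_cv=rmse_cv,
            )
        )
    return SweepResult(
        response=response,
        scores=rank_models(scores),
        models=models,
        train=train,
        validation=valid,
        n_outliers_removed=int(removed.size),
    )


def compute_plot_cfi(
    harvest_images: dict[str, np.ndarray],
    harvest_rois: dict[str, ROIPolygon],
    threshold: int = 150,
) -> list[CFIResult]:
    """Enhance each plot's harvest image and score its white-pixel fraction."""
    results = []
    for plot_id in sorted(harvest_images):
        enhanced = enhance_image(harvest_images[plot_id])
        results.append(compute_cfi(enhanced, harvest_rois[plot_id], threshold))
    return results


@dataclass
class PipelineResult:
    observations: pd.DataFrame
    rue_records: pd.DataFrame
    sweeps: dict[str, SweepResult]
    cfi: pd.DataFrame
    yield_model: YieldModel
    hi_estimates: list[HIEstimate]
    hi_evaluation: pd.DataFrame
    mech_rue_modeled: pd.DataFrame = field(default=None)
    mech_rue_measured_biomass: pd.DataFrame = field(default=None)


def analyze_study(bundle: StudyBundle, config: PipelineConfig) -> PipelineResult:
    """Run the full analysis on an in-memory study bundle."""
    observations = extract_observations(
        bundle.rasters,
        bundle.rois,
        bundle.observations,
        bundle.weather,
        bundle.config.planting_date,
        segmentation_threshold=config.segmentation_threshold,
        par_fraction=config.par_fraction,
        base_temp_c=config.base_temp_c,
        ceiling_temp_c=config.ceiling_temp_c,
    )
    rue_records = build_rue_records(observations)

    sweeps = {
        "ipar_f": sweep_predictors(
            observations, "ipar_f", seed=config.seed,
            train_fraction=config.train_fraction,
            outlier_factor=config.outlier_factor, terms=config.model_terms,
        ),
        "biomass": sweep_predictors(
            observations, "biomass", seed=config.seed,
            train_fraction=config.train_fraction,
            outlier_factor=config.outlier_factor, terms=config.model_terms,
        ),
        "rue": sweep_predictors(
            rue_records, "rue", seed=config.seed,
            train_fraction=config.train_fraction,
            outlier_factor=config.outlier_factor,
        ),
    }

    # CFI → lint yield
    cfi_results = compute_plot_cfi(
        bundle.harvest_images, bundle.harvest_rois, threshold=config.cfi_threshold
    )
    cfi_df = pd.DataFrame([c.__dict__ for c in cfi_results])
    harvest_rows = bundle.observations[
        bundle.observations["lint_yield_kg_ha"].notna()
    ][["plot_id", "lint_yield_kg_ha"]]
    cfi_df = cfi_df.merge(harvest_rows, on="plot_id", how="inner")
    yield_model = fit_yield_model(
        cfi_df["cfi"].to_numpy(), cfi_df["lint_yield_kg_ha"].to_numpy()
    )

    # Harvest index: predicted yield over predicted max seasonal biomass
    best_biomass = sweeps["biomass"].best
    hi_estimates: list[HIEstimate] = []
    for plot_id, grp in observations.groupby("plot_id", sort=True):
        cfi_row = cfi_df[cfi_df["plot_id"] == plot_id]
        if cfi_row.empty:
            continue
        yield_pred = predict_yield(yield_model, float(cfi_row["cfi"].iloc[0]))
        biomass_pred = predict_response(best_biomass, grp)
        hi_pred = predict_hi(yield_pred, list(biomass_pred))
        hi_meas = measured_hi(
            float(cfi_row["lint_yield_kg_ha"].iloc[0]), grp["biomass"].tolist()
        )
        hi_estimates.append(
            HIEstimate(
                plot_id=plot_id, season=config.season,
                hi_pred=hi_pred, hi_meas=hi_meas,
            )
        )
    hi_evaluation = evaluate_hi(hi_estimates)

    mech_modeled = mechanistic_rue(
        best_biomass, sweeps["ipar_f"].best, observations
    )
    mech_measured = mechanistic_rue(
        None, sweeps["ipar_f"].best, observations, use_measured_biomass=True
    )

    return PipelineResult(
        observations=observations,
        rue_records=rue_records,
        sweeps=sweeps,
        cfi=cfi_df,
        yield_model=yield_model,
        hi_estimates=hi_estimates,
        hi_evaluation=hi_evaluation,
        mech_rue_modeled=mech_modeled,
        mech_rue_measured_biomass=mech_measured,
    )


def write_score_table(scores: list[ModelScore], path) -> None:
    """CSV score table (predictor, r2, aicc, bic, r2cv, rmsecv), rank order."""
    if not scores:
        raise DegenerateInputError("no scores to write")
    pd.DataFrame(
        {
            "predictor": [s.predictor for s in scores],
            "r2": [s.r2_train for s in scores],
            "aicc": [s.aicc for s in scores],
            "bic": [s.bic for s in scores],
            "r2cv": [s.r2_cv for s in scores],
            "rmsecv": [s.rmse_cv for s in scores],
        }
    ).to_csv(path, index=False)


def write_results(result: PipelineResult, config: PipelineConfig, outdir) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for response, sweep in result.sweeps.items():
        write_score_table(sweep.scores, out / f"scores_{response}.csv")
    obs = result.observations.copy()
    obs["date"] = obs["date"].map(lambda d: d.isoformat())
    obs.to_csv(out / "observations.csv", index=False)
    result.cfi.to_csv(out / "cfi.csv", index=False)
    (out / "yield_model.json").write_text(
        json.dumps(result.yield_model.__dict__, indent=2)
    )
    result.hi_evaluation.to_csv(out / "hi_evaluation.csv", index=False)
    pd.DataFrame([e.__dict__ for e in result.hi_estimates]).to_csv(
        out / "hi_estimates.csv", index=False
    )
    log = {
        "seed": config.seed,
        "segmentation_threshold": config.segmentation_threshold,
        "cfi_threshold": config.cfi_threshold,
        "par_fraction": config.par_fraction,
        "base_temp_c": config.base_temp_c,
        "ceiling_temp_c": config.ceiling_temp_c,
        "train_fraction": config.train_fraction,
        "outlier_factor": config.outlier_factor,
        "model_terms": config.model_terms,
        "outliers_removed": {
            resp: sweep.n_outliers_removed for resp, sweep in result.sweeps.items()
        },
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return out


def load_study(config: PipelineConfig) -> StudyBundle:
    """Assemble a study bundle from on-disk inputs (non-synthetic mode)."""
    from cottonphys.io import (
        read_ground_csv,
        read_harvest_images,
        read_raster_npz,
        read_raster_tiff,
        read_roi_csv,
    )
    from cottonphys.thermal_time import read_weather_csv

    for key in ("weather_path", "rasters_dir", "rois_path", "ground_path",
                "planting_date"):
        if getattr(config, key) is None:
            raise ConfigError(f"non-synthetic mode requires config key {key!r}")
    weather = read_weather_csv(config.weather_path)
    rois = read_roi_csv(config.rois_path)
    ground = read_ground_csv(config.ground_path)
    rasters: dict[tuple[str, dt.date], MultispectralRaster] = {}
    for path in sorted(Path(config.rasters_dir).glob("*")):
        if path.suffix not in (".npz", ".tif", ".tiff"):
            continue
        plot_id, date_str = path.stem.rsplit("_", 1)
        reader = read_raster_npz if path.suffix == ".npz" else read_raster_tiff
        rasters[(plot_id, dt.date.fromisoformat(date_str))] = reader(path)
    if not rasters:
        raise ConfigError(f"no rasters found in {config.rasters_dir}")
    harvest_images = (
        read_harvest_images(config.harvest_dir) if config.harvest_dir else {}
    )
    harvest_rois = (
        read_roi_csv(config.harvest_rois_path) if config.harvest_rois_path else rois
    )
    sim = SimConfig(
        seed=0,
        planting_date=dt.date.fromisoformat(config.planting_date),
        season=config.season,
    )
    sampling_dates = sorted({d for _, d in rasters})
    return StudyBundle(
        config=sim,
        weather=weather,
        sampling_dates=sampling_dates,
        plots=[],
        rois=rois,
        harvest_rois=harvest_rois,
        rasters=rasters,
        harvest_images=harvest_images,
        observations=ground,
        truth=pd.DataFrame(),
        plot_truth=pd.DataFrame(),
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Generate or load the study, run the full analysis, write outputs."""
    if config.synthetic:
        bundle = generate_study(SimConfig(seed=config.sim_seed))
    else:
        bundle = load_study(config)
    result = analyze_study(bundle, config)
    if config.out_dir:
        write_results(result, config, config.out_dir)
    return result
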
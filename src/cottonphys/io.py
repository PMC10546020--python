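"""Table, raster and image I/O for the pipeline's external formats.

Rasters are plain multiband TIFFs (band order blue, green, red, red-edge,
NIR) or ``.npz`` band bundles; ROI tables are CSV with WKT polygons;
harvest imagery is 8-bit PNG; masks are single-band uint8 TIFFs of {0, 1}.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from shapely import wkt as shapely_wkt

from cottonphys.exceptions import ConfigError
from cottonphys.segmentation import BAND_NAMES, MultispectralRaster, ROIPolygon
from cottonphys.simulate import StudyBundle
from cottonphys.thermal_time import write_weather_csv


def write_raster_tiff(raster: MultispectralRaster, path) -> None:
    tifffile.imwrite(str(path), raster.to_stack().astype(np.float32))


def read_raster_tiff(path) -> MultispectralRaster:
    stack = tifffile.imread(str(path)).astype(np.float64)
    return MultispectralRaster.from_stack(stack)


def write_raster_npz(raster: MultispectralRaster, path) -> None:
    np.savez(str(path), **{name: raster.bands[name] for name in BAND_NAMES})


def read_raster_npz(path) -> MultispectralRaster:
    with np.load(str(path)) as data:
        return MultispectralRaster({name: data[name] for name in BAND_NAMES})


def write_mask_tiff(mask: np.ndarray, path) -> None:
    tifffile.imwrite(str(path), mask.astype(np.uint8))


def write_roi_csv(rois: dict[str, ROIPolygon], path) -> None:
    pd.DataFrame(
        {
            "plot_id": list(rois),
            "wkt": [rois[p].polygon.wkt for p in rois],
        }
    ).to_csv(path, index=False)


def read_roi_csv(path) -> dict[str, ROIPolygon]:
    df = pd.read_csv(path)
    if not {"plot_id", "wkt"} <= set(df.columns):
        raise ConfigError("ROI CSV needs columns plot_id, wkt")
    return {
        str(r.plot_id): ROIPolygon(str(r.plot_id), shapely_wkt.loads(r.wkt))
        for r in df.itertuples()
    }


def write_study(bundle: StudyBundle, outdir) -> Path:
    """Write a synthetic study to disk in the pipeline's input formats."""
    out = Path(outdir)
    (out / "rasters").mkdir(parents=True, exist_ok=True)
    (out / "harvest").mkdir(exist_ok=True)
    write_weather_csv(bundle.weather, out / "weather.csv")
    write_roi_csv(bundle.rois, out / "rois.csv")
    write_roi_csv(bundle.harvest_rois, out / "harvest_rois.csv")
    obs = bundle.observations.copy()
    obs["date"] = obs["date"].map(lambda d: d.isoformat())
    obs.to_csv(out / "ground.csv", index=False)
    truth = bundle.truth.copy()
    truth["date"] = truth["date"].map(lambda d: d.isoformat())
    truth.to_csv(out / "truth.csv", index=False)
    bundle.plot_truth.to_csv(out / "plot_truth.csv", index=False)
    for (plot_id, date), raster in bundle.rasters.items():
        write_raster_npz(raster, out / "rasters" / f"{plot_id}_{date.isoformat()}.npz")
    for plot_id, img in bundle.harvest_images.items():
        iio.imwrite(out / "harvest" / f"{plot_id}.png", img)
    meta = {
        "planting_date": bundle.config.planting_date.isoformat(),
        "season": bundle.config.season,
        "seed": bundle.config.seed,
        "sampling_dates": [d.isoformat() for d in bundle.sampling_dates],
    }
    (out / "study.json").write_text(json.dumps(meta, indent=2))
    return out


def read_ground_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"plot_id", "date", "par_above", "par_below", "biomass_g_m2"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"ground CSV missing columns: {sorted(missing)}")
    df["date"] = df["date"].map(dt.date.fromisoformat)
    return df


def read_harvest_images(directory) -> dict[str, np.ndarray]:
    images = {}
    for path in sorted(Path(directory).glob("*.png")):
        images[path.stem] = iio.imread(path)
    return images
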
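"""Canopy/soil segmentation and per-plot reflectance extraction.

Canopy pixels are separated from bare soil with a classification index — the
product of NDVI, (NIR−R)/(NIR+R), and the excess greenness index ExG,
2G−R−B, both computed on reflectance — thresholded at a global value
(default 0.02, strict ``>``). Mean band reflectance is then taken over the
canopy pixels whose centers fall inside a plot's region-of-interest polygon
(the middle rows of the plot).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon

from cottonphys.exceptions import ConfigError, EmptyROIError

logger = logging.getLogger(__name__)

#: Canonical band order for 5-band multispectral rasters.
BAND_NAMES = ("blue", "green", "red", "rededge", "nir")

#: Global threshold on NDVI×ExG above which a pixel is canopy.
DEFAULT_SEGMENTATION_THRESHOLD = 0.02


@dataclass
class MultispectralRaster:
    """Five named reflectance planes (unitless, nominally 0–1)."""

    bands: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = set(BAND_NAMES) - set(self.bands)
        if missing:
            raise ConfigError(f"raster missing bands: {sorted(missing)}")
        shapes = {name: b.shape for name, b in self.bands.items()}
        if len(set(shapes.values())) != 1:
            raise ConfigError(f"band shapes differ: {shapes}")
        for name, b in self.bands.items():
            if not np.all(np.isfinite(b)):
                raise ConfigError(f"band {name} contains non-finite values")
            n_out = int(np.sum((b < 0) | (b > 1)))
            if n_out:
                # Retained, not clipped: calibration noise must not silently
                # alter downstream masks.
                logger.info("band %s: %d pixels outside [0, 1]", name, n_out)

    @classmethod
    def from_stack(cls, stack: np.ndarray) -> "MultispectralRaster":
        """Build from a (5, H, W) array in canonical band order."""
        if stack.ndim != 3 or stack.shape[0] != len(BAND_NAMES):
            raise ConfigError(f"expected (5, H, W) stack, got {stack.shape}")
        return cls({name: stack[i] for i, name in enumerate(BAND_NAMES)})

    def to_stack(self) -> np.ndarray:
        return np.stack([self.bands[name] for name in BAND_NAMES])

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    @property
    def height(self) -> int:
        return self.shape[0]

    @property
    def width(self) -> int:
        return self.shape[1]


@dataclass(frozen=True)
class ROIPolygon:
    """A plot's region of interest in pixel coordinates.

    Coordinates are (x, y) = (column, row) with row 0 at the top; the pixel
    at (row, col) has its center at (col + 0.5, row + 0.5).
    """

    plot_id: str
    polygon: Polygon

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or self.polygon.area == 0:
            raise ConfigError(f"ROI {self.plot_id}: invalid or zero-area polygon")

    @classmethod
    def from_vertices(cls, plot_id: str, vertices) -> "ROIPolygon":
        return cls(plot_id=plot_id, polygon=Polygon(vertices))


@dataclass(frozen=True)
class BandMeans:
    """Mean canopy reflectance per band over a plot ROI."""

    plot_id: str
    date: dt.date | None
    means: dict[str, float]
    n_canopy_pixels: int


def classification_index(raster: MultispectralRaster) -> np.ndarray:
    """Per-pixel NDVI × ExG used to separate canopy from soil.

    Pixels where NIR + R = 0 (NDVI undefined) map to 0.
    """
    b = raster.bands["blue"]
    g = raster.bands["green"]
    r = raster.bands["red"]
    nir = raster.bands["nir"]
    denom = nir + r
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(denom != 0, (nir - r) / np.where(denom == 0, 1.0, denom), 0.0)
    exg = 2.0 * g - r - b
    return ndvi * exg


def canopy_mask(
    index: np.ndarray, threshold: float = DEFAULT_SEGMENTATION_THRESHOLD
) -> np.ndarray:
    """Boolean canopy mask: index strictly greater than ``threshold``."""
    if not np.isfinite(threshold):
        raise ConfigError("segmentation threshold must be finite")
    return index > threshold


def pixel_centers_in_polygon(polygon: Polygon, shape: tuple[int, int]) -> np.ndarray:
    """Boolean (H, W) array: pixel centers strictly inside the polygon.

    Boundary pixels are excluded (strict interior containment).
    """
    h, w = shape
    minx, miny, maxx, maxy = polygon.bounds
    rows = np.arange(max(0, int(np.floor(miny - 0.5))), min(h, int(np.ceil(maxy))))
    cols = np.arange(max(0, int(np.floor(minx - 0.5))), min(w, int(np.ceil(maxx))))
    inside = np.zeros(shape, dtype=bool)
    if rows.size == 0 or cols.size == 0:
        return inside
    cc, rr = np.meshgrid(cols, rows)
    xs = cc + 0.5
    ys = rr + 0.5
    hit = shapely.contains_xy(polygon, xs.ravel(), ys.ravel()).reshape(rr.shape)
    inside[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1] = hit
    return inside


def extract_roi_reflectance(
    raster: MultispectralRaster,
    mask: np.ndarray,
    roi: ROIPolygon,
    date: dt.date | None = None,
    allow_unmasked_fallback: bool = False,
) -> BandMeans:
    """Mean band reflectance over canopy pixels inside the ROI.

    Pixels count if their center is strictly inside the ROI polygon *and*
    they are canopy in ``mask``. If no canopy pixel falls in the ROI an
    :class:`EmptyROIError` is raised unless ``allow_unmasked_fallback`` is
    set, in which case the unmasked ROI mean is returned (logged).
    """
    if mask.shape != raster.shape:
        raise ConfigError(f"mask shape {mask.shape} != raster shape {raster.shape}")
    in_roi = pixel_centers_in_polygon(roi.polygon, raster.shape)
    if not in_roi.any():
        raise EmptyROIError(f"ROI {roi.plot_id} does not intersect the raster")
    selected = in_roi & mask
    if not selected.any():
        if not allow_unmasked_fallback:
            raise EmptyROIError(
                f"ROI {roi.plot_id}: no canopy pixels (pass "
                "allow_unmasked_fallback=True for the unmasked mean)"
            )
        logger.warning("ROI %s: no canopy pixels, using unmasked mean", roi.plot_id)
        selected = in_roi
    means = {
        name: float(raster.bands[name][selected].mean()) for name in BAND_NAMES
    }
    return BandMeans(
        plot_id=roi.plot_id,
        date=date,
        means=means,
        n_canopy_pixels=int(selected.sum()),
    )
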
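"""Cotton fiber index (CFI) from pre-harvest RGB imagery.

Open cotton bolls appear as near-achromatic bright blobs against darker
soil and defoliated vegetation. A simple global threshold misclassifies
background, so the image is first enhanced: grayscale (mean of R, G, B),
an edge-preserving bilateral smoothing, additive 5×5 Laplacian sharpening
to restore boll edges, and a 3×3 arithmetic-mean filter to remove the
noise the sharpening introduces. White pixels are then those strictly
above an 8-bit threshold (default 150), and

    CFI = white pixels in ROI / total pixels in ROI.

Lint yield (kg ha⁻¹) is regressed linearly on CFI; no train/validation
split is used for this regression (plot counts are small at harvest).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.restoration import denoise_bilateral

from cottonphys.exceptions import ConfigError, DegenerateInputError, EmptyROIError
from cottonphys.segmentation import ROIPolygon, pixel_centers_in_polygon

#: 8-bit intensity above which (strictly) a pixel counts as white cotton.
DEFAULT_CFI_THRESHOLD = 150


@dataclass(frozen=True)
class CFIResult:
    plot_id: str
    white_pixels: int
    total_pixels: int
    cfi: float


@dataclass(frozen=True)
class YieldModel:
    """Linear CFI → lint yield model (kg ha⁻¹)."""

    slope: float
    intercept: float
    r2: float
    rmse: float
    n: int


def _laplacian_kernel() -> np.ndarray:
    k = np.full((5, 5), -1.0)
    k[2, 2] = 24.0
    return k


def enhance_image(
    img: np.ndarray,
    sigma_spatial: float = 3.0,
    sigma_range: float = 30.0,
    mean_size: int = 3,
) -> np.ndarray:
    """Grayscale + bilateral + Laplacian sharpening + mean filter.

    Input is an (H, W, 3) uint8 RGB image; output is an (H, W) uint8
    enhanced intensity image. All convolutions use reflect padding, so a
    constant image passes through unchanged. ``sigma_range`` is in 8-bit
    intensity units.
    """
    if img.dtype != np.uint8:
        raise ConfigError(f"expected 8-bit image, got dtype {img.dtype}")
    if img.ndim != 3 or img.shape[2] != 3:
        raise ConfigError(f"expected (H, W, 3) RGB image, got shape {img.shape}")
    gray = img.astype(np.float64).mean(axis=2)
    smoothed = (
        denoise_bilateral(
            gray / 255.0,
            sigma_color=sigma_range / 255.0,
            sigma_spatial=sigma_spatial,
            mode="reflect",
        )
        * 255.0
    )
    lap = ndimage.convolve(smoothed, _laplacian_kernel(), mode="reflect")
    sharpened = np.clip(smoothed + lap, 0.0, 255.0)
    mean = ndimage.uniform_filter(sharpened, size=mean_size, mode="reflect")
    return np.clip(np.rint(mean), 0, 255).astype(np.uint8)


def compute_cfi(
    enhanced: np.ndarray,
    roi: ROIPolygon,
    threshold: int = DEFAULT_CFI_THRESHOLD,
) -> CFIResult:
    """White-pixel fraction inside the ROI of an enhanced intensity image."""
    if enhanced.ndim != 2:
        raise ConfigError(f"expected single-channel image, got shape {enhanced.shape}")
    in_roi = pixel_centers_in_polygon(roi.polygon, enhanced.shape)
    total = int(in_roi.sum())
    if total == 0:
        raise EmptyROIError(f"ROI {roi.plot_id} contains no pixels")
    white = int(np.sum(enhanced[in_roi] > threshold))
    return CFIResult(
        plot_id=roi.plot_id, white_pixels=white, total_pixels=total,
        cfi=white / total,
    )


def fit_yield_model(cfi: np.ndarray, lint_yield: np.ndarray) -> YieldModel:
    """Ordinary least-squares lint yield (kg ha⁻¹) on CFI."""
    cfi = np.asarray(cfi, dtype=float)
    lint_yield = np.asarray(lint_yield, dtype=float)
    if cfi.size != lint_yield.size:
        raise DegenerateInputError("cfi and yield arrays differ in length")
    if cfi.size < 3:
        raise DegenerateInputError(f"need at least 3 plots, got {cfi.size}")
    if np.all(cfi == cfi[0]):  # np.var can round away from exact zero
        raise DegenerateInputError("zero variance in CFI")
    slope, intercept = np.polyfit(cfi, lint_yield, 1)
    pred = slope * cfi + intercept
    resid = lint_yield - pred
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((lint_yield - lint_yield.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    rmse = float(np.sqrt(np.mean(resid**2)))
    return YieldModel(
        slope=float(slope), intercept=float(intercept), r2=r2, rmse=rmse,
        n=int(cfi.size),
    )


def predict_yield(model: YieldModel, cfi: float) -> float:
    """Predicted lint yield (kg ha⁻¹), floored at 0."""
    return max(0.0, model.slope * cfi + model.intercept)
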
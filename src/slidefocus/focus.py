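"""Per-sub-tile focus scoring and background detection.

Two classic edge-based focus measures, computed at full resolution on
8-bit luma:

* **Tenengrad** — mean squared Sobel gradient magnitude above a noise
  floor. The normalization by pixel count makes scores comparable across
  sub-tile sizes; the floor suppresses sensor noise on flat areas.
* **Sum-modified-Laplacian (SML)** — mean of ``|2I - I(x-s) - I(x+s)| +
  |2I - I(y-s) - I(y+s)|`` over interior pixels above a floor; the
  best-ranked measure in published autofocus comparisons.

Both decrease monotonically with Gaussian defocus on textured tissue and
vanish on constant regions. Background (bare glass) is detected per pixel
as bright *and* unsaturated — near-white in brightfield H&E — and
summarized per sub-tile as a fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import ndimage

from .errors import SlideValidationError
from .wsi_io import RasterRegion, TileTask, to_grayscale

__all__ = [
    "FocusParams",
    "BackgroundParams",
    "SubTileRecord",
    "tenengrad",
    "sum_modified_laplacian",
    "background_fraction",
    "score_tile",
]

#: Default squared-gradient noise floor for Tenengrad (8-bit luma units²).
DEFAULT_TENENGRAD_THRESHOLD = 100.0
#: Default absolute-Laplacian floor and step for SML (8-bit luma units).
DEFAULT_SML_THRESHOLD = 7.0
DEFAULT_SML_STEP = 1

_SOBEL_X = np.array([[-1.0, 0.0, 1.0],
                     [-2.0, 0.0, 2.0],
                     [-1.0, 0.0, 1.0]])
_SOBEL_Y = _SOBEL_X.T


@dataclass(frozen=True)
class FocusParams:
    """Focus-measure selection and its noise floor.

    ``gradient_threshold`` is in squared-gradient units for ``tenengrad``
    and absolute-Laplacian units for ``sml``; ``None`` picks the
    per-measure default. All values are echoed into reports.
    """

    measure: str = "tenengrad"
    gradient_threshold: Optional[float] = None
    sml_step: int = DEFAULT_SML_STEP

    def __post_init__(self):
        if self.measure not in ("tenengrad", "sml"):
            raise SlideValidationError(f"unknown focus measure {self.measure!r}")
        if self.gradient_threshold is not None and self.gradient_threshold < 0:
            raise SlideValidationError("gradient_threshold must be >= 0")
        if self.sml_step < 1:
            raise SlideValidationError("sml_step must be >= 1")

    @property
    def resolved_threshold(self) -> float:
        if self.gradient_threshold is not None:
            return self.gradient_threshold
        return (DEFAULT_TENENGRAD_THRESHOLD if self.measure == "tenengrad"
                else DEFAULT_SML_THRESHOLD)

    def score(self, intensity: np.ndarray) -> float:
        if self.measure == "tenengrad":
            return tenengrad(intensity, self.resolved_threshold)
        return sum_modified_laplacian(intensity, self.sml_step, self.resolved_threshold)

    def to_dict(self) -> dict:
        return {"measure": self.measure,
                "gradient_threshold": self.resolved_threshold,
                "sml_step": self.sml_step}


@dataclass(frozen=True)
class BackgroundParams:
    """Rule for bare-glass detection on brightfield H&E-like slides.

    A pixel is background when its luma is at least ``luma_min`` and its
    HSV-style saturation ``(max-min)/max`` is at most ``saturation_max``
    — bright and colorless. A sub-tile with at least ``bg_subtile_min``
    background pixels is pure background; tissue sub-tiles at or above
    ``bg_high_min`` carry a "high percentage of background" flag.
    """

    luma_min: float = 220.0
    saturation_max: float = 0.10
    bg_subtile_min: float = 0.90
    bg_high_min: float = 0.50

    def __post_init__(self):
        if not 0.0 <= self.luma_min <= 255.0:
            raise SlideValidationError("luma_min must be in [0, 255]")
        if not 0.0 <= self.saturation_max <= 1.0:
            raise SlideValidationError("saturation_max must be in [0, 1]")
        if not 0.0 <= self.bg_high_min < self.bg_subtile_min <= 1.0:
            raise SlideValidationError(
                "need 0 <= bg_high_min < bg_subtile_min <= 1")

    def to_dict(self) -> dict:
        return {"luma_min": self.luma_min,
                "saturation_max": self.saturation_max,
                "bg_subtile_min": self.bg_subtile_min,
                "bg_high_min": self.bg_high_min}


@dataclass
class SubTileRecord:
    """Focus score, background fraction, and (later) category of one sub-tile."""

    grid_x: int
    grid_y: int
    focus_score: float
    bg_fraction: float
    category: Optional[str] = None


def tenengrad(intensity: np.ndarray, gradient_threshold: float = DEFAULT_TENENGRAD_THRESHOLD) -> float:
    """Thresholded, count-normalized Tenengrad focus score.

    Sobel gradients are taken with reflect padding so every pixel is
    evaluated; the score is the sum of squared gradient magnitudes
    exceeding ``gradient_threshold``, divided by the pixel count.
    """
    intensity = np.asarray(intensity, dtype=np.float64)
    if intensity.ndim != 2 or min(intensity.shape) < 3:
        raise SlideValidationError("tenengrad needs a 2D lattice at least 3x3")
    if gradient_threshold < 0:
        raise SlideValidationError("gradient_threshold must be >= 0")
    gx = ndimage.convolve(intensity, _SOBEL_X, mode="reflect")
    gy = ndimage.convolve(intensity, _SOBEL_Y, mode="reflect")
    energy = gx * gx + gy * gy
    return float(energy[energy > gradient_threshold].sum() / energy.size)


def sum_modified_laplacian(intensity: np.ndarray, step: int = DEFAULT_SML_STEP,
                           threshold: float = DEFAULT_SML_THRESHOLD) -> float:
    """Thresholded, count-normalized sum-modified-Laplacian focus score.

    The modified Laplacian at an interior pixel is the sum of the absolute
    second differences in x and y, each taken at spacing ``step``; only
    values at or above ``threshold`` contribute, and the total is divided
    by the number of interior pixels.
    """
    intensity = np.asarray(intensity, dtype=np.float64)
    if intensity.ndim != 2:
        raise SlideValidationError("sum_modified_laplacian needs a 2D lattice")
    if step < 1:
        raise SlideValidationError("step must be >= 1")
    h, w = intensity.shape
    if h < 2 * step + 1 or w < 2 * step + 1:
        raise SlideValidationError(
            f"lattice {h}x{w} too small for SML step {step}")
    if threshold < 0:
        raise SlideValidationError("threshold must be >= 0")
    c = intensity[step:-step, step:-step]
    ml = (np.abs(2.0 * c - intensity[step:-step, : w - 2 * step]
                 - intensity[step:-step, 2 * step:])
          + np.abs(2.0 * c - intensity[: h - 2 * step, step:-step]
                   - intensity[2 * step:, step:-step]))
    return float(ml[ml >= threshold].sum() / ml.size)


def background_fraction(region, params: BackgroundParams = BackgroundParams()) -> float:
    """Fraction of pixels that are bright and unsaturated (bare glass)."""
    pixels = region.pixels if isinstance(region, RasterRegion) else np.asarray(region)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise SlideValidationError("background_fraction expects a 3-channel region")
    rgb = pixels.astype(np.float64)
    luma = to_grayscale(pixels)
    mx = rgb.max(axis=2)
    mn = rgb.min(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(mx > 0, (mx - mn) / np.where(mx > 0, mx, 1.0), 0.0)
    is_bg = (luma >= params.luma_min) & (sat <= params.saturation_max)
    return float(is_bg.mean())


def score_tile(region: RasterRegion, task: TileTask, sub_tile_side_px: int,
               fparams: FocusParams = FocusParams(),
               bparams: BackgroundParams = BackgroundParams()) -> List[SubTileRecord]:
    """Score every sub-tile of a tile region.

    The region must exactly cover the task's rectangle (dimensions
    multiples of the sub-tile side). Focus scores are computed on the
    grayscale sub-image, background fractions on the RGB sub-image; the
    records come back row-major with lattice positions offset by the
    task's ``(grid_x0, grid_y0)``.
    """
    pixels = region.pixels
    h, w = pixels.shape[:2]
    if h % sub_tile_side_px or w % sub_tile_side_px:
        raise SlideValidationError(
            f"region {w}x{h} is not a multiple of sub-tile side {sub_tile_side_px}")
    luma = to_grayscale(pixels)
    records: List[SubTileRecord] = []
    for gy in range(h // sub_tile_side_px):
        y0 = gy * sub_tile_side_px
        for gx in range(w // sub_tile_side_px):
            x0 = gx * sub_tile_side_px
            sub_rgb = pixels[y0 : y0 + sub_tile_side_px, x0 : x0 + sub_tile_side_px]
            sub_luma = luma[y0 : y0 + sub_tile_side_px, x0 : x0 + sub_tile_side_px]
            records.append(SubTileRecord(
                grid_x=task.grid_x0 + gx,
                grid_y=task.grid_y0 + gy,
                focus_score=fparams.score(sub_luma),
                bg_fraction=background_fraction(sub_rgb, bparams),
            ))
    return records
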
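"""Slide access and tile planning.

Opens large 8-bit RGB rasters (flat or pyramidal TIFF, PNG, or a simple
``{level}/{col}_{row}.png`` tile directory), serves full-resolution
rectangular regions with a half-open ``[x, x+w) x [y, y+h)`` convention,
and plans the non-overlapping tile decomposition used by the pipeline.

All scoring happens at level 0 (the largest plane): downsampling makes a
defocused image look sharper than it is, so pyramid levels other than 0
are never consulted for assessment.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import imageio.v3 as iio
import tifffile

from .errors import RegionRangeError, SlideFormatError, SlideValidationError

__all__ = [
    "SlideSource",
    "TileTask",
    "RasterRegion",
    "open_slide",
    "read_region",
    "plan_tiles",
    "to_grayscale",
]

#: Default side of a worker tile in pixels ("moderate size" fetch unit).
DEFAULT_TILE_SIDE = 2048
#: Default side of the atomic scoring sub-tile in pixels.
DEFAULT_SUB_TILE_SIDE = 128

_TILE_NAME_RE = re.compile(r"^(\d+)_(\d+)\.png$")


@dataclass
class SlideSource:
    """Handle to a slide exposing dimensions and region reads at level 0."""

    path: Path
    width_px: int
    height_px: int
    n_channels: int
    source_kind: str  # flat_tiff | pyramidal_tiff | png | tile_directory
    _pixels: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def level0(self) -> np.ndarray:
        """Full level-0 plane as a (H, W, 3) uint8 array, cached."""
        if self._pixels is None:
            self._pixels = _load_level0(self.path, self.source_kind)
        return self._pixels


@dataclass(frozen=True)
class TileTask:
    """A full-resolution rectangle assigned to one worker.

    ``x_px``/``y_px`` are multiples of the sub-tile side, so the sub-tile
    lattices of adjacent tiles align; ``grid_x0``/``grid_y0`` locate the
    tile's first sub-tile in the slide-wide lattice.
    """

    tile_id: int
    x_px: int
    y_px: int
    width_px: int
    height_px: int
    grid_x0: int
    grid_y0: int


@dataclass
class RasterRegion:
    """Pixels of a requested rectangle, clipped to slide bounds."""

    pixels: np.ndarray  # (H, W, 3) uint8
    x_px: int
    y_px: int
    width_px: int
    height_px: int
    clipped: bool = False


def _as_rgb8(arr: np.ndarray, path) -> np.ndarray:
    if arr.dtype != np.uint8:
        raise SlideFormatError(
            f"{path}: only 8-bit images are supported, got dtype {arr.dtype}"
        )
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise SlideFormatError(
            f"{path}: expected an RGB image, got shape {arr.shape}"
        )
    return np.ascontiguousarray(arr)


def _scan_tile_directory(root: Path):
    """Layout ``{level}/{col}_{row}.png``; only level 0 is read."""
    level0 = root / "0"
    if not level0.is_dir():
        raise SlideFormatError(f"{root}: tile directory has no level-0 subdirectory '0'")
    tiles = {}
    for name in os.listdir(level0):
        m = _TILE_NAME_RE.match(name)
        if m:
            tiles[(int(m.group(1)), int(m.group(2)))] = level0 / name
    if not tiles:
        raise SlideFormatError(f"{root}: no {{col}}_{{row}}.png tiles in level 0")
    return tiles


def _load_level0(path: Path, kind: str) -> np.ndarray:
    if kind in ("flat_tiff", "pyramidal_tiff"):
        with tifffile.TiffFile(path) as tf:
            pages = list(tf.pages)
            # level 0 = the largest plane, regardless of IFD order
            best = max(pages, key=lambda p: p.shape[0] * p.shape[1])
            arr = best.asarray()
        return _as_rgb8(arr, path)
    if kind == "png":
        return _as_rgb8(iio.imread(path), path)
    if kind == "tile_directory":
        tiles = _scan_tile_directory(path)
        cols = max(c for c, _ in tiles) + 1
        rows = max(r for _, r in tiles) + 1
        grid = {}
        for (c, r), p in tiles.items():
            grid[(c, r)] = _as_rgb8(iio.imread(p), p)
        col_w = [grid[(c, 0)].shape[1] for c in range(cols)]
        row_h = [grid[(0, r)].shape[0] for r in range(rows)]
        out = np.empty((sum(row_h), sum(col_w), 3), dtype=np.uint8)
        y = 0
        for r in range(rows):
            x = 0
            for c in range(cols):
                t = grid.get((c, r))
                if t is None:
                    raise SlideFormatError(f"{path}: missing tile {c}_{r}.png")
                out[y : y + t.shape[0], x : x + t.shape[1]] = t
                x += col_w[c]
            y += row_h[r]
        return out
    raise SlideFormatError(f"{path}: unknown source kind {kind!r}")


def open_slide(path) -> SlideSource:
    """Open a slide file or tile directory and report level-0 dimensions.

    Supported kinds: flat TIFF, pyramidal (multi-IFD) TIFF, PNG, and a
    directory laid out as ``{level}/{col}_{row}.png``. Raises
    :class:`SlideFormatError` for unreadable or unsupported inputs.
    """
    path = Path(path)
    if not path.exists():
        raise SlideFormatError(f"{path}: no such file or directory")

    if path.is_dir():
        kind = "tile_directory"
        arr = _load_level0(path, kind)
        h, w = arr.shape[:2]
        src = SlideSource(path, w, h, 3, kind, _pixels=arr)
    else:
        suffix = path.suffix.lower()
        if suffix in (".tif", ".tiff"):
            try:
                with tifffile.TiffFile(path) as tf:
                    pages = list(tf.pages)
                    if not pages:
                        raise SlideFormatError(f"{path}: TIFF contains no image planes")
                    shapes = [p.shape for p in pages]
            except SlideFormatError:
                raise
            except Exception as exc:
                raise SlideFormatError(f"{path}: unreadable TIFF ({exc})") from exc
            kind = "pyramidal_tiff" if len(shapes) > 1 else "flat_tiff"
            h, w = max(shapes, key=lambda s: s[0] * s[1])[:2]
            src = SlideSource(path, int(w), int(h), 3, kind)
        elif suffix == ".png":
            try:
                arr = _as_rgb8(iio.imread(path), path)
            except SlideFormatError:
                raise
            except Exception as exc:
                raise SlideFormatError(f"{path}: unreadable PNG ({exc})") from exc
            h, w = arr.shape[:2]
            src = SlideSource(path, w, h, 3, "png", _pixels=arr)
        else:
            raise SlideFormatError(
                f"{path}: unsupported format {suffix!r} (use TIFF, PNG, or a tile directory)"
            )
    if src.width_px < 1 or src.height_px < 1:
        raise SlideValidationError(f"{path}: zero-area image")
    return src


def read_region(slide: SlideSource, x_px: int, y_px: int,
                width_px: int, height_px: int) -> RasterRegion:
    """Read a full-resolution rectangle, clipping at the slide edges.

    The rectangle is half-open: pixels ``[x, x+w) x [y, y+h)``. A request
    overlapping an edge returns the clipped part with ``clipped=True``; a
    request entirely outside the slide raises :class:`RegionRangeError`.
    Reads are deterministic and never resampled.
    """
    if width_px < 1 or height_px < 1:
        raise SlideValidationError("region width and height must be >= 1")
    x0, y0 = max(x_px, 0), max(y_px, 0)
    x1 = min(x_px + width_px, slide.width_px)
    y1 = min(y_px + height_px, slide.height_px)
    if x0 >= x1 or y0 >= y1:
        raise RegionRangeError(
            f"region ({x_px},{y_px},{width_px},{height_px}) lies outside "
            f"slide {slide.width_px}x{slide.height_px}"
        )
    pixels = slide.level0()[y0:y1, x0:x1].copy()
    clipped = (x1 - x0 != width_px) or (y1 - y0 != height_px)
    return RasterRegion(pixels, x0, y0, x1 - x0, y1 - y0, clipped=clipped)


def plan_tiles(slide: SlideSource,
               tile_side_px: int = DEFAULT_TILE_SIDE,
               sub_tile_side_px: int = DEFAULT_SUB_TILE_SIDE) -> List[TileTask]:
    """Plan the non-overlapping, sub-tile-aligned tile decomposition.

    The assessed area is the largest sub-tile-aligned rectangle,
    ``floor(W/s) x floor(H/s)`` sub-tiles; partial sub-tiles at the right
    and bottom edges are excluded so every score covers a full 128x128
    window (or whatever ``sub_tile_side_px`` is). Edge tiles may be smaller
    than ``tile_side_px`` but stay multiples of the sub-tile side. Tiles
    are returned row-major by (y, x).
    """
    if sub_tile_side_px < 1 or tile_side_px < 1:
        raise SlideValidationError("tile and sub-tile sides must be positive")
    if tile_side_px % sub_tile_side_px != 0:
        raise SlideValidationError(
            f"tile side {tile_side_px} is not a multiple of sub-tile side {sub_tile_side_px}"
        )
    grid_w = slide.width_px // sub_tile_side_px
    grid_h = slide.height_px // sub_tile_side_px
    if grid_w == 0 or grid_h == 0:
        raise SlideValidationError(
            f"slide {slide.width_px}x{slide.height_px} is smaller than one "
            f"{sub_tile_side_px}px sub-tile; nothing to assess"
        )
    assessed_w = grid_w * sub_tile_side_px
    assessed_h = grid_h * sub_tile_side_px
    tasks: List[TileTask] = []
    tile_id = 0
    for y in range(0, assessed_h, tile_side_px):
        h = min(tile_side_px, assessed_h - y)
        for x in range(0, assessed_w, tile_side_px):
            w = min(tile_side_px, assessed_w - x)
            tasks.append(TileTask(
                tile_id=tile_id, x_px=x, y_px=y, width_px=w, height_px=h,
                grid_x0=x // sub_tile_side_px, grid_y0=y // sub_tile_side_px,
            ))
            tile_id += 1
    return tasks


#: ITU-R BT.601 luma weights, used for both focus input and background luma.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def to_grayscale(region) -> np.ndarray:
    """Luma of an RGB region (0.299 R + 0.587 G + 0.114 B), float64.

    Kept in floating point: quantizing before the gradient computation
    would discard exactly the small differences the focus measures need.
    Accepts a :class:`RasterRegion` or a raw (H, W, 3) array.
    """
    pixels = region.pixels if isinstance(region, RasterRegion) else np.asarray(region)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise SlideValidationError("to_grayscale expects a 3-channel RGB region")
    return pixels.astype(np.float64) @ LUMA_WEIGHTS
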
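"""Sharpness-grid assembly and map rendering.

The merger assembles per-tile sub-tile records into one dense slide-wide
lattice, keyed by lattice coordinate so the result is independent of the
order (or partitioning) in which tiles were processed. The renderer turns
a classified grid into a categorical raster — one ``scale x scale`` block
per sub-tile — with a bit-exact palette, written as PNG (a lossy format
would corrupt the categorical colors).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Tuple

import numpy as np
import imageio.v3 as iio

from .classify import CATEGORIES
from .errors import IncompleteGridError, MergeConflictError, SlideValidationError
from .focus import SubTileRecord

__all__ = ["SharpnessGrid", "DEFAULT_PALETTE", "merge_tile_results", "render_map", "write_map_png"]

#: Category -> RGB. Honors the conventional legend: green sharp, red
#: blurred, light variants for high-background tiles, yellow medium,
#: gray background. Config-overridable; values must stay distinct.
DEFAULT_PALETTE: Dict[str, Tuple[int, int, int]] = {
    "sharp": (0, 160, 0),
    "sharp_bg": (150, 230, 150),
    "blurred": (200, 0, 0),
    "blurred_bg": (255, 170, 170),
    "medium": (230, 200, 0),
    "background": (160, 160, 160),
}


@dataclass
class SharpnessGrid:
    """Dense lattice of sub-tile records covering the assessed slide area."""

    grid_width: int
    grid_height: int
    cells: List[List[SubTileRecord]]  # [row][col]
    sub_tile_side_px: int = 128

    def iter_records(self) -> Iterator[SubTileRecord]:
        for row in self.cells:
            yield from row

    def to_dict(self) -> dict:
        """JSON-ready form; stable field order for byte-identical dumps."""
        return {
            "grid_width": self.grid_width,
            "grid_height": self.grid_height,
            "sub_tile_side_px": self.sub_tile_side_px,
            "cells": [
                [{"focus_score": r.focus_score, "bg_fraction": r.bg_fraction,
                  "category": r.category} for r in row]
                for row in self.cells
            ],
        }


def merge_tile_results(partials: Iterable[List[SubTileRecord]],
                       grid_width: int, grid_height: int,
                       sub_tile_side_px: int = 128) -> SharpnessGrid:
    """Merge per-tile record lists into the slide-wide grid.

    Keyed by ``(grid_x, grid_y)``, so any partitioning and any input
    order give an identical grid. A coordinate claimed twice raises
    :class:`MergeConflictError`; unfilled cells raise
    :class:`IncompleteGridError` listing the gaps.
    """
    if grid_width < 1 or grid_height < 1:
        raise SlideValidationError("grid dimensions must be >= 1")
    filled: Dict[Tuple[int, int], SubTileRecord] = {}
    for records in partials:
        for rec in records:
            key = (rec.grid_x, rec.grid_y)
            if not (0 <= rec.grid_x < grid_width and 0 <= rec.grid_y < grid_height):
                raise SlideValidationError(
                    f"record at {key} outside {grid_width}x{grid_height} grid")
            if key in filled:
                raise MergeConflictError(key)
            filled[key] = rec
    missing = [(x, y) for y in range(grid_height) for x in range(grid_width)
               if (x, y) not in filled]
    if missing:
        raise IncompleteGridError(missing)
    cells = [[filled[(x, y)] for x in range(grid_width)] for y in range(grid_height)]
    return SharpnessGrid(grid_width, grid_height, cells, sub_tile_side_px)


def render_map(grid: SharpnessGrid,
               palette: Dict[str, Tuple[int, int, int]] = DEFAULT_PALETTE,
               scale: int = 1) -> np.ndarray:
    """Render the categorical sharpness map as an RGB uint8 raster.

    Cell ``(i, j)`` becomes a uniform ``scale x scale`` block of its
    category color; output shape is ``(grid_height*scale,
    grid_width*scale, 3)``. Rendering is pure and bit-exact.
    """
    if scale < 1:
        raise SlideValidationError("scale must be >= 1")
    missing = set(CATEGORIES) - set(palette)
    if missing:
        raise SlideValidationError(f"palette missing categories: {sorted(missing)}")
    if len({tuple(palette[c]) for c in CATEGORIES}) != len(CATEGORIES):
        raise SlideValidationError("palette colors must be distinct")
    small = np.empty((grid.grid_height, grid.grid_width, 3), dtype=np.uint8)
    for y, row in enumerate(grid.cells):
        for x, rec in enumerate(row):
            if rec.category is None:
                raise SlideValidationError(
                    f"sub-tile ({rec.grid_x},{rec.grid_y}) is unclassified")
            small[y, x] = palette[rec.category]
    if scale == 1:
        return small
    return np.repeat(np.repeat(small, scale, axis=0), scale, axis=1)


def write_map_png(path, grid: SharpnessGrid,
                  palette: Dict[str, Tuple[int, int, int]] = DEFAULT_PALETTE,
                  scale: int = 1) -> None:
    """Render and write the map losslessly as PNG."""
    iio.imwrite(path, render_map(grid, palette, scale), extension=".png")
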
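"""Region-of-interest selection.

The texture extractors operate on the largest axis-aligned rectangle
inscribed in the closed contour of the tissue region, optionally tiled
into 32x32 mini-ROIs.  Coordinates are 0-based and half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

from .exceptions import EmptyForegroundError, ROITooSmallError

__all__ = ["Rectangle", "MiniROIGrid", "segment_foreground",
           "largest_inscribed_rectangle", "tile_mini_rois", "extract_roi"]


@dataclass(frozen=True)
class Rectangle:
    """Axis-aligned rectangle: rows [row0, row0+height), cols [col0, col0+width)."""

    row0: int
    col0: int
    height: int
    width: int

    @property
    def area(self) -> int:
        return self.height * self.width

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row0, self.row0 + self.height),
                slice(self.col0, self.col0 + self.width))

    def to_dict(self) -> dict:
        return {"row0": self.row0, "col0": self.col0,
                "height": self.height, "width": self.width}


@dataclass
class MiniROIGrid:
    """Tiling of a rectangle into fixed-size square tiles."""

    rows: int
    cols: int
    tile: int
    rect: Rectangle
    tiles: list[tuple[int, int, np.ndarray]]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)


def segment_foreground(image: np.ndarray, method: str = "otsu",
                       level: float | None = None) -> np.ndarray:
    """Threshold an image and keep the largest connected component.

    ``method="otsu"`` picks the threshold automatically; ``method="fixed"``
    keeps pixels strictly above ``level``.  Holes in the retained
    component are filled.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise EmptyForegroundError("empty image")
    if method == "otsu":
        if img.max() == img.min():
            raise EmptyForegroundError("image has a single gray level")
        thr = threshold_otsu(img)
    elif method == "fixed":
        if level is None:
            raise ValueError("fixed thresholding needs a level")
        thr = level
    else:
        raise ValueError(f"unknown method {method!r}")
    fg = img > thr
    if not fg.any():
        raise EmptyForegroundError("no pixel above threshold")
    lab = label(fg, connectivity=2)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    mask = lab == counts.argmax()
    return ndimage.binary_fill_holes(mask)


def largest_inscribed_rectangle(mask: np.ndarray) -> Rectangle:
    """Largest all-foreground axis-aligned rectangle in a binary mask.

    Runs in O(H*W) with the histogram-stack method: each row maintains
    per-column heights of consecutive foreground pixels, and a monotone
    stack enumerates all maximal rectangles ending at that row.  Ties in
    area are broken by the smallest (row0, col0).
    """
    m = np.asarray(mask).astype(bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not m.any():
        raise EmptyForegroundError("mask has no foreground pixel")
    n_rows, n_cols = m.shape
    heights = np.zeros(n_cols, dtype=np.int64)
    best: tuple[int, int, int] | None = None  # (-area, row0, col0)
    best_rect = None
    for r in range(n_rows):
        heights = (heights + 1) * m[r]
        stack: list[tuple[int, int]] = []  # (start_col, height)
        for c in range(n_cols + 1):
            h = int(heights[c]) if c < n_cols else 0
            start = c
            while stack and stack[-1][1] >= h:
                sc, sh = stack.pop()
                if sh > 0:
                    key = (-sh * (c - sc), r - sh + 1, sc)
                    if best is None or key < best:
                        best = key
                        best_rect = Rectangle(r - sh + 1, sc, sh, c - sc)
                start = sc
            if h > 0 and (not stack or stack[-1][1] < h):
                stack.append((start, h))
    assert best_rect is not None
    return best_rect


def tile_mini_rois(image: np.ndarray, rect: Rectangle,
                   tile: int = 32) -> MiniROIGrid:
    """Tile a rectangle into ``tile`` x ``tile`` blocks.

    Tiles are anchored at the rectangle's top-left corner; trailing
    remainder pixels are discarded.
    """
    if rect.height < tile or rect.width < tile:
        raise ROITooSmallError(
            f"rectangle {rect.height}x{rect.width} smaller than one "
            f"{tile}x{tile} tile")
    img = np.asarray(image)
    rows, cols = rect.height // tile, rect.width // tile
    tiles = []
    for i in range(rows):
        for j in range(cols):
            r0 = rect.row0 + i * tile
            c0 = rect.col0 + j * tile
            tiles.append((i, j, img[r0:r0 + tile, c0:c0 + tile]))
    return MiniROIGrid(rows=rows, cols=cols, tile=tile, rect=rect, tiles=tiles)


def extract_roi(image: np.ndarray, method: str = "otsu",
                level: float | None = None) -> tuple[Rectangle, np.ndarray]:
    """Segment, inscribe, and crop: returns the ROI rectangle and its pixels."""
    mask = segment_foreground(image, method=method, level=level)
    rect = largest_inscribed_rectangle(mask)
    return rect, np.asarray(image)[rect.slices]
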
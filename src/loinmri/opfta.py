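"""One-point fractal texture features.

Each 32x32 mini-ROI is reduced to a single fractal value by
differential box counting evaluated at one scale (box size 8): the tile
is partitioned into (32/8)^2 boxes, the gray-level column height is
h = ceil(256 * 8 / 32) = 64 units, each box contributes
ceil((max+1)/h) - ceil((min+1)/h) + 1 and the value is
log(N) / log(32/8).  A flat tile therefore scores exactly 2, the
topological dimension of a smooth surface.  The per-tile values are
arranged in a matrix mirroring the tile layout, quantized, and seven
second-order statistics are taken from its co-occurrence matrix:
uniformity (UNI), entropy (ENT), correlation (COR), homogeneity (HOM),
inertia (INE), contrast (CON) and efficiency (EFI, normalized entropy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ContractError, NoPairsError
from .glcm import CoocMatrix, compute_cooccurrence, glcm_features
from .roi import MiniROIGrid, Rectangle, tile_mini_rois

__all__ = ["FractalMatrix", "OPFTAFeatures", "mini_roi_fractal_value",
           "build_fractal_matrix", "opfta_features", "OPFTAFeaturizer",
           "OPFTA_FEATURE_NAMES"]

OPFTA_FEATURE_NAMES = ("UNI", "ENT", "COR", "HOM", "INE", "CON", "EFI")


def mini_roi_fractal_value(tile: np.ndarray, box: int = 8,
                           gray_range: int = 256) -> float:
    """Single-scale differential box-counting value of one square tile."""
    tile = np.asarray(tile)
    if tile.ndim != 2 or tile.shape[0] != tile.shape[1]:
        raise ContractError("tile must be square")
    size = tile.shape[0]
    if size % box != 0 or box < 1 or box >= size:
        raise ContractError("box size must divide the tile size")
    g = size // box
    blocks = tile.astype(np.int64).reshape(g, box, g, box)
    bmax = blocks.max(axis=(1, 3))
    bmin = blocks.min(axis=(1, 3))
    h = -(-gray_range * box // size)  # ceil, gray units per box layer
    n_box = -(-(bmax + 1) // h) - (-(-(bmin + 1) // h)) + 1
    n_total = int(n_box.sum())
    return float(np.log(n_total) / np.log(size / box))


@dataclass
class FractalMatrix:
    """Per-mini-ROI fractal values in tile position, plus quantized levels."""

    values: np.ndarray     # (R, C) float
    quantized: np.ndarray  # (R, C) int levels in [0, levels)
    levels: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def build_fractal_matrix(grid: MiniROIGrid, box: int = 8,
                         levels: int = 8) -> FractalMatrix:
    """Assemble per-tile fractal values and quantize the observed range.

    Quantization bins the observed [min, max] linearly into ``levels``
    levels; a constant matrix maps to level 0 everywhere.
    """
    if not grid.tiles:
        raise ContractError("empty mini-ROI grid")
    size = grid.tile
    if size % box != 0 or box < 1 or box >= size:
        raise ContractError("box size must divide the tile size")
    g = size // box
    h = -(-256 * box // size)
    # all tiles at once: stack -> (tiles, g, box, g, box) -> box extrema
    stack = np.stack([blk for _, _, blk in grid.tiles]).astype(np.int64)
    blocks = stack.reshape(len(grid.tiles), g, box, g, box)
    bmax = blocks.max(axis=(2, 4))
    bmin = blocks.min(axis=(2, 4))
    n_box = -(-(bmax + 1) // h) - (-(-(bmin + 1) // h)) + 1
    flat = np.log(n_box.sum(axis=(1, 2))) / np.log(size / box)
    values = np.empty(grid.shape, dtype=float)
    for (i, j, _), v in zip(grid.tiles, flat):
        values[i, j] = v
    vmin, vmax = values.min(), values.max()
    if vmax > vmin:
        q = np.floor((values - vmin) / (vmax - vmin) * levels).astype(np.int64)
        q = np.clip(q, 0, levels - 1)
    else:
        q = np.zeros(grid.shape, dtype=np.int64)
    return FractalMatrix(values=values, quantized=q, levels=levels)


@dataclass
class OPFTAFeatures:
    UNI: float
    ENT: float
    COR: float
    HOM: float
    INE: float
    CON: float
    EFI: float
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in OPFTA_FEATURE_NAMES])


def opfta_features(fm: FractalMatrix, distance: int = 1) -> OPFTAFeatures:
    """Seven second-order statistics of the quantized fractal matrix.

    The co-occurrence matrix is accumulated exactly as for the gray
    texture (distance 1, four directions, symmetric); 1xK matrices use
    the directions available.  Efficiency is the entropy normalized by
    log2 of the number of occupied levels (1 when a single level is
    occupied), saturated at 1.
    """
    q = fm.quantized
    if q.size < 2:
        raise NoPairsError("fractal matrix admits no pairs")
    m: CoocMatrix = compute_cooccurrence(q, levels=fm.levels,
                                         distance=distance, prequantized=True)
    g = glcm_features(m)
    occupied = int(np.unique(q).size)
    efi = 1.0 if occupied <= 1 else min(1.0, g.ENT / np.log2(occupied))
    return OPFTAFeatures(UNI=g.ENE, ENT=g.ENT, COR=g.COR,
                         HOM=float((m.p / (1.0 + np.abs(
                             np.arange(fm.levels)[:, None]
                             - np.arange(fm.levels)[None, :]))).sum()),
                         INE=g.INE, CON=g.CON, EFI=efi,
                         degenerate=g.degenerate)


class OPFTAFeaturizer(TransformerMixin, BaseEstimator):
    """Transformer mapping rectangular gray regions to the seven features.

    Each input region is tiled into ``tile`` x ``tile`` mini-ROIs, each
    tile is reduced to its single-scale fractal value, and second-order
    statistics are taken on the assembled matrix.
    """

    def __init__(self, box: int = 8, tile: int = 32, levels: int = 8,
                 distance: int = 1):
        self.box = box
        self.tile = tile
        self.levels = levels
        self.distance = distance

    def fit(self, X, y=None):  # stateless
        return self

    def transform(self, X) -> np.ndarray:
        rows = []
        for region in X:
            region = np.asarray(region)
            rect = Rectangle(0, 0, region.shape[0], region.shape[1])
            grid = tile_mini_rois(region, rect, tile=self.tile)
            fm = build_fractal_matrix(grid, box=self.box, levels=self.levels)
            rows.append(opfta_features(fm, distance=self.distance).as_array())
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(OPFTA_FEATURE_NAMES, dtype=object)
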
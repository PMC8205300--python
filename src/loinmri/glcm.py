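"""Gray-level co-occurrence texture features.

Pairs of quantized gray levels at distance 1 are counted along the four
2-D directions (0, 45, 90, 135 degrees) together with their opposites
and accumulated into a single symmetric matrix, from which ten
second-order statistics are computed: energy (ENE), entropy (ENT),
correlation (COR), Haralick's correlation (HC), inverse difference
moment (IDM), inertia (INE), cluster shade (CS), cluster prominence
(CP), contrast (CON) and dissimilarity (DIS).  No closed-form source
distinguishes CON from INE, so both are defined as the second moment of
|i - j| and kept as distinct columns of the feature schema.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from skimage.feature import graycomatrix

from .exceptions import NoPairsError

__all__ = ["CoocMatrix", "GLCMFeatures", "quantize", "compute_cooccurrence",
           "glcm_features", "GLCMFeaturizer", "GLCM_FEATURE_NAMES"]

GLCM_FEATURE_NAMES = ("ENE", "ENT", "COR", "HC", "IDM", "INE",
                      "CS", "CP", "CON", "DIS")

_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


def quantize(region: np.ndarray, levels: int, max_value: int = 256) -> np.ndarray:
    """Linear binning of gray values [0, max_value) into ``levels`` levels."""
    region = np.asarray(region)
    q = (region.astype(np.int64) * levels) // max_value
    return np.clip(q, 0, levels - 1).astype(np.uint8)


@dataclass
class CoocMatrix:
    """Accumulated symmetric co-occurrence counts and probabilities."""

    counts: np.ndarray  # (G, G) integer counts
    levels: int
    distance: int = 1

    @property
    def p(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total


def compute_cooccurrence(region: np.ndarray, levels: int = 32,
                         distance: int = 1,
                         prequantized: bool = False) -> CoocMatrix:
    """Accumulate one symmetric co-occurrence matrix over four directions.

    ``region`` is quantized into ``levels`` gray levels unless
    ``prequantized`` is set (then its values must already be < levels).
    Each ordered pair is counted once per direction and once for the
    opposite direction, so the matrix is symmetric.
    """
    region = np.asarray(region)
    if region.ndim != 2 or region.size < 2:
        raise NoPairsError("region must be 2-D with at least two pixels")
    q = region.astype(np.uint8) if prequantized else quantize(region, levels)
    if prequantized and q.max() >= levels:
        raise ValueError("prequantized values must be < levels")
    per_angle = graycomatrix(q, distances=[distance], angles=list(_ANGLES),
                             levels=levels, symmetric=True, normed=False)
    counts = per_angle[:, :, 0, :].sum(axis=2).astype(np.int64)
    if counts.sum() == 0:
        raise NoPairsError("region admits no neighbouring pixel pair")
    return CoocMatrix(counts=counts, levels=levels, distance=distance)


@dataclass
class GLCMFeatures:
    ENE: float
    ENT: float
    COR: float
    HC: float
    IDM: float
    INE: float
    CS: float
    CP: float
    CON: float
    DIS: float
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in GLCM_FEATURE_NAMES])


def _marginal_moments(p: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Index grid differences and marginal mean/sd of a symmetric p-matrix."""
    g = p.shape[0]
    idx = np.arange(g, dtype=float)
    pi = p.sum(axis=1)
    mu = float((idx * pi).sum())
    sigma = float(np.sqrt(((idx - mu) ** 2 * pi).sum()))
    return idx, mu, sigma


def glcm_features(m: CoocMatrix) -> GLCMFeatures:
    """The ten second-order statistics of a normalized co-occurrence matrix.

    Entropy uses log base 2 (bits) with 0*log(0) = 0.  For a degenerate
    matrix (single occupied level, zero marginal variance) correlation
    and Haralick's correlation are returned as their limit 1 with the
    ``degenerate`` flag set.
    """
    p = m.p
    idx, mu, sigma = _marginal_moments(p)
    i = idx[:, None]
    j = idx[None, :]
    diff = i - j
    ene = float((p ** 2).sum())
    nz = p[p > 0]
    ent = float(-(nz * np.log2(nz)).sum())
    con = float(((diff ** 2) * p).sum())
    dis = float((np.abs(diff) * p).sum())
    idm = float((p / (1.0 + diff ** 2)).sum())
    s = i + j - 2.0 * mu
    cs = float((s ** 3 * p).sum())
    cp = float((s ** 4 * p).sum())
    if sigma == 0.0:
        cor = hc = 1.0
        degenerate = True
    else:
        cov = float(((i - mu) * (j - mu) * p).sum())
        cor = cov / (sigma * sigma)
        hc = (float((i * j * p).sum()) - mu * mu) / (sigma * sigma)
        degenerate = False
    return GLCMFeatures(ENE=ene, ENT=ent, COR=cor, HC=hc, IDM=idm,
                        INE=con, CS=cs, CP=cp, CON=con, DIS=dis,
                        degenerate=degenerate)


class GLCMFeaturizer(TransformerMixin, BaseEstimator):
    """Transformer mapping rectangular gray regions to the ten GLCM features.

    Parameters
    ----------
    levels : int, default 32
        Number of quantization levels for 8-bit input.
    distance : int, default 1
        Pair displacement in pixels.
    """

    def __init__(self, levels: int = 32, distance: int = 1):
        self.levels = levels
        self.distance = distance

    def fit(self, X, y=None):  # stateless
        return self

    def transform(self, X) -> np.ndarray:
        rows = []
        for region in X:
            m = compute_cooccurrence(region, levels=self.levels,
                                     distance=self.distance)
            rows.append(glcm_features(m).as_array())
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(GLCM_FEATURE_NAMES, dtype=object)
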
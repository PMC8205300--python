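"""Synthetic low-field-MRI-like phantoms and coupled quality traits.

Low-field scanners produce noisy 8-bit images of a roughly elliptical
muscle cross-section on a dark background, with spatially correlated
gray-level texture and bright intramuscular fat streaks.  This module
generates such phantoms, cohorts of phantoms whose physicochemical
traits (water activity, pH, moisture, lipids, instrumental color L*,
salt) are linear functions of the latent texture parameters, and
triplicate laboratory-style measurements per sample.  Because the
traits are coupled to *latent* generator parameters rather than to
extracted features, the texture extractors can be validated against an
independent ground truth.

All randomness flows through explicit integer seeds; identical inputs
give bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line as draw_line

from .exceptions import ContractError, InvalidSpecError

__all__ = [
    "PhantomSpec",
    "SampleRecord",
    "TraitCoupling",
    "Cohort",
    "TriplicateMeasurements",
    "generate_phantom",
    "generate_cohort",
    "generate_triplicates",
    "predict_traits",
    "DEFAULT_COUPLING_FRESH",
    "DEFAULT_COUPLING_DRY_CURED",
]

#: names of the latent texture parameters traits are coupled to
LATENT_NAMES = ("texture_sd", "n_streaks", "base_gray")

# trait bounds used when clipping coupled values into physical range
_TRAIT_BOUNDS = {
    "aw": (0.0, 1.0),
    "ph": (0.0, 14.0),
    "moisture": (0.0, 100.0),
    "lipids": (0.0, 100.0),
    "color_L": (0.0, 100.0),
    "salt": (0.0, 100.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic slice.

    Defaults emulate a spin-echo acquisition matrix of 256x204 pixels
    with a centred elliptical tissue region.

    Parameters
    ----------
    height, width : int
        Image shape in pixels.
    ellipse_center : (float, float)
        Ellipse centre as (row, col).
    ellipse_axes : (float, float)
        Semi-axes (a along rows, b along columns), pixels.
    base_gray : int
        Mean in-tissue gray level, 1-255.
    texture_corr_length : float
        Gaussian smoothing sigma of the correlated texture field, pixels.
    texture_sd : float
        Standard deviation of the correlated field, gray levels.
    n_streaks : int
        Number of bright fat-like line segments drawn inside the ellipse.
    streak_gray : int
        Gray level of the streaks, 1-255.
    noise_sd : float
        Standard deviation of i.i.d. pixel noise, gray levels.
    seed : int
        Seed of the generator; same spec + seed gives identical images.
    """

    height: int = 204
    width: int = 256
    ellipse_center: tuple[float, float] = (102.0, 128.0)
    ellipse_axes: tuple[float, float] = (70.0, 100.0)
    base_gray: int = 120
    texture_corr_length: float = 3.0
    texture_sd: float = 20.0
    n_streaks: int = 6
    streak_gray: int = 220
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise InvalidSpecError("image dimensions must be positive")
        if not (0 < self.base_gray <= 255):
            raise InvalidSpecError("base_gray must be in (0, 255]")
        if not (0 < self.streak_gray <= 255):
            raise InvalidSpecError("streak_gray must be in (0, 255]")
        if self.texture_sd < 0 or self.noise_sd < 0:
            raise InvalidSpecError("texture_sd and noise_sd must be >= 0")
        if self.n_streaks < 0:
            raise InvalidSpecError("n_streaks must be >= 0")
        cr, cc = self.ellipse_center
        a, b = self.ellipse_axes
        if a <= 0 or b <= 0:
            raise InvalidSpecError("ellipse axes must be positive")
        if (cr - a < 0 or cr + a > self.height - 1
                or cc - b < 0 or cc + b > self.width - 1):
            raise InvalidSpecError("ellipse must fit inside the image")

    def ellipse_mask(self) -> np.ndarray:
        """Boolean membership mask of the elliptical tissue region."""
        rr, cc = np.mgrid[0:self.height, 0:self.width]
        cr, ccen = self.ellipse_center
        a, b = self.ellipse_axes
        return ((rr - cr) / a) ** 2 + ((cc - ccen) / b) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render one 8-bit phantom image from a :class:`PhantomSpec`.

    Inside the ellipse the gray level is ``base_gray`` plus a spatially
    correlated Gaussian field (white noise smoothed with kernel sigma
    ``texture_corr_length`` and rescaled to in-ellipse standard
    deviation ``texture_sd``), bright streaks, and i.i.d. Gaussian
    noise; the result is clipped to [0, 255].  The background is 0.
    """
    rng = np.random.default_rng(spec.seed)
    mask = spec.ellipse_mask()
    img = np.zeros((spec.height, spec.width), dtype=float)
    img[mask] = float(spec.base_gray)

    # correlated texture: smoothed white noise, empirically rescaled so
    # the in-ellipse field has exactly the requested standard deviation
    white = rng.standard_normal((spec.height, spec.width))
    if spec.texture_sd > 0:
        smooth = ndimage.gaussian_filter(white, sigma=spec.texture_corr_length)
        sd = smooth[mask].std()
        if sd > 0:
            img[mask] += smooth[mask] * (spec.texture_sd / sd)

    # bright fat-like streaks: line segments between two in-ellipse points
    cr, cc = spec.ellipse_center
    a, b = spec.ellipse_axes
    for _ in range(spec.n_streaks):
        # draw segment endpoints uniformly inside a shrunken ellipse
        pts = []
        while len(pts) < 2:
            r = cr + rng.uniform(-0.9, 0.9) * a
            c = cc + rng.uniform(-0.9, 0.9) * b
            if ((r - cr) / a) ** 2 + ((c - cc) / b) ** 2 <= 0.81:
                pts.append((int(round(r)), int(round(c))))
        rr_l, cc_l = draw_line(pts[0][0], pts[0][1], pts[1][0], pts[1][1])
        keep = mask[rr_l, cc_l]
        img[rr_l[keep], cc_l[keep]] = float(spec.streak_gray)

    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=int(mask.sum()))
        img[mask] += noise

    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class SampleRecord:
    """Physicochemical traits of one loin sample."""

    sample_id: str
    state: str  # "fresh" or "dry-cured"
    aw: float
    ph: float
    moisture: float
    lipids: float
    color_L: float
    salt: float | None = None

    def __post_init__(self) -> None:
        if self.state not in ("fresh", "dry-cured"):
            raise ContractError(f"unknown state {self.state!r}")
        if not (0.0 <= self.aw <= 1.0):
            raise ContractError("water activity must lie in [0, 1]")
        for name in ("moisture", "lipids"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ContractError(f"{name} must lie in [0, 100]")
        if self.state == "fresh":
            if self.salt is not None:
                raise ContractError("fresh samples carry no salt value")
        else:
            if self.salt is None or not (0.0 <= self.salt <= 100.0):
                raise ContractError("dry-cured samples need salt in [0, 100]")


@dataclass(frozen=True)
class TraitCoupling:
    """Linear map from latent phantom parameters to one trait.

    ``value = intercept + sum(coef[k] * latent[k]) + N(0, noise_sd)``
    with latents on their raw scales.
    """

    intercept: float
    coef: Mapping[str, float]
    noise_sd: float = 0.0

    def mean(self, latents: Mapping[str, float]) -> float:
        return self.intercept + sum(c * float(latents[k])
                                    for k, c in self.coef.items())


def _coupling(mean: float, coef: dict[str, float], noise_sd: float,
              centers: Mapping[str, float]) -> TraitCoupling:
    # re-express a coupling given at the latent centers as a raw-scale one
    intercept = mean - sum(c * centers[k] for k, c in coef.items())
    return TraitCoupling(intercept, coef, noise_sd)


_CENTERS = {"texture_sd": 18.0, "n_streaks": 7.0, "base_gray": 120.0}

#: default fresh-loin couplings; intercepts target typical fresh means
#: (aw 0.97, pH 5.54, moisture 72 %, lipids 6 %, L* 48.4)
DEFAULT_COUPLING_FRESH: dict[str, TraitCoupling] = {
    "aw": _coupling(0.97, {"texture_sd": 8e-4, "n_streaks": -5e-4}, 0.002, _CENTERS),
    "ph": _coupling(5.54, {"texture_sd": 0.004, "base_gray": 0.002}, 0.02, _CENTERS),
    "moisture": _coupling(72.0, {"texture_sd": 0.30, "n_streaks": -0.40}, 0.6, _CENTERS),
    "lipids": _coupling(6.0, {"n_streaks": 0.25, "base_gray": 0.01}, 0.25, _CENTERS),
    "color_L": _coupling(48.4, {"base_gray": 0.08, "texture_sd": 0.10}, 0.35, _CENTERS),
}

#: default dry-cured couplings; means shift with curing (aw 0.88, pH 5.85,
#: moisture 42 %, lipids 6.1 %, L* 37.4, salt 2.9 %)
DEFAULT_COUPLING_DRY_CURED: dict[str, TraitCoupling] = {
    "aw": _coupling(0.88, {"texture_sd": 8e-4, "n_streaks": -5e-4}, 0.002, _CENTERS),
    "ph": _coupling(5.85, {"texture_sd": 0.004, "base_gray": 0.002}, 0.02, _CENTERS),
    "moisture": _coupling(42.1, {"texture_sd": 0.30, "n_streaks": -0.40}, 0.6, _CENTERS),
    "lipids": _coupling(6.1, {"n_streaks": 0.25, "base_gray": 0.01}, 0.25, _CENTERS),
    "color_L": _coupling(37.4, {"base_gray": 0.08, "texture_sd": 0.10}, 0.35, _CENTERS),
    "salt": _coupling(2.92, {"n_streaks": 0.03}, 0.08, _CENTERS),
}


@dataclass
class Cohort:
    """Result of :func:`generate_cohort`.

    Attributes
    ----------
    images : list of ndarray
        One phantom per sample.
    records : list of SampleRecord
        Trait values per sample (clipped into physical range).
    latents : pandas.DataFrame
        Latent parameters per sample, indexed by ``sample_id``.
    coupling : dict
        The trait couplings actually used (ground truth for recovery).
    n_clipped : int
        Number of trait values clipped into range.
    """

    images: list[np.ndarray]
    records: list[SampleRecord]
    latents: pd.DataFrame
    coupling: dict[str, TraitCoupling]
    n_clipped: int = 0

    def records_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            rows.append({
                "sample_id": rec.sample_id, "state": rec.state, "aw": rec.aw,
                "ph": rec.ph, "moisture": rec.moisture, "lipids": rec.lipids,
                "color_L": rec.color_L,
                "salt": "" if rec.salt is None else rec.salt,
            })
        return pd.DataFrame(rows)


def predict_traits(latents: pd.DataFrame,
                   coupling: Mapping[str, TraitCoupling]) -> pd.DataFrame:
    """Noise-free trait means implied by latents under a coupling."""
    out = {t: [c.mean(row) for _, row in latents.iterrows()]
           for t, c in coupling.items()}
    return pd.DataFrame(out, index=latents.index)


def generate_cohort(n: int,
                    state: str = "fresh",
                    coupling: Mapping[str, TraitCoupling] | None = None,
                    seed: int = 0,
                    base_spec: PhantomSpec | None = None) -> Cohort:
    """Generate ``n`` phantoms with linearly coupled quality traits.

    Latent parameters are drawn per sample (texture_sd ~ U(8, 28),
    n_streaks ~ U{2..12}, base_gray ~ U(100, 140)); each trait is a
    linear function of the latents plus Gaussian noise, clipped into
    physical range with a warning count.
    """
    if n < 10:
        raise ContractError("cohort size must be at least 10")
    if state not in ("fresh", "dry-cured"):
        raise ContractError(f"unknown state {state!r}")
    if coupling is None:
        coupling = (DEFAULT_COUPLING_FRESH if state == "fresh"
                    else DEFAULT_COUPLING_DRY_CURED)
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)

    texture_sd = rng.uniform(8.0, 28.0, n)
    n_streaks = rng.integers(2, 13, n)
    base_gray = rng.uniform(100.0, 140.0, n)
    ids = [f"{state[0].upper()}{i + 1:03d}" for i in range(n)]
    latents = pd.DataFrame(
        {"texture_sd": texture_sd, "n_streaks": n_streaks.astype(float),
         "base_gray": base_gray},
        index=pd.Index(ids, name="sample_id"),
    )

    images, records = [], []
    n_clipped = 0
    for i, sid in enumerate(ids):
        spec = PhantomSpec(
            height=base.height, width=base.width,
            ellipse_center=base.ellipse_center, ellipse_axes=base.ellipse_axes,
            base_gray=int(round(base_gray[i])),
            texture_corr_length=base.texture_corr_length,
            texture_sd=float(texture_sd[i]), n_streaks=int(n_streaks[i]),
            streak_gray=base.streak_gray, noise_sd=base.noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        images.append(generate_phantom(spec))

        traits = {}
        for trait, cpl in coupling.items():
            v = cpl.mean(latents.loc[sid])
            if cpl.noise_sd > 0:
                v += rng.normal(0.0, cpl.noise_sd)
            lo, hi = _TRAIT_BOUNDS.get(trait, (-np.inf, np.inf))
            clipped = min(max(v, lo), hi)
            if clipped != v:
                n_clipped += 1
            traits[trait] = clipped
        if state == "fresh":
            traits.pop("salt", None)
        records.append(SampleRecord(sample_id=sid, state=state,
                                    salt=traits.get("salt"),
                                    **{k: traits[k] for k in
                                       ("aw", "ph", "moisture", "lipids", "color_L")}))
    if n_clipped:
        warnings.warn(f"{n_clipped} trait value(s) clipped into physical range",
                      stacklevel=2)
    return Cohort(images, records, latents, dict(coupling), n_clipped)


@dataclass
class TriplicateMeasurements:
    """Repeated laboratory measurements, one block per trait.

    ``values[trait]`` has shape (n_samples, m) and row means exactly
    equal to the corresponding record value.
    """

    values: dict[str, np.ndarray] = field(default_factory=dict)
    sample_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for trait, block in self.values.items():
            for sid, reps in zip(self.sample_ids, block):
                for j, v in enumerate(reps):
                    rows.append({"sample_id": sid, "trait": trait,
                                 "rep": j + 1, "value": v})
        return pd.DataFrame(rows)


def generate_triplicates(records: Sequence[SampleRecord],
                         within_sd: float | Mapping[str, float],
                         seed: int = 0,
                         m: int = 3) -> TriplicateMeasurements:
    """Draw ``m`` repeated measurements per sample and trait.

    Draws are Gaussian around the record value and re-centred so that
    each sample's replicate mean equals the record value exactly; the
    replicate spread (sample standard deviation) is unaffected by the
    re-centring.
    """
    if m < 2:
        raise ContractError("at least two replicates are required")
    rng = np.random.default_rng(seed)
    traits = ["aw", "ph", "moisture", "lipids", "color_L"]
    if records and records[0].state == "dry-cured":
        traits.append("salt")
    out = TriplicateMeasurements(sample_ids=[r.sample_id for r in records])
    for trait in traits:
        sd = within_sd[trait] if isinstance(within_sd, Mapping) else float(within_sd)
        if sd < 0:
            raise ContractError("within_sd must be >= 0")
        base = np.array([getattr(r, trait) for r in records], dtype=float)
        eps = rng.normal(0.0, sd, size=(len(records), m)) if sd > 0 else \
            np.zeros((len(records), m))
        eps -= eps.mean(axis=1, keepdims=True)
        out.values[trait] = base[:, None] + eps
    return out
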
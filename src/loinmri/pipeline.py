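"""End-to-end helpers: image -> ROI -> texture features -> feature table."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .glcm import GLCM_FEATURE_NAMES, GLCMFeaturizer
from .opfta import OPFTA_FEATURE_NAMES, OPFTAFeaturizer
from .roi import extract_roi

__all__ = ["extract_features", "build_feature_table"]


def extract_features(image: np.ndarray, algorithm: str = "opfta",
                     **kwargs) -> dict[str, float]:
    """Segment an image, crop the inscribed ROI and compute texture features."""
    _, region = extract_roi(image)
    if algorithm == "glcm":
        values = GLCMFeaturizer(**kwargs).transform([region])[0]
        names = GLCM_FEATURE_NAMES
    elif algorithm == "opfta":
        values = OPFTAFeaturizer(**kwargs).transform([region])[0]
        names = OPFTA_FEATURE_NAMES
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return dict(zip(names, values))


def build_feature_table(images: Sequence[np.ndarray],
                        sample_ids: Sequence[str],
                        algorithm: str = "opfta",
                        **kwargs) -> pd.DataFrame:
    """Feature rows for a cohort of images, indexed by sample id."""
    rows = [extract_features(img, algorithm=algorithm, **kwargs)
            for img in images]
    out = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"))
    out.insert(0, "algorithm", algorithm)
    return out
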
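"""Packaged fixtures.

The fresh-loin CCD fixture carries the published 13-run face-centered
central composite design over echo time (TE, 18-26 ms) and repetition
time (TR, 630-910 ms) together with the five observed responses: the
correlation coefficients of the water-activity, pH, moisture, lipid
and instrumental-color-L* prediction models at each TE/TR combination.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .rsm import CCDesign

__all__ = ["load_fresh_loin_ccd", "RESPONSE_COLUMNS"]

RESPONSE_COLUMNS = {"r_aw": "aw", "r_ph": "ph", "r_moisture": "moisture",
                    "r_lipids": "lipids", "r_colorL": "colorL"}


def load_fresh_loin_ccd() -> tuple[CCDesign, pd.DataFrame]:
    """Load the packaged 13-run fresh-loin design and its five responses.

    Returns the :class:`~loinmri.rsm.CCDesign` (runs in the published
    order) and a DataFrame of the five response vectors indexed by run
    (columns ``aw, ph, moisture, lipids, colorL``).
    """
    with resources.files("loinmri.data").joinpath(
            "ccd_fresh_loin.csv").open() as fh:
        raw = pd.read_csv(fh).set_index("run")
    design = CCDesign(center=(22.0, 770.0), deltas=(4.0, 140.0), alpha=1.0,
                      runs=raw[["te_coded", "tr_coded", "te_ms", "tr_ms"]]
                      .astype(float))
    responses = raw[list(RESPONSE_COLUMNS)].rename(columns=RESPONSE_COLUMNS)
    return design, responses
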
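"""Validation metrics for the predictive models.

The five metrics are, for predictions f_i and real values y_i with mean
ybar over n samples:

    r      = sqrt( sum(f_i - ybar)^2 / sum(y_i - ybar)^2 )       (>= 0)
    RMSEP  = 100 * sqrt( mean (f_i - y_i)^2 )                    (percent)
    MAE    = mean |f_i - y_i|
    TSTD   = mean over samples of the per-sample standard deviation
             of repeated laboratory measurements
    WAPE   = 100 * sum |f_i - y_i| / sum f_i                     (percent)

For in-sample least-squares fitted values, r coincides with the
absolute Pearson correlation between f and y; the signed Pearson
correlation is reported as a separate diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import ContractError, DegenerateDataError

__all__ = ["MetricsReport", "compute_metrics", "compute_tstd",
           "compare_groups_anova"]


@dataclass
class MetricsReport:
    r: float
    rmsep: float
    mae: float
    wape: float
    n: int
    pearson: float
    tstd: float | None = None

    def to_dict(self) -> dict:
        return {"r": self.r, "rmsep": self.rmsep, "mae": self.mae,
                "wape": self.wape, "tstd": self.tstd, "n": self.n,
                "pearson": self.pearson}


def compute_metrics(f, y) -> MetricsReport:
    """Evaluate predictions ``f`` against real values ``y``."""
    f = np.asarray(f, dtype=float)
    y = np.asarray(y, dtype=float)
    if f.shape != y.shape or f.ndim != 1:
        raise ContractError("f and y must be 1-D of equal length")
    n = f.size
    if n < 2:
        raise ContractError("at least two samples are required")
    ybar = y.mean()
    ss_y = ((y - ybar) ** 2).sum()
    if ss_y == 0:
        raise DegenerateDataError("constant real values: r undefined")
    sum_f = f.sum()
    if sum_f == 0:
        raise DegenerateDataError("predictions sum to zero: WAPE undefined")
    r = float(np.sqrt(((f - ybar) ** 2).sum() / ss_y))
    rmsep = float(100.0 * np.sqrt(((f - y) ** 2).mean()))
    mae = float(np.abs(f - y).mean())
    wape = float(100.0 * np.abs(f - y).sum() / sum_f)
    if f.std() == 0:
        pearson = float("nan")
    else:
        pearson = float(np.corrcoef(f, y)[0, 1])
    return MetricsReport(r=r, rmsep=rmsep, mae=mae, wape=wape, n=n,
                         pearson=pearson)


def compute_tstd(measurements) -> float:
    """Mean per-sample standard deviation of repeated true measurements.

    ``measurements`` is an (N, M) array or a sequence of per-sample
    vectors (possibly of different lengths, each >= 2).
    """
    if isinstance(measurements, np.ndarray) and measurements.ndim == 2:
        rows: Sequence[np.ndarray] = list(measurements)
    else:
        rows = [np.asarray(row, dtype=float) for row in measurements]
    if len(rows) == 0:
        raise ContractError("no samples")
    sds = []
    for row in rows:
        row = np.asarray(row, dtype=float)
        if row.size < 2:
            raise ContractError("each sample needs at least two measurements")
        sds.append(row.std(ddof=1))
    return float(np.mean(sds))


def compare_groups_anova(group_a, group_b) -> tuple[float, float]:
    """One-way ANOVA F and p for a two-group comparison (equals t^2)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ContractError("each group needs at least two values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise DegenerateDataError("both groups are constant")
    res = stats.f_oneway(a, b)
    return float(res.statistic), float(res.pvalue)
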
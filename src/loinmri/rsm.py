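"""Face-centered central composite design and response-surface analysis.

The acquisition parameters echo time (TE) and repetition time (TR) are
optimized over a two-factor face-centered central composite design
(alpha = 1): 4 factorial corners, 4 axial points and a replicated
center, 13 runs in total.  For each response (the cross-validated
correlation coefficient of one quality trait) a full quadratic surface

    y = b0 + b1*A + b2*B + b12*A*B + b11*A^2 + b22*B^2

is fitted by least squares on the coded factors, and the classical
response-surface ANOVA is produced: partial (Type III) sums of squares
per term, residual decomposition into lack of fit and pure error from
the replicated runs, F tests, and the fit diagnostics R^2, adjusted
R^2, PRESS-based predicted R^2 and the adequate-precision signal
ratio.  In-range optimization maximizes an aggregate of the predicted
surfaces over the rectangular factor region by grid search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import ContractError, DegenerateDataError

__all__ = ["CCDesign", "FitDiagnostics", "OptimizationResult",
           "build_ccd", "ResponseSurface", "fit_quadratic", "anova_rsm",
           "diagnostics", "optimize_in_range", "TERM_NAMES"]

TERM_NAMES = ("TE", "TR", "TE x TR", "TE^2", "TR^2")


@dataclass
class CCDesign:
    """Two-factor face-centered central composite design.

    ``runs`` holds one row per run with coded and uncoded factor levels
    (columns ``te_coded, tr_coded, te_ms, tr_ms``).
    """

    center: tuple[float, float]
    deltas: tuple[float, float]
    alpha: float
    runs: pd.DataFrame

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def n_center(self) -> int:
        return int(((self.runs["te_coded"] == 0)
                    & (self.runs["tr_coded"] == 0)).sum())

    def coded(self) -> np.ndarray:
        return self.runs[["te_coded", "tr_coded"]].to_numpy(dtype=float)

    def code(self, te, tr) -> tuple[np.ndarray, np.ndarray]:
        """Map uncoded (ms) factor values onto the coded scale."""
        return ((np.asarray(te, dtype=float) - self.center[0]) / self.deltas[0],
                (np.asarray(tr, dtype=float) - self.center[1]) / self.deltas[1])

    def bounds(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """Uncoded factor ranges spanned by the design."""
        te = self.runs["te_ms"]
        tr = self.runs["tr_ms"]
        return (float(te.min()), float(te.max())), \
               (float(tr.min()), float(tr.max()))


def build_ccd(center: tuple[float, float] = (22.0, 770.0),
              deltas: tuple[float, float] = (4.0, 140.0),
              alpha: float = 1.0,
              n_center: int = 5) -> CCDesign:
    """Construct the design: 4 factorial + 4 axial + ``n_center`` center runs.

    With ``alpha=1`` the axial points sit on the faces of the factorial
    square (the setting used throughout); other alphas give rotatable
    variants and are accepted but flagged with a warning.
    """
    if deltas[0] <= 0 or deltas[1] <= 0:
        raise ContractError("factor deltas must be positive")
    if alpha != 1.0:
        import warnings
        warnings.warn("alpha != 1 leaves the face-centered setting",
                      stacklevel=2)
    coded = ([(-1.0, -1.0), (1.0, -1.0), (-1.0, 1.0), (1.0, 1.0)]
             + [(-alpha, 0.0), (alpha, 0.0), (0.0, -alpha), (0.0, alpha)]
             + [(0.0, 0.0)] * n_center)
    rows = []
    for i, (a, b) in enumerate(coded, start=1):
        rows.append({"run": i, "te_coded": a, "tr_coded": b,
                     "te_ms": center[0] + deltas[0] * a,
                     "tr_ms": center[1] + deltas[1] * b})
    return CCDesign(center=center, deltas=deltas, alpha=alpha,
                    runs=pd.DataFrame(rows).set_index("run"))


@dataclass
class FitDiagnostics:
    r_squared: float
    adj_r_squared: float
    pred_r_squared: float
    press: float
    adequate_precision: float


@dataclass
class OptimizationResult:
    te: float
    tr: float
    aggregate: float
    predictions: dict[str, float]
    aggregation: str


def _model_matrix(coded: np.ndarray) -> np.ndarray:
    a, b = coded[:, 0], coded[:, 1]
    return np.column_stack([np.ones_like(a), a, b, a * b, a * a, b * b])


class ResponseSurface(RegressorMixin, BaseEstimator):
    """Quadratic response surface on two coded factors.

    ``fit`` expects ``X`` of shape (n, 2) with the *coded* factor levels
    and the n response values.  Fitted attributes:

    coef_ : ndarray (6,), coefficients for (1, A, B, AB, A^2, B^2)
    fitted_, residuals_ : per-run values
    anova_ : DataFrame with SS, df, MS, F, p and S/NS remark per term
        (model, the five terms, lack of fit, pure error, residual, total)
    diagnostics_ : :class:`FitDiagnostics`
    """

    def __init__(self, alpha_level: float = 0.05):
        self.alpha_level = alpha_level

    def fit(self, X, y):
        coded = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if coded.ndim != 2 or coded.shape[1] != 2:
            raise ContractError("X must have shape (n_runs, 2)")
        if len(y) != len(coded):
            raise ContractError("response length does not match the design")
        if not np.isfinite(y).all():
            raise ContractError("response values must be finite")
        n = len(y)
        M = _model_matrix(coded)
        p = M.shape[1]
        if n <= p:
            raise ContractError("design too small for the quadratic model")
        mtm_inv = np.linalg.inv(M.T @ M)
        beta = mtm_inv @ M.T @ y
        fitted = M @ beta
        resid = y - fitted

        self.X_ = coded
        self.y_ = y
        self.coef_ = beta
        self.fitted_ = fitted
        self.residuals_ = resid
        self._mtm_inv = mtm_inv
        self._hat_diag = np.einsum("ij,jk,ik->i", M, mtm_inv, M)
        self._anova_cache: pd.DataFrame | None = None
        self._diag_cache: FitDiagnostics | None = None
        return self

    @property
    def anova_(self) -> pd.DataFrame:
        """Per-term ANOVA; requires replicated runs for the pure error."""
        if self._anova_cache is None:
            self._anova_cache = self._anova()
        return self._anova_cache

    @property
    def diagnostics_(self) -> FitDiagnostics:
        if self._diag_cache is None:
            self._diag_cache = self._diagnostics()
        return self._diag_cache

    def predict(self, X) -> np.ndarray:
        coded = np.asarray(X, dtype=float)
        return _model_matrix(coded) @ self.coef_

    # -- ANOVA -------------------------------------------------------------

    def _pure_error(self) -> tuple[float, int]:
        """Pure-error SS and df pooled over replicated design points."""
        df = pd.DataFrame(self.X_, columns=["a", "b"]).round(12)
        df["y"] = self.y_
        ss, dof = 0.0, 0
        for _, grp in df.groupby(["a", "b"]):
            if len(grp) > 1:
                ss += float(((grp["y"] - grp["y"].mean()) ** 2).sum())
                dof += len(grp) - 1
        return ss, dof

    def _anova(self) -> pd.DataFrame:
        y = self.y_
        n = len(y)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        ss_res = float((self.residuals_ ** 2).sum())
        ss_mod = ss_tot - ss_res
        df_mod, df_res = 5, n - 6
        ms_res = ss_res / df_res
        rows = []

        def f_row(term, ss, dof, ms_den, df_den):
            ms = ss / dof
            F = ms / ms_den if ms_den > 0 else np.inf
            pval = float(stats.f.sf(F, dof, df_den))
            rows.append({"term": term, "SS": ss, "df": dof, "MS": ms,
                         "F": F, "p": pval,
                         "remark": "S" if pval < self.alpha_level else "NS"})

        f_row("model", ss_mod, df_mod, ms_res, df_res)
        # partial (Type III) SS per non-intercept term
        for t, term in enumerate(TERM_NAMES, start=1):
            ss_t = float(self.coef_[t] ** 2 / self._mtm_inv[t, t])
            f_row(term, ss_t, 1, ms_res, df_res)
        ss_pe, df_pe = self._pure_error()
        if df_pe == 0:
            raise DegenerateDataError(
                "lack of fit requires replicated design points")
        ss_lof = ss_res - ss_pe
        df_lof = df_res - df_pe
        f_row("lack of fit", ss_lof, df_lof, ss_pe / df_pe, df_pe)
        rows.append({"term": "pure error", "SS": ss_pe, "df": df_pe,
                     "MS": ss_pe / df_pe, "F": np.nan, "p": np.nan,
                     "remark": ""})
        rows.append({"term": "residual", "SS": ss_res, "df": df_res,
                     "MS": ms_res, "F": np.nan, "p": np.nan, "remark": ""})
        rows.append({"term": "total", "SS": ss_tot, "df": n - 1,
                     "MS": np.nan, "F": np.nan, "p": np.nan, "remark": ""})
        return pd.DataFrame(rows).set_index("term")

    def _diagnostics(self) -> FitDiagnostics:
        y, resid = self.y_, self.residuals_
        n = len(y)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        ss_res = float((resid ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        adj = 1.0 - (ss_res / (n - 6)) / (ss_tot / (n - 1))
        lev = self._hat_diag
        if np.any(lev >= 1.0 - 1e-12):
            raise DegenerateDataError("leverage 1: PRESS undefined")
        press = float(((resid / (1.0 - lev)) ** 2).sum())
        pred = 1.0 - press / ss_tot
        ms_res = ss_res / (n - 6)
        if ms_res > 0:
            adeq = float((self.fitted_.max() - self.fitted_.min())
                         / np.sqrt(6.0 * ms_res / n))
        else:
            adeq = float("inf")
        return FitDiagnostics(r_squared=r2, adj_r_squared=adj,
                              pred_r_squared=pred, press=press,
                              adequate_precision=adeq)


# -- functional wrappers ----------------------------------------------------

def fit_quadratic(design: CCDesign, response) -> ResponseSurface:
    """Least-squares quadratic fit on the coded design."""
    response = np.asarray(response, dtype=float)
    if len(response) != design.n_runs:
        raise ContractError("response length does not match the design")
    return ResponseSurface().fit(design.coded(), response)


def anova_rsm(fit: ResponseSurface) -> pd.DataFrame:
    return fit.anova_


def diagnostics(fit: ResponseSurface) -> FitDiagnostics:
    return fit.diagnostics_


def optimize_in_range(fits: Mapping[str, ResponseSurface] |
                      Sequence[ResponseSurface],
                      design: CCDesign,
                      aggregation: str = "mean",
                      weights: Mapping[str, float] | None = None,
                      step: tuple[float, float] = (0.1, 1.0)) -> OptimizationResult:
    """Grid-search maximization of the aggregated predicted surfaces.

    The grid covers the rectangular uncoded factor region spanned by
    the design (default resolution 0.1 ms in TE, 1 ms in TR).
    ``aggregation`` is ``"mean"`` (unweighted mean of the predicted
    responses) or ``"weighted"`` with explicit per-response weights.
    Ties resolve to the smallest (TE, TR).
    """
    if not isinstance(fits, Mapping):
        fits = {f"response_{i}": f for i, f in enumerate(fits)}
    if len(fits) == 0:
        raise ContractError("at least one fitted surface is required")
    (te_lo, te_hi), (tr_lo, tr_hi) = design.bounds()
    n_te = int(round((te_hi - te_lo) / step[0])) + 1
    n_tr = int(round((tr_hi - tr_lo) / step[1])) + 1
    if n_te < 1 or n_tr < 1:
        raise ContractError("empty optimization region")
    te = np.linspace(te_lo, te_hi, n_te)
    tr = np.linspace(tr_lo, tr_hi, n_tr)
    TE, TR = np.meshgrid(te, tr, indexing="ij")
    a, b = design.code(TE.ravel(), TR.ravel())
    coded = np.column_stack([a, b])
    preds = {name: f.predict(coded) for name, f in fits.items()}
    if aggregation == "mean":
        agg = np.mean(list(preds.values()), axis=0)
    elif aggregation == "weighted":
        if weights is None:
            raise ContractError("weighted aggregation needs weights")
        w = np.array([weights[name] for name in preds])
        agg = np.average(list(preds.values()), axis=0, weights=w)
    else:
        raise ContractError(f"unknown aggregation {aggregation!r}")
    best = int(np.argmax(agg))  # first occurrence: smallest (TE, TR)
    return OptimizationResult(
        te=float(TE.ravel()[best]), tr=float(TR.ravel()[best]),
        aggregate=float(agg[best]),
        predictions={name: float(v[best]) for name, v in preds.items()},
        aggregation=aggregation)
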
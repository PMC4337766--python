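"""Descriptive summaries: loess trends of DD vs NDVI and category tables.

These mirror the exploratory layer of the analysis: a local-linear (loess)
trend of mean diel displacement against NDVI together with a trend in its
coefficient of variation, and per-individual medians/means by forage
category.  Medians are used for DD to blunt occasional migration-scale
outliers; inferential weight stays with the mixed models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.nonparametric.smoothers_lowess import lowess

DEFAULT_SPAN = 0.75


class LoessSmoother(BaseEstimator):
    """Local linear regression with tricube weights (loess, degree 1)."""

    def __init__(self, span: float = DEFAULT_SPAN) -> None:
        self.span = span

    def fit(self, x: np.ndarray, y: np.ndarray):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) < 10:
            raise ValueError("need at least 10 points for a loess fit")
        if not 0.0 < self.span <= 1.0:
            raise ValueError("span must lie in (0, 1]")
        if int(np.ceil(self.span * len(x))) < 3:
            raise ValueError("span too small for a local linear fit")
        self.x_, self.y_ = x, y
        return self

    def predict(self, grid: np.ndarray) -> np.ndarray:
        grid = np.atleast_1d(np.asarray(grid, dtype=float))
        out = lowess(
            self.y_, self.x_, frac=self.span, it=0, xvals=grid, is_sorted=False
        )
        return np.asarray(out, dtype=float)


@dataclass
class LoessCurve:
    """Loess trend of the mean and (optionally) the CV of DD vs NDVI."""

    ndvi_grid: np.ndarray
    fitted_mean: np.ndarray
    fitted_cv: np.ndarray | None
    span: float
    degree: int = 1


def loess_fit(
    x: np.ndarray, y: np.ndarray, span: float = DEFAULT_SPAN, grid: np.ndarray | None = None
) -> LoessCurve:
    """Loess trend of ``y`` on ``x`` evaluated on a grid inside the data range."""
    sm = LoessSmoother(span=span).fit(x, y)
    if grid is None:
        grid = np.linspace(np.min(sm.x_), np.max(sm.x_), 100)
    return LoessCurve(np.asarray(grid, float), sm.predict(grid), None, span)


def cv_trend(
    records: pd.DataFrame, span: float = DEFAULT_SPAN, grid: np.ndarray | None = None
) -> LoessCurve:
    """Mean and coefficient-of-variation trends of DD along NDVI.

    The CV at each observation is SD/mean of DD over the span-nearest NDVI
    neighbors (a sliding window in NDVI order); the pointwise CVs are then
    loess-smoothed.  Windows with mean zero are skipped.
    """
    d = records.loc[records["valid"] if "valid" in records.columns else slice(None)]
    d = d.dropna(subset=["ndvi", "dd_km"]).sort_values("ndvi")
    x = d["ndvi"].to_numpy(dtype=float)
    y = d["dd_km"].to_numpy(dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 valid records")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 100)
    mean_curve = LoessSmoother(span=span).fit(x, y).predict(grid)
    k = max(3, int(np.ceil(span * n)))
    half = k // 2
    cvs, cx = [], []
    for i in range(n):
        lo = np.clip(i - half, 0, n - k)
        w = y[lo : lo + k]
        m = w.mean()
        if m == 0:
            continue
        cvs.append(w.std(ddof=1) / m)
        cx.append(x[i])
    cv_curve = LoessSmoother(span=span).fit(np.array(cx), np.array(cvs)).predict(grid)
    return LoessCurve(np.asarray(grid, float), mean_curve, cv_curve, span)


def category_summaries(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-individual and pooled summaries by forage category.

    Per individual x category: median DD, mean MP and day count.  Pooled
    values are unweighted averages of the per-individual statistics, plus
    the 0.95 DD quantile over all valid days.
    """
    d = records[records["valid"]] if "valid" in records.columns else records
    per = (
        d.groupby(["individual_id", "forage_category"], observed=False)
        .agg(
            median_dd=("dd_km", "median"),
            mean_mp=("mp", "mean"),
            n_days=("dd_km", "size"),
        )
        .reset_index()
    )
    per = per[per["n_days"] > 0]
    pooled = (
        per.groupby("forage_category", observed=False)[["median_dd", "mean_mp"]]
        .mean()
        .reset_index()
    )
    pooled["n_days"] = (
        per.groupby("forage_category", observed=False)["n_days"].sum().to_numpy()
    )
    overall = pd.DataFrame(
        {
            "dd_q95": [float(np.quantile(d["dd_km"].dropna(), 0.95))],
            "dd_max": [float(d["dd_km"].max())],
            "n_days": [int(len(d))],
        }
    )
    return {"per_individual": per, "pooled": pooled, "overall": overall}
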
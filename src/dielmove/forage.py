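"""NDVI alignment and forage-availability categories.

Daily movement records receive the ecosystem NDVI value for their date and a
seasonal forage category — low (LFA), medium (MFA) or high (HFA) forage
availability — from three equal-width bins spanning the NDVI range observed
across all valid movement days, pooled over individuals.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

FORAGE_LEVELS = ("LFA", "MFA", "HFA")


def assign_daily_ndvi(records: pd.DataFrame, ndvi: pd.DataFrame) -> pd.DataFrame:
    """Attach an NDVI value to each record by date.

    A daily NDVI series gives an exact lookup; a coarser series is linearly
    interpolated in time.  Records outside the NDVI date span are dropped
    with a warning.
    """
    ndvi = ndvi.sort_values("date")
    nd = pd.to_datetime(ndvi["date"]).astype("int64").to_numpy(dtype=float)
    nv = ndvi["ndvi"].to_numpy(dtype=float)
    records = records.copy()
    rd = pd.to_datetime(records["date"]).astype("int64").to_numpy(dtype=float)
    inside = (rd >= nd[0]) & (rd <= nd[-1])
    if not inside.all():
        warnings.warn(
            f"dropping {int((~inside).sum())} record(s) outside the NDVI date span",
            stacklevel=2,
        )
    records = records.loc[inside].copy()
    records["ndvi"] = np.interp(rd[inside], nd, nv)
    return records


class ForageBinner(BaseEstimator):
    """Three equal-width NDVI bins learned from valid movement days.

    ``fit`` computes the interior cut points ``edges_`` splitting the
    observed NDVI range into thirds; ``transform`` assigns LFA / MFA / HFA
    with half-open intervals and a closed top interval.
    """

    def fit(self, records: pd.DataFrame, y=None):
        mask = records["valid"] if "valid" in records.columns else np.ones(len(records), bool)
        v = records.loc[mask, "ndvi"].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if len(v) == 0:
            raise ValueError("no valid NDVI values to bin")
        lo, hi = float(v.min()), float(v.max())
        if hi == lo:
            raise ValueError("degenerate NDVI range: max equals min")
        self.range_ = (lo, hi)
        width = (hi - lo) / 3.0
        self.edges_ = (lo + width, lo + 2.0 * width)
        return self

    def transform(self, records: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "edges_"):
            raise RuntimeError("call fit before transform")
        e1, e2 = self.edges_
        v = records["ndvi"].to_numpy(dtype=float)
        cat = np.where(v < e1, "LFA", np.where(v < e2, "MFA", "HFA"))
        out = records.copy()
        out["forage_category"] = pd.Categorical(cat, categories=list(FORAGE_LEVELS))
        return out

    def fit_transform(self, records: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(records).transform(records)


def bin_forage(records: pd.DataFrame) -> pd.DataFrame:
    """Learn equal-width bins on valid records and categorize every record."""
    return ForageBinner().fit_transform(records)
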
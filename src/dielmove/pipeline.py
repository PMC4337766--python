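"""End-to-end pipeline: tracks + NDVI + ranks -> diel records -> model fits."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import forage, glmm, spectral, trajectory
from .trajectory import DEFAULT_DAY_OFFSET_HOURS, GpsTrack


def compute_diel_records(
    tracks: dict[str, GpsTrack],
    ndvi: pd.DataFrame,
    ranks: pd.DataFrame,
    day_offset_hours: int = DEFAULT_DAY_OFFSET_HOURS,
) -> tuple[pd.DataFrame, dict[str, trajectory.DisplacementSeries]]:
    """Diel records (DD, NDVI, forage category, rank) for all individuals.

    Also returns each individual's hourly displacement series for the
    spectral stage.
    """
    rank_map = ranks.set_index("individual_id")["rank"]
    rec_list = []
    series_by_ind: dict[str, trajectory.DisplacementSeries] = {}
    for ind, track in tracks.items():
        reg = trajectory.regularize_and_interpolate(track)
        series = trajectory.hourly_displacements(reg, day_offset_hours)
        series_by_ind[ind] = series
        rec = trajectory.diel_displacement(
            series, trajectory.day_fix_counts(reg, day_offset_hours)
        )
        rec["rank"] = rank_map.get(ind, "low")
        rec_list.append(rec)
    records = pd.concat(rec_list, ignore_index=True)
    records = forage.assign_daily_ndvi(records, ndvi)
    records = forage.bin_forage(records)
    return records, series_by_ind


def compute_mp(
    records: pd.DataFrame,
    series_by_ind: dict[str, trajectory.DisplacementSeries],
    alpha: float = spectral.DEFAULT_ALPHA,
    n_surrogates: int = spectral.DEFAULT_N_SURROGATES,
    seed: int = 0,
) -> pd.DataFrame:
    """Fill the MP column of the diel records."""
    return spectral.fill_mp(records, series_by_ind, alpha, n_surrogates, seed)


def fit_models(records: pd.DataFrame) -> dict[str, dict]:
    """Fit the DD and MP mixed-model suites on triplet model rows."""
    out = {}
    for response in ("dd", "mp"):
        rows = trajectory.extract_model_rows(records, response)
        out[response] = glmm.fit_model_suite(rows, response)
        out[response]["n_rows"] = len(rows)
    return out


def run_pipeline(
    tracks: dict[str, GpsTrack],
    ndvi: pd.DataFrame,
    ranks: pd.DataFrame,
    day_offset_hours: int = DEFAULT_DAY_OFFSET_HOURS,
    alpha: float = spectral.DEFAULT_ALPHA,
    n_surrogates: int = spectral.DEFAULT_N_SURROGATES,
    seed: int = 0,
) -> dict:
    """tracks -> DD -> MP -> forage bins -> both model suites."""
    records, series = compute_diel_records(tracks, ndvi, ranks, day_offset_hours)
    records = compute_mp(records, series, alpha, n_surrogates, seed)
    models = fit_models(records)
    return {"records": records, "models": models}


def lag_anchor(records: pd.DataFrame, response: str) -> tuple[float, float]:
    """Lag values at which prediction curves are drawn: the response's
    median over all individuals for DD, its mean for MP."""
    rows = trajectory.extract_model_rows(records, response)
    stat = np.median if response == "dd" else np.mean
    return float(stat(rows["lag1"])), float(stat(rows["lag2"]))
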
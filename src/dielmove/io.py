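"""CSV readers/writers for the pipeline's tabular interfaces.

Tracks: ``individual_id,timestamp,lat,lon,success`` with ISO-8601 hourly
timestamps; missing rows count as failed fixes.  NDVI: ``date,ndvi``.
Ranks: ``individual_id,rank``.  Diel records:
``individual_id,date,dd_km,n_fixes,valid,ndvi,forage_category,rank,mp``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trajectory import GpsTrack


def tracks_from_frame(df: pd.DataFrame) -> dict[str, GpsTrack]:
    """Per-individual GpsTrack objects on a full hourly grid.

    Hours absent from the table (between each individual's first and last
    row) are inserted as failed fixes.
    """
    out: dict[str, GpsTrack] = {}
    df = df.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if (df["timestamp"].dt.minute != 0).any() or (df["timestamp"].dt.second != 0).any():
        raise ValueError("timestamps must fall on whole hours")
    for ind, grp in df.groupby("individual_id", sort=True):
        grp = grp.sort_values("timestamp")
        if grp["timestamp"].duplicated().any():
            raise ValueError(f"duplicate timestamps for {ind}")
        grid = pd.date_range(grp["timestamp"].iloc[0], grp["timestamp"].iloc[-1], freq="h")
        g = grp.set_index("timestamp").reindex(grid)
        success = g["success"].fillna(0).astype(bool).to_numpy()
        lat = g["lat"].to_numpy(dtype=float)
        lon = g["lon"].to_numpy(dtype=float)
        lat[~success] = np.nan
        lon[~success] = np.nan
        out[str(ind)] = GpsTrack(str(ind), grid, lat, lon, success)
    return out


def read_tracks(path) -> dict[str, GpsTrack]:
    return tracks_from_frame(pd.read_csv(path))


def read_ndvi(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"])
    return df[["date", "ndvi"]]


def read_ranks(path) -> pd.DataFrame:
    return pd.read_csv(path)[["individual_id", "rank"]]


def read_diel_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"])
    return df


def write_diel_records(records: pd.DataFrame, path) -> None:
    cols = [
        c
        for c in (
            "individual_id", "date", "dd_km", "n_fixes", "valid",
            "ndvi", "forage_category", "rank", "mp",
        )
        if c in records.columns
    ]
    out = records[cols].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_tracks(tracks: pd.DataFrame, path) -> None:
    out = tracks.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, float_format="%.6f")
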